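"""Genome-wide target ranking for one query compound in a synthetic world.

Generates a small world in which structurally similar drugs target
network-proximal proteins, re-queries one drug's own fingerprint
(leave-one-out), and prints the top-ranked candidate targets.  The
concordance score of a gene is the Pearson correlation between the
query's chemical-similarity profile over the drug space and the gene's
network functional-similarity profile; the planted targets should surface
at the top.
"""

from netpharm import rank_targets
from netpharm.synthetic import generate_world

world = generate_world(seed=11, n_nodes=300, n_drugs=60, n_families=10, n_queries=5)
query = world.queries[0]
truth = sorted(query.true_targets)
print(f"query {query.compound_id} copies drug {query.source_drug_id}; "
      f"planted targets: {', '.join(truth)}")

ranking = rank_targets(
    query.fingerprint, world.space, world.net, query_id=query.compound_id
)
print(f"\ntop 10 of {len(ranking)} candidate genes (score = concordance):")
for gene, score, rank in list(ranking.entries())[:10]:
    mark = " <- planted" if gene in query.true_targets else ""
    print(f"  {rank:2d}. {gene}  {score:+.3f}{mark}")

ranks = {g: r for g, _, r in ranking.entries()}
print("\nranks of the planted targets:", [ranks[t] for t in truth])
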