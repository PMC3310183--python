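"""Gene-set enrichment and network hub depletion of a candidate target set.

Takes the pooled planted targets of a synthetic world as the candidate
set, tests them against the world's gene-set collection (upper-tailed
hypergeometric, ranked by increasing p, with coverage k/K per set) and
against the top-5% degree/betweenness hubs (lower-tailed).  The planted
set should rank first; the depletion p quantifies avoidance of hubs.
"""

from netpharm import enrich_gene_sets, hub_depletion
from netpharm.synthetic import generate_world

world = generate_world(seed=11, n_nodes=300, n_drugs=60, n_families=10, n_queries=15)
candidates = world.planted_targets
print(f"candidate set: {len(candidates)} pooled planted target genes")

universe = frozenset(world.net.nodes) & frozenset().union(
    *(g.members for g in world.collection)
)
results = enrich_gene_sets(candidates, world.collection, universe, tail="upper")
print(f"\ntop 5 of {len(results)} gene sets (universe N={results[0].universe_N}):")
print(f"{'set':10s} {'K':>4s} {'k':>4s} {'p-value':>10s} {'coverage':>9s}")
for r in results[:5]:
    print(f"{r.set_id:10s} {r.set_K:4d} {r.overlap_k:4d} {r.p_value:10.3g} {r.coverage:9.4f}")

print("\nhub depletion (lower-tailed; small p = candidates avoid hubs):")
for metric in ("degree", "betweenness"):
    res = hub_depletion(candidates, world.net, metric=metric, hub_fraction=0.05)
    print(f"  {metric:12s} k={res.overlap_k} of K={res.set_K} hubs, p = {res.p_value:.3g}")
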