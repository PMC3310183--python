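"""Self-contained synthetic worlds for exercising the full pipeline.

A world plants the method's core assumption — structurally similar drugs
target network-proximal proteins — into generated data:

* a scale-free (preferential-attachment) protein-interaction network;
* a drug space partitioned into structural families, each sharing a core
  feature set and targeting the radius-1 neighborhood of a family anchor
  node, so chemical similarity and target proximity co-vary;
* query compounds copied from space drugs (optionally feature-perturbed)
  with the source drug's targets as planted truth;
* a gene-set collection of random sets plus one planted set (the pooled
  planted targets) that enrichment must recover.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .enrichment import GeneSet
from .space import DrugRecord, DrugSpace

__all__ = [
    "Query",
    "SyntheticWorld",
    "generate_network",
    "generate_drug_space",
    "generate_queries",
    "generate_random_fingerprints",
    "generate_gene_set_collection",
    "generate_world",
    "DEFAULT_PARAMS",
]

#: Default world: the conditions used throughout the test-bench analyses.
DEFAULT_PARAMS = {
    "n_nodes": 1000,
    "attach_m": 3,
    "n_drugs": 200,
    "n_families": 20,
    "features_per_drug": 30,
    "targets_per_drug": 4,
    "feature_universe": 2000,
    "noise": 0.3,
    "atc_c_fraction": 0.3,
    "n_queries": 50,
    "perturbation": 0.0,
    "n_random_sets": 50,
    "random_set_size": 40,
}


@dataclass(frozen=True)
class Query:
    """A query compound with its planted ground truth."""

    compound_id: str
    fingerprint: frozenset
    source_drug_id: str
    true_targets: frozenset


@dataclass
class SyntheticWorld:
    net: nx.Graph
    space: DrugSpace
    queries: tuple
    collection: list
    params: dict
    seed: int

    @property
    def planted_targets(self) -> frozenset:
        """Union of all queries' planted target genes."""
        out: set = set()
        for q in self.queries:
            out |= q.true_targets
        return frozenset(out)

    def write(self, outdir) -> None:
        """Emit the world in the formats the real-data loaders consume."""
        from pathlib import Path

        from . import io as npio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "network.tsv", "w") as fh:
            fh.write("# synthetic protein-interaction network edge list\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.net.edges):
                fh.write(f"{a}\t{b}\n")
        npio.write_drug_space(self.space, outdir / "drug_space.tsv")
        npio.write_compounds(
            [npio.Compound(q.compound_id, None, q.fingerprint) for q in self.queries],
            outdir / "compounds.tsv",
        )
        npio.write_gmt(self.collection, outdir / "gene_sets.gmt")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("compound_id\tsource_drug_id\ttrue_targets\n")
            for q in self.queries:
                fh.write(
                    f"{q.compound_id}\t{q.source_drug_id}\t"
                    + ",".join(sorted(q.true_targets))
                    + "\n"
                )


def _node_label(i: int, n: int) -> str:
    width = max(4, len(str(n)))
    return f"G{i + 1:0{width}d}"


def generate_network(n_nodes: int, attach_m: int = 3, seed: int = 0) -> nx.Graph:
    """Scale-free network by preferential attachment; connected by design.

    Nodes are relabelled G0001..G{n}.  ``attach_m`` is the number of edges
    each arriving node attaches with; m=1 yields a tree.
    """
    if not n_nodes >= attach_m + 1 >= 2:
        raise ValueError(
            f"need n_nodes >= attach_m + 1 >= 2, got n_nodes={n_nodes}, attach_m={attach_m}"
        )
    g = nx.barabasi_albert_graph(n_nodes, attach_m, seed=int(seed))
    mapping = {i: _node_label(i, n_nodes) for i in g.nodes}
    return nx.relabel_nodes(g, mapping)


def generate_drug_space(
    net: nx.Graph,
    n_drugs: int = 200,
    n_families: int = 20,
    features_per_drug: int = 30,
    targets_per_drug: int = 4,
    noise: float = 0.3,
    seed: int = 0,
    feature_universe: int = 2000,
    atc_c_fraction: float = 0.3,
) -> DrugSpace:
    """Drug space of structural families tied to network neighborhoods.

    Each family shares a core feature set; a drug keeps a fraction
    ``1 - noise`` of it (sampled) and fills up with private random
    features.  Each family has an anchor node; every family drug's
    targets are sampled from the anchor's closed radius-1 neighborhood
    (expanded with a warning if too small), so within-family drugs are
    both chemically similar and target-proximal.  A fraction of drugs is
    tagged with an ATC code in class "C".
    """
    if n_families > n_drugs:
        raise ValueError("n_families must be <= n_drugs")
    if targets_per_drug < 1:
        raise ValueError("targets_per_drug must be >= 1")
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(int(seed))
    nodes = sorted(net.nodes)
    universe = np.arange(feature_universe)

    anchors = rng.choice(len(nodes), size=n_families, replace=False)
    family_core = [
        rng.choice(universe, size=features_per_drug, replace=False)
        for _ in range(n_families)
    ]
    family_pool = []
    for a in anchors:
        anchor = nodes[a]
        pool = {anchor} | set(net.neighbors(anchor))
        radius = 1
        while len(pool) < targets_per_drug:
            radius += 1
            pool = set(nx.single_source_shortest_path_length(net, anchor, cutoff=radius))
            warnings.warn(
                f"family anchor {anchor}: radius expanded to {radius} to reach "
                f"{targets_per_drug} candidate targets",
                stacklevel=2,
            )
        family_pool.append(sorted(pool))

    n_core = round((1 - noise) * features_per_drug)
    width = max(4, len(str(n_drugs)))
    drugs = []
    for i in range(n_drugs):
        fam = i % n_families
        core = rng.choice(family_core[fam], size=n_core, replace=False)
        fp = set(f"F{t}" for t in core)
        while len(fp) < features_per_drug:
            extra = rng.choice(universe, size=features_per_drug - len(fp), replace=False)
            fp |= {f"F{t}" for t in extra}
        targets = rng.choice(
            family_pool[fam], size=min(targets_per_drug, len(family_pool[fam])), replace=False
        )
        atc: tuple
        if rng.random() < atc_c_fraction:
            atc = (f"C{rng.integers(1, 11):02d}",)
        else:
            atc = (f"N{rng.integers(1, 11):02d}",)
        drugs.append(
            DrugRecord(
                drug_id=f"D{i + 1:0{width}d}",
                fingerprint=frozenset(fp),
                targets=frozenset(str(t) for t in targets),
                atc_codes=atc,
            )
        )
    meta = {
        "feature_universe": feature_universe,
        "n_families": n_families,
        "family_anchor": {f"family_{f}": nodes[a] for f, a in enumerate(anchors)},
    }
    return DrugSpace(drugs, meta=meta)


def generate_queries(
    space: DrugSpace,
    n_queries: int = 50,
    perturbation: float = 0.0,
    seed: int = 0,
) -> tuple:
    """Queries copied from space drugs, with planted target truth.

    Each query picks a random source drug, copies its fingerprint, and
    resamples a ``perturbation`` fraction of features from the feature
    universe; its planted truth is the source drug's target set.  With
    perturbation 0 this is the leave-one-out design: the drug's own
    fingerprint re-queried against the space.
    """
    if not 0 <= perturbation < 1:
        raise ValueError("perturbation must be in [0, 1)")
    rng = np.random.default_rng(int(seed))
    universe = [f"F{t}" for t in range(space.meta.get("feature_universe", 2000))]
    out = []
    width = max(3, len(str(n_queries)))
    for i in range(n_queries):
        src = space[int(rng.integers(len(space)))]
        fp = set(src.fingerprint)
        n_swap = round(perturbation * len(fp))
        if n_swap:
            drop = rng.choice(sorted(fp), size=n_swap, replace=False)
            fp -= set(drop)
            # refill with novel features so similarity to the source decays
            while len(fp) < len(src.fingerprint):
                add = rng.choice(universe, size=len(src.fingerprint) - len(fp), replace=False)
                fp |= {str(a) for a in add if str(a) not in src.fingerprint}
        out.append(
            Query(
                compound_id=f"Q{i + 1:0{width}d}",
                fingerprint=frozenset(fp),
                source_drug_id=src.drug_id,
                true_targets=src.targets,
            )
        )
    return tuple(out)


def generate_random_fingerprints(
    n: int, size: int = 30, feature_universe: int = 2000, seed: int = 0
) -> tuple:
    """Fingerprints drawn independently of any drug space (null queries)."""
    rng = np.random.default_rng(int(seed))
    return tuple(
        frozenset(f"F{t}" for t in rng.choice(feature_universe, size=size, replace=False))
        for _ in range(n)
    )


def generate_gene_set_collection(
    net: nx.Graph,
    n_sets: int = 50,
    set_size: int = 40,
    planted_set=frozenset(),
    seed: int = 0,
) -> list:
    """Random gene sets from the network nodes plus one planted set.

    The planted set (typically the pooled planted targets of the world's
    queries) is appended with id ``PLANTED``; if empty, only the random
    sets are returned.
    """
    nodes = sorted(net.nodes)
    if set_size > len(nodes):
        raise ValueError("set_size exceeds the node count")
    rng = np.random.default_rng(int(seed))
    width = max(3, len(str(n_sets)))
    sets = [
        GeneSet(
            set_id=f"RS{i + 1:0{width}d}",
            name=f"random set {i + 1}",
            members=frozenset(str(g) for g in rng.choice(nodes, size=set_size, replace=False)),
        )
        for i in range(n_sets)
    ]
    planted_set = frozenset(planted_set)
    if planted_set:
        missing = planted_set - set(nodes)
        if missing:
            raise ValueError(f"planted genes not in the network: {sorted(missing)}")
        sets.append(GeneSet(set_id="PLANTED", name="planted target set", members=planted_set))
    return sets


def generate_world(seed: int = 42, **overrides) -> SyntheticWorld:
    """Generate a full synthetic world from one seed.

    Defaults are :data:`DEFAULT_PARAMS` (1000-node network, 200 drugs in
    20 families, feature noise 0.3, 50 leave-one-out queries); any
    parameter can be overridden by keyword.  Component seeds are derived
    deterministically from ``seed``.
    """
    params = dict(DEFAULT_PARAMS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise TypeError(f"unknown world parameters: {sorted(unknown)}")
    params.update(overrides)

    seed = int(seed)
    net = generate_network(params["n_nodes"], params["attach_m"], seed=seed)
    space = generate_drug_space(
        net,
        n_drugs=params["n_drugs"],
        n_families=params["n_families"],
        features_per_drug=params["features_per_drug"],
        targets_per_drug=params["targets_per_drug"],
        noise=params["noise"],
        seed=seed + 1,
        feature_universe=params["feature_universe"],
        atc_c_fraction=params["atc_c_fraction"],
    )
    queries = generate_queries(
        space,
        n_queries=params["n_queries"],
        perturbation=params["perturbation"],
        seed=seed + 2,
    )
    planted: set = set()
    for q in queries:
        planted |= q.true_targets
    collection = generate_gene_set_collection(
        net,
        n_sets=params["n_random_sets"],
        set_size=params["random_set_size"],
        planted_set=frozenset(planted),
        seed=seed + 3,
    )
    return SyntheticWorld(
        net=net,
        space=space,
        queries=queries,
        collection=collection,
        params=params,
        seed=seed,
    )
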