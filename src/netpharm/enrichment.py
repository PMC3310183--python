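"""Hypergeometric enrichment/depletion of candidate target sets.

Covers the three analyses run on a pooled candidate-target set:

* enrichment against a known drug-target set (e.g. targets of drugs whose
  ATC code starts with "C", the cardiovascular class), upper-tailed;
* enrichment against a gene-set collection (pathways, GO-style flat
  sets from GMT), upper-tailed, ranked by increasing p, with a coverage
  statistic k/K per set;
* depletion among network hubs (top-5% degree or betweenness nodes),
  lower-tailed.

Significance is the raw p < alpha rule (no multiplicity correction); a
Benjamini-Hochberg column is emitted alongside for reference but is not
used to declare significance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import top_fraction_nodes

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeom_tail",
    "coverage",
    "enrich_gene_sets",
    "known_targets_by_atc",
    "hub_depletion",
]


@dataclass(frozen=True)
class GeneSet:
    """One named gene set (a pathway, GO term, or planted synthetic set)."""

    set_id: str
    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass
class EnrichmentResult:
    """One hypergeometric test record.

    With universe size N, set size K, sample (candidate) size n and
    overlap k: upper tail is P(X >= k), lower tail P(X <= k) for
    X ~ Hypergeometric(N, K, n).  Coverage is k / K, the fraction of the
    set's members present among the candidates.
    """

    set_id: str
    name: str
    universe_N: int
    set_K: int
    sample_n: int
    overlap_k: int
    tail: str
    p_value: float
    coverage: float
    p_adjusted: float | None = None


def hypergeom_tail(N, K, n, k, tail: str = "upper"):
    """Exact hypergeometric tail probability.

    ``tail="upper"`` gives P(X >= k), ``"lower"`` gives P(X <= k), for X the
    overlap between a size-n sample and a size-K set drawn without
    replacement from a size-N universe.  Evaluated through scipy's
    log-space survival/cumulative functions, so deep tails keep relative
    accuracy.  Scalars or broadcastable integer arrays are accepted.
    """
    N = np.asarray(N, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    k = np.asarray(k, dtype=np.int64)
    if np.any(K < 0) or np.any(K > N):
        raise ValueError("require 0 <= K <= N")
    if np.any(n < 0) or np.any(n > N):
        raise ValueError("require 0 <= n <= N")
    if np.any(k < 0) or np.any(k > np.minimum(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    if tail == "upper":
        p = np.exp(stats.hypergeom.logsf(k - 1, N, K, n))
    elif tail == "lower":
        p = np.exp(stats.hypergeom.logcdf(k, N, K, n))
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return float(p) if p.ndim == 0 else p


def coverage(overlap_k: int, set_K: int) -> float:
    """Fraction k/K of a gene set's members found among the candidates.

    Reports print this to 4 decimals.
    """
    if set_K < 1:
        raise ValueError("set size K must be >= 1")
    if not 0 <= overlap_k <= set_K:
        raise ValueError(f"require 0 <= k <= K, got k={overlap_k}, K={set_K}")
    return overlap_k / set_K


def enrich_gene_sets(candidates, collection, universe, tail: str = "upper"):
    """Test every gene set in a collection against a candidate gene set.

    Candidates outside the universe are dropped with a warning; each
    set's membership is intersected with the universe (sets left empty
    are skipped).  Results are sorted by increasing p-value (ties by
    set_id) — the ranking convention of the enrichment tables — and a
    Benjamini-Hochberg adjusted p is attached for reference.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    candidates = frozenset(candidates)
    outside = candidates - universe
    if outside:
        warnings.warn(
            f"{len(outside)} candidate gene(s) outside the universe dropped",
            stacklevel=2,
        )
        candidates = candidates & universe
    N = len(universe)
    n = len(candidates)

    results = []
    for gs in collection:
        members = gs.members & universe
        K = len(members)
        if K == 0:
            warnings.warn(
                f"gene set {gs.set_id!r} has no members in the universe; skipped",
                stacklevel=2,
            )
            continue
        k = len(candidates & members)
        results.append(
            EnrichmentResult(
                set_id=gs.set_id,
                name=gs.name,
                universe_N=N,
                set_K=K,
                sample_n=n,
                overlap_k=k,
                tail=tail,
                p_value=hypergeom_tail(N, K, n, k, tail),
                coverage=coverage(k, K),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_id))
    if results:
        adj = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, a in zip(results, adj):
            r.p_adjusted = float(min(a, 1.0))
    return results


def known_targets_by_atc(space, atc_prefix: str) -> frozenset:
    """Union of target sets of drugs with an ATC code matching a prefix.

    Matching is case-insensitive on the code string; prefix "C" selects
    the cardiovascular first level.  Drugs without ATC codes are simply
    excluded.
    """
    if not atc_prefix:
        raise ValueError("ATC prefix must be non-empty")
    prefix = atc_prefix.upper()
    out: set = set()
    for d in space:
        if any(code.upper().startswith(prefix) for code in d.atc_codes):
            out |= d.targets
    return frozenset(out)


def hub_depletion(
    candidates, net, metric: str = "degree", hub_fraction: float = 0.05
) -> EnrichmentResult:
    """Lower-tailed test of candidate under-representation among hubs.

    The hub set is the top ``hub_fraction`` of network nodes by degree or
    betweenness; the universe is the full node set.  A small p means the
    candidates avoid topologically central proteins.
    """
    candidates = frozenset(candidates)
    outside = candidates - set(net.nodes)
    if outside:
        warnings.warn(
            f"{len(outside)} candidate gene(s) not in the network dropped",
            stacklevel=2,
        )
        candidates = candidates - outside
    if not candidates:
        raise ValueError("no candidate genes in the network")
    hubs = top_fraction_nodes(net, metric, hub_fraction)
    N = net.number_of_nodes()
    K = len(hubs)
    n = len(candidates)
    k = len(candidates & hubs)
    return EnrichmentResult(
        set_id=f"hub_{metric}_top{hub_fraction:g}",
        name=f"top {hub_fraction:.0%} {metric} hubs",
        universe_N=N,
        set_K=K,
        sample_n=n,
        overlap_k=k,
        tail="lower",
        p_value=hypergeom_tail(N, K, n, k, "lower"),
        coverage=coverage(k, K),
    )
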