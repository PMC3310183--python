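"""Concordance scoring and genome-wide target ranking for query compounds.

A query compound's likelihood of targeting a gene is scored by the
correlation between two profile vectors indexed by the reference drug
space: the compound's chemical-similarity profile (Tanimoto to each
reference drug) and the gene's functional-similarity profile (network
proximity to each reference drug's known targets).  Structurally similar
drugs tend to hit functionally related — i.e. network-proximal — proteins,
so a high concordance marks the gene as a candidate target.

Zero-variance profiles carry no concordance evidence; their score is a
degenerate flag (NaN) that sorts below every real correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fingerprints import structure_profile
from .network import functional_profile_matrix

__all__ = [
    "concordance_score",
    "RankedTargets",
    "PooledTargets",
    "rank_targets",
    "select_top_percent",
    "pool_targets",
    "mean_compounds_per_target",
    "recovery_at_top",
]


def concordance_score(s, f, method: str = "pearson") -> float:
    """Correlation between a structure profile and a functional profile.

    Returns NaN (the degenerate flag, ranked below any real score) when
    either profile has zero variance.  ``method`` is ``"pearson"``
    (default) or ``"spearman"``.
    """
    s = np.asarray(s, dtype=float)
    f = np.asarray(f, dtype=float)
    if s.shape != f.shape:
        raise ValueError(f"profile length mismatch: {s.shape} vs {f.shape}")
    if s.size < 3:
        raise ValueError("profiles must have length >= 3")
    if method == "spearman":
        s = stats.rankdata(s)
        f = stats.rankdata(f)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sc = s - s.mean()
    fc = f - f.mean()
    denom = math.sqrt(float(sc @ sc) * float(fc @ fc))
    if denom == 0.0:
        return float("nan")
    return float(sc @ fc) / denom


@dataclass
class RankedTargets:
    """Genome-wide ranking of candidate targets for one query compound.

    ``genes`` is the full network node set in rank order (rank = position
    + 1); ``scores`` is aligned, with NaN marking degenerate entries.
    """

    query_id: str
    genes: tuple
    scores: tuple
    degenerate: bool = False  # True when the whole query was unscorable

    def __len__(self) -> int:
        return len(self.genes)

    def entries(self):
        """Iterate (gene_id, score, rank) in rank order."""
        for i, (g, s) in enumerate(zip(self.genes, self.scores)):
            yield g, s, i + 1

    def rank_of(self, gene: str) -> int:
        return self.genes.index(gene) + 1


@dataclass
class PooledTargets:
    """Union of per-compound top-fraction target sets with selection counts."""

    fraction: float
    counts: dict  # gene -> number of compounds selecting it

    @property
    def genes(self) -> frozenset:
        return frozenset(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


def _order(genes, scores):
    """Rank order: decreasing score, NaN last, ties by ascending gene id."""
    return sorted(
        range(len(genes)),
        key=lambda i: (math.isnan(scores[i]), -(scores[i] if not math.isnan(scores[i]) else 0.0), genes[i]),
    )


def rank_targets(
    query,
    space,
    net,
    *,
    query_id: str = "query",
    kernel: str = "gauss",
    method: str = "pearson",
    profiles=None,
) -> RankedTargets:
    """Score and rank every network gene as a candidate target of ``query``.

    ``profiles`` may be a precomputed ``(genes, matrix)`` pair from
    :func:`netpharm.network.functional_profile_matrix`; it is
    query-independent and should be reused across compounds.

    A query whose structure profile has zero variance (e.g. no feature
    overlap with any reference drug) cannot be scored: the result is
    flagged degenerate and ordered by gene id alone.
    """
    if len(space) < 3:
        raise ValueError("drug space must contain at least 3 drugs")
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if profiles is None:
        profiles = functional_profile_matrix(net, space, kernel=kernel)
    genes, fmat = profiles

    s = structure_profile(query, space)
    if method == "spearman":
        s_used = stats.rankdata(s)
        fmat_used = stats.rankdata(fmat, axis=1)
    else:
        s_used = s
        fmat_used = fmat

    sc = s_used - s_used.mean()
    s_norm = math.sqrt(float(sc @ sc))
    if s_norm == 0.0:
        warnings.warn(
            f"query {query_id!r}: structure profile has zero variance; "
            "ranking is degenerate",
            stacklevel=2,
        )
        scores = tuple(float("nan") for _ in genes)
        order = sorted(range(len(genes)), key=lambda i: genes[i])
        return RankedTargets(
            query_id=query_id,
            genes=tuple(genes[i] for i in order),
            scores=tuple(scores[i] for i in order),
            degenerate=True,
        )

    fc = fmat_used - fmat_used.mean(axis=1, keepdims=True)
    f_norms = np.sqrt((fc * fc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (fc @ sc) / (f_norms * s_norm)
    r[f_norms == 0.0] = np.nan

    scores = [float(x) for x in r]
    order = _order(genes, scores)
    return RankedTargets(
        query_id=query_id,
        genes=tuple(genes[i] for i in order),
        scores=tuple(scores[i] for i in order),
        degenerate=False,
    )


def select_top_percent(r: RankedTargets, fraction: float) -> frozenset:
    """The top max(1, floor(fraction*N)) ranked genes, skipping degenerates.

    A fully degenerate ranking yields an empty set (with a warning).
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = len(r.genes)
    count = max(1, int(fraction * n))
    valid = [g for g, s in zip(r.genes, r.scores) if not math.isnan(s)]
    if not valid:
        warnings.warn(
            f"query {r.query_id!r}: fully degenerate ranking; empty selection",
            stacklevel=2,
        )
        return frozenset()
    return frozenset(valid[:count])


def pool_targets(rankings, fraction: float) -> PooledTargets:
    """Pool per-compound top-fraction selections across a formula's compounds.

    Returns the union with, for each gene, the number of compounds whose
    top-fraction set contains it.  Degenerate rankings contribute nothing;
    at least one non-degenerate ranking is required.
    """
    counts: dict = {}
    n_usable = 0
    for r in rankings:
        if r.degenerate:
            continue
        n_usable += 1
        for g in select_top_percent(r, fraction):
            counts[g] = counts.get(g, 0) + 1
    if n_usable == 0:
        raise ValueError("no non-degenerate rankings to pool")
    return PooledTargets(fraction=fraction, counts=counts)


def mean_compounds_per_target(p: PooledTargets) -> float:
    """Average number of compounds selecting each pooled target gene."""
    if not p.counts:
        raise ValueError("pooled target set is empty")
    return sum(p.counts.values()) / len(p.counts)


def recovery_at_top(r: RankedTargets, truth, fraction: float) -> float:
    """Fraction of true targets recovered in the top-fraction selection."""
    truth = frozenset(truth)
    if not truth:
        raise ValueError("truth set is empty")
    missing = truth - set(r.genes)
    if missing:
        raise ValueError(f"truth genes not in the ranking: {sorted(missing)}")
    top = select_top_percent(r, fraction)
    return len(truth & top) / len(truth)
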