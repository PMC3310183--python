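"""Recovery evaluation of target ranking on worlds with planted truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import functional_profile_matrix
from .prediction import rank_targets, recovery_at_top

__all__ = ["RecoverySummary", "loo_recovery_summary", "null_recovery"]


@dataclass
class RecoverySummary:
    """Aggregate leave-one-out recovery over a world's queries.

    ``top_percentile_rate`` is the fraction of queries for which *all*
    planted targets rank within the top ``1 - percentile`` of genes;
    ``mean_recovery`` averages :func:`recovery_at_top` at ``top_fraction``.
    """

    n_queries: int
    percentile: float
    top_percentile_rate: float
    top_fraction: float
    mean_recovery: float
    per_query_recovery: tuple
    per_query_all_in_top: tuple


def loo_recovery_summary(
    world,
    top_fraction: float = 0.01,
    percentile: float = 0.95,
    kernel: str = "gauss",
    method: str = "pearson",
    profiles=None,
) -> RecoverySummary:
    """Rank every query of a synthetic world and score planted-target recovery."""
    if profiles is None:
        profiles = functional_profile_matrix(world.net, world.space, kernel=kernel)
    n_genes = world.net.number_of_nodes()
    cutoff = max(1, int((1 - percentile) * n_genes))
    recoveries = []
    all_in_top = []
    for q in world.queries:
        r = rank_targets(
            q.fingerprint,
            world.space,
            world.net,
            query_id=q.compound_id,
            kernel=kernel,
            method=method,
            profiles=profiles,
        )
        recoveries.append(recovery_at_top(r, q.true_targets, top_fraction))
        ranks = {g: i + 1 for i, g in enumerate(r.genes)}
        all_in_top.append(all(ranks[t] <= cutoff for t in q.true_targets))
    return RecoverySummary(
        n_queries=len(world.queries),
        percentile=percentile,
        top_percentile_rate=float(np.mean(all_in_top)),
        top_fraction=top_fraction,
        mean_recovery=float(np.mean(recoveries)),
        per_query_recovery=tuple(recoveries),
        per_query_all_in_top=tuple(all_in_top),
    )


def null_recovery(
    world,
    fingerprints,
    top_fraction: float = 0.01,
    kernel: str = "gauss",
    method: str = "pearson",
    profiles=None,
):
    """Recovery of the world's planted truths under unrelated fingerprints.

    Pairs each null fingerprint with the corresponding query's truth set
    and returns the per-query recovery fractions; with fingerprints drawn
    independently of the drug space these should scatter around
    ``top_fraction``.
    """
    if profiles is None:
        profiles = functional_profile_matrix(world.net, world.space, kernel=kernel)
    out = []
    for q, fp in zip(world.queries, fingerprints):
        r = rank_targets(
            fp,
            world.space,
            world.net,
            query_id=f"null:{q.compound_id}",
            kernel=kernel,
            method=method,
            profiles=profiles,
        )
        out.append(recovery_at_top(r, q.true_targets, top_fraction))
    return tuple(out)
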