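"""End-to-end orchestration: profiling, ranking, pooling, enrichment, depletion.

``run_pipeline`` reproduces the full analysis structure: per-compound
genome-wide rankings, pooled candidate-target sets at two selection
fractions (defaults 0.1% and 1%), enrichment of each pooled set against a
known drug-target set (ATC class filter) and against gene-set collections
(with coverage), and hub-depletion tests (degree and betweenness, top-5%
hubs) — all written as TSV tables that are recomputable from the emitted
per-compound files.

Also houses the echocardiographic fractional-shortening utility used when
relating predictions to cardiac-function readouts.
"""

from __future__ import annotations

import logging
import sys
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as npio
from .enrichment import GeneSet, enrich_gene_sets, hub_depletion, known_targets_by_atc
from .fingerprints import compute_fingerprint
from .network import functional_profile_matrix, load_network
from .prediction import (
    mean_compounds_per_target,
    pool_targets,
    rank_targets,
    select_top_percent,
)

logger = logging.getLogger("netpharm")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "fs_percent"]


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    compounds_path: str
    drug_space_path: str
    network_path: str
    gene_set_paths: tuple = ()
    top_fractions: tuple = (0.001, 0.01)
    hub_fraction: float = 0.05
    kernel: str = "gauss"
    correlation: str = "pearson"
    alpha: float = 0.05
    atc_prefix: str = "C"
    seed: int = 0
    output_dir: str = "netpharm_out"

    def __post_init__(self):
        for f in self.top_fractions:
            if not 0 < f < 1:
                raise ValueError(f"top fraction {f} not in (0, 1)")
        if not 0 < self.hub_fraction < 1:
            raise ValueError("hub_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data["top_fractions"] = tuple(data.get("top_fractions", (0.001, 0.01)))
        data["gene_set_paths"] = tuple(data.get("gene_set_paths", ()))
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["top_fractions"] = list(self.top_fractions)
        data["gene_set_paths"] = list(self.gene_set_paths)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunReport:
    """In-memory handles to everything a run computed and wrote."""

    config: PipelineConfig
    n_compounds_ranked: int
    n_compounds_skipped: int
    ranking_paths: dict
    pooled: dict          # fraction -> PooledTargets
    mean_per_target: dict  # fraction -> float
    known_target_enrichment: dict   # fraction -> EnrichmentResult
    gene_set_tables: dict  # (collection name, fraction) -> DataFrame
    hub_table: pd.DataFrame
    log_path: str


def _enrichment_frame(results, alpha: float) -> pd.DataFrame:
    rows = [
        {
            "set_id": r.set_id,
            "name": r.name,
            "universe_N": r.universe_N,
            "set_K": r.set_K,
            "sample_n": r.sample_n,
            "overlap_k": r.overlap_k,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "coverage": f"{r.coverage:.4f}",
            "significant": r.p_value < alpha,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _compound_fingerprints(compounds):
    """Resolve each compound to a fingerprint; skip unusable ones with a log."""
    usable, skipped = [], []
    for c in compounds:
        fp = c.fingerprint
        if fp is None and c.structure:
            try:
                fp = compute_fingerprint(c.structure)
            except (ValueError, RuntimeError) as exc:
                logger.warning("compound %s skipped: %s", c.compound_id, exc)
                skipped.append(c.compound_id)
                continue
        if not fp:
            logger.warning(
                "compound %s skipped: no structure and no precomputed features",
                c.compound_id,
            )
            skipped.append(c.compound_id)
            continue
        usable.append((c.compound_id, frozenset(fp)))
    return usable, skipped


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write the report tables under ``output_dir``.

    Deterministic given the configuration: profile matrices are computed
    once per (drug space, network) and all orderings are tie-broken by
    identifier.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info(
            "netpharm %s | python %s | seed %d",
            __version__,
            sys.version.split()[0],
            config.seed,
        )
        net = load_network(config.network_path)
        rep = net.graph["load_report"]
        logger.info(
            "network: %d nodes, %d edges (%d self-loops and %d duplicate edges "
            "dropped; %d component(s), sizes %s)",
            rep.n_nodes,
            rep.n_edges,
            rep.n_self_loops_dropped,
            rep.n_duplicate_edges_dropped,
            rep.n_components,
            list(rep.component_sizes[:5]),
        )
        space = npio.read_drug_space(config.drug_space_path)
        logger.info("drug space: %d drugs", len(space))
        compounds = npio.read_compounds(config.compounds_path)
        usable, skipped = _compound_fingerprints(compounds)
        logger.info(
            "compounds: %d usable, %d skipped (no usable structure/features)",
            len(usable),
            len(skipped),
        )
        if not usable:
            raise RuntimeError("stage ranking: no usable compounds")

        profiles = functional_profile_matrix(net, space, kernel=config.kernel)

        rankings = []
        ranking_paths = {}
        rank_dir = outdir / "rankings"
        rank_dir.mkdir(exist_ok=True)
        for cid, fp in usable:
            r = rank_targets(
                fp,
                space,
                net,
                query_id=cid,
                kernel=config.kernel,
                method=config.correlation,
                profiles=profiles,
            )
            rankings.append(r)
            path = rank_dir / f"{cid}.tsv"
            npio.write_ranking(r, path)
            ranking_paths[cid] = str(path)

        pooled, mean_per_target, known_enr = {}, {}, {}
        universe_nodes = frozenset(net.nodes)
        known = known_targets_by_atc(space, config.atc_prefix) & universe_nodes
        gene_set_tables = {}
        collections = {
            Path(p).stem: npio.read_gmt(p) for p in config.gene_set_paths
        }
        for frac in config.top_fractions:
            p = pool_targets(rankings, frac)
            pooled[frac] = p
            mean_per_target[frac] = mean_compounds_per_target(p)
            npio.write_pooled(p, outdir / f"pooled_top{frac:g}.tsv")
            logger.info(
                "top %.3g%%: %d pooled target genes, mean %.2f compounds/target",
                100 * frac,
                len(p),
                mean_per_target[frac],
            )
            if known:
                res = enrich_gene_sets(
                    p.genes,
                    [
                        GeneSet(
                            set_id=f"ATC_{config.atc_prefix}",
                            name=f"known targets of ATC '{config.atc_prefix}' drugs",
                            members=known,
                        )
                    ],
                    universe_nodes,
                    tail="upper",
                )[0]
                known_enr[frac] = res
                logger.info(
                    "known-target enrichment at top %.3g%%: p = %.3g",
                    100 * frac,
                    res.p_value,
                )
            for name, coll in collections.items():
                members_union = frozenset().union(*(gs.members for gs in coll))
                universe = universe_nodes & members_union
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    results = enrich_gene_sets(p.genes, coll, universe, tail="upper")
                frame = _enrichment_frame(results, config.alpha)
                frame.to_csv(
                    outdir / f"enrichment_{name}_top{frac:g}.tsv", sep="\t", index=False
                )
                gene_set_tables[(name, frac)] = frame

        hub_rows = []
        for metric in ("degree", "betweenness"):
            for frac in config.top_fractions:
                res = hub_depletion(
                    pooled[frac].genes, net, metric=metric, hub_fraction=config.hub_fraction
                )
                hub_rows.append(
                    {
                        "metric": metric,
                        "top_fraction": frac,
                        "universe_N": res.universe_N,
                        "hub_K": res.set_K,
                        "sample_n": res.sample_n,
                        "overlap_k": res.overlap_k,
                        "lower_p": res.p_value,
                        "significant": res.p_value < config.alpha,
                    }
                )
        hub_table = pd.DataFrame(hub_rows)
        hub_table.to_csv(outdir / "hub_depletion.tsv", sep="\t", index=False)
        config.to_yaml(outdir / "config.yaml")
        logger.info("report written to %s", outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()

    return RunReport(
        config=config,
        n_compounds_ranked=len(usable),
        n_compounds_skipped=len(skipped),
        ranking_paths=ranking_paths,
        pooled=pooled,
        mean_per_target=mean_per_target,
        known_target_enrichment=known_enr,
        gene_set_tables=gene_set_tables,
        hub_table=hub_table,
        log_path=str(log_path),
    )


def fs_percent(lvedd: float, lveds: float) -> float:
    """Left-ventricular fractional shortening, in percent.

    FS% = 100 * (LVEDd - LVEDs) / LVEDd, from end-diastolic and
    end-systolic diameters (mm).  A systolic diameter exceeding the
    diastolic one is physically impossible and raises instead of
    returning a negative shortening.
    """
    if lvedd <= 0:
        raise ValueError("LVEDd must be positive")
    if lveds < 0:
        raise ValueError("LVEDs must be non-negative")
    if lveds > lvedd:
        raise ValueError(
            f"LVEDs ({lveds}) exceeds LVEDd ({lvedd}): negative shortening"
        )
    return 100.0 * (lvedd - lveds) / lvedd
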