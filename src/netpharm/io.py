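"""Readers and writers for the package's plain-text interchange formats.

* drug space: TSV with columns ``drug_id``, ``features`` (";"-separated
  tokens), ``targets`` (","-separated gene ids), ``atc`` (","-separated,
  optional);
* compounds: TSV with columns ``id`` and at least one of ``structure``
  (SMILES) or ``features``;
* gene sets: GMT (set_id TAB description TAB member...);
* rankings and pooled tables: TSV mirrors of the in-memory records.

Synthetic worlds emit exactly these formats, so synthetic and real runs
share one code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .enrichment import GeneSet
from .space import DrugRecord, DrugSpace

FEATURE_SEP = ";"
LIST_SEP = ","

__all__ = [
    "Compound",
    "read_drug_space",
    "write_drug_space",
    "read_compounds",
    "write_compounds",
    "read_gmt",
    "write_gmt",
    "write_ranking",
    "write_pooled",
]


@dataclass(frozen=True)
class Compound:
    """A query compound: id plus a structure string and/or feature set."""

    compound_id: str
    structure: str | None = None
    fingerprint: frozenset | None = None


def _split(cell, sep):
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(tok for tok in str(cell).split(sep) if tok)


def read_drug_space(path) -> DrugSpace:
    """Load a reference drug space from TSV (order preserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"drug_id", "features", "targets"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing drug-space columns {sorted(missing)}")
    drugs = []
    for row in df.itertuples(index=False):
        drugs.append(
            DrugRecord(
                drug_id=row.drug_id,
                fingerprint=frozenset(_split(row.features, FEATURE_SEP)),
                targets=frozenset(_split(row.targets, LIST_SEP)),
                atc_codes=_split(getattr(row, "atc", None), LIST_SEP),
            )
        )
    return DrugSpace(drugs)


def write_drug_space(space: DrugSpace, path) -> None:
    rows = [
        {
            "drug_id": d.drug_id,
            "features": FEATURE_SEP.join(sorted(d.fingerprint)),
            "targets": LIST_SEP.join(sorted(d.targets)),
            "atc": LIST_SEP.join(d.atc_codes),
        }
        for d in space
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_compounds(path) -> list:
    """Load query compounds from TSV; structure and features both optional."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "id" not in df.columns:
        raise ValueError(f"{path}: compounds file needs an 'id' column")
    out = []
    for row in df.itertuples(index=False):
        structure = getattr(row, "structure", None)
        if isinstance(structure, float):  # NaN from pandas
            structure = None
        feats = _split(getattr(row, "features", None), FEATURE_SEP)
        out.append(
            Compound(
                compound_id=row.id,
                structure=structure or None,
                fingerprint=frozenset(feats) if feats else None,
            )
        )
    return out


def write_compounds(compounds, path) -> None:
    rows = [
        {
            "id": c.compound_id,
            "structure": c.structure or "",
            "features": FEATURE_SEP.join(sorted(c.fingerprint or ())),
        }
        for c in compounds
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list:
    """Parse a GMT gene-set collection (set_id TAB description TAB members)."""
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need id, description "
                    f"and at least one member"
                )
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                warnings.warn(f"{path}: line {lineno}: empty gene set skipped")
                continue
            sets.append(GeneSet(set_id=fields[0], name=fields[1] or fields[0], members=members))
    return sets


def write_gmt(collection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def write_ranking(ranking, path) -> None:
    """Write one compound's ranking as TSV: gene_id, score, rank."""
    rows = [
        {"gene_id": g, "score": "" if s != s else f"{s:.6f}", "rank": r}
        for g, s, r in ranking.entries()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pooled(pooled, path) -> None:
    """Write a pooled-target table as TSV: gene_id, n_compounds."""
    rows = [
        {"gene_id": g, "n_compounds": pooled.counts[g]}
        for g in sorted(pooled.counts)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
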