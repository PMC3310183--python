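"""The reference drug space: ordered drugs with fingerprints and known targets.

Every profile vector in the package (structure-similarity profiles of query
compounds, functional-similarity profiles of candidate genes) is indexed by
the drug space's fixed order, so the order is frozen at construction.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field


@dataclass(frozen=True)
class DrugRecord:
    """One reference drug: id, fingerprint, known target genes, ATC codes."""

    drug_id: str
    fingerprint: frozenset
    targets: frozenset = frozenset()
    atc_codes: tuple = ()


class DrugSpace(Sequence):
    """Ordered, immutable collection of :class:`DrugRecord`.

    Drugs with zero in-network targets are retained; their functional
    profile column is simply zero.  ``meta`` carries generator provenance
    (e.g. the synthetic feature universe) and is not otherwise interpreted.
    """

    def __init__(self, drugs: Iterable[DrugRecord], meta: dict | None = None):
        drugs = tuple(drugs)
        ids = [d.drug_id for d in drugs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate drug ids: {dupes}")
        self._drugs = drugs
        self._index = {d.drug_id: i for i, d in enumerate(drugs)}
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self._drugs)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return DrugSpace(self._drugs[i], meta=self.meta)
        return self._drugs[i]

    def __iter__(self):
        return iter(self._drugs)

    @property
    def ids(self) -> tuple:
        return tuple(d.drug_id for d in self._drugs)

    def index_of(self, drug_id: str) -> int:
        return self._index[drug_id]

    def get(self, drug_id: str) -> DrugRecord:
        return self._drugs[self._index[drug_id]]

    def all_features(self) -> frozenset:
        out: set = set()
        for d in self._drugs:
            out |= d.fingerprint
        return frozenset(out)

    def all_targets(self) -> frozenset:
        out: set = set()
        for d in self._drugs:
            out |= d.targets
        return frozenset(out)

    def __repr__(self) -> str:
        return f"DrugSpace({len(self)} drugs)"
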