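"""Atom-environment fingerprints and Tanimoto set similarity.

A fingerprint is a plain set of opaque feature identifiers.  For real
molecules the features are circular atom environments (radius 0-2 around
every heavy atom, atoms typed by element and heavy-atom degree), in the
spirit of the MOLPRINT-2D descriptor family; for synthetic benchmark data
they are arbitrary tokens.  Downstream code consumes only set overlap, so
the two are interchangeable.
"""

from __future__ import annotations

from collections.abc import Collection, Set
from typing import Union

import numpy as np

#: A fingerprint is any set of hashable feature identifiers.
Fingerprint = frozenset

__all__ = ["Fingerprint", "compute_fingerprint", "tanimoto", "structure_profile"]


def compute_fingerprint(structure: str, max_radius: int = 2) -> frozenset:
    """Compute the atom-environment fingerprint of a molecule.

    Parameters
    ----------
    structure
        A SMILES string.
    max_radius
        Largest bond-topological radius of the environments (default 2).

    Returns
    -------
    frozenset of str
        One feature per distinct (atom, radius) environment.  An atom's
        radius-r feature is its own type followed by the sorted types of
        all atoms at each shell distance 1..r; empty shells are skipped,
        so a lone heavy atom (e.g. methane) yields a single feature.

    Raises
    ------
    RuntimeError
        If RDKit is not installed; fingerprints must then be supplied
        precomputed.
    ValueError
        If the structure string does not parse.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdmolops
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RuntimeError(
            "structure parsing requires RDKit; "
            "fingerprints must be supplied precomputed"
        ) from exc

    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparsable structure: {structure!r}")

    n = mol.GetNumAtoms()
    if n == 0:
        return frozenset()
    dmat = rdmolops.GetDistanceMatrix(mol)

    def atom_type(idx: int) -> str:
        a = mol.GetAtomWithIdx(idx)
        return f"{a.GetSymbol()}{a.GetDegree()}"

    features: set[str] = set()
    for i in range(n):
        env = atom_type(i)
        features.add(env)
        for r in range(1, max_radius + 1):
            shell = sorted(
                atom_type(j) for j in range(n) if j != i and dmat[i, j] == r
            )
            if not shell:
                continue  # empty shell adds no information
            env = env + "|" + ",".join(shell)
            features.add(env)
    return frozenset(features)


def tanimoto(a: Set, b: Set) -> float:
    """Tanimoto (Jaccard) coefficient |a∩b| / |a∪b| of two feature sets.

    Two empty sets score 0 by convention: an empty fingerprint carries no
    evidence of similarity.
    """
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def structure_profile(query: Set, space: "Collection") -> np.ndarray:
    """Similarity profile of a query fingerprint over a drug space.

    Returns a float array of Tanimoto similarities, one per drug, in the
    drug space's fixed order.  ``space`` is a :class:`~netpharm.space.DrugSpace`
    (or any sequence of records with a ``fingerprint`` attribute).
    """
    if len(space) == 0:
        raise ValueError("drug space is empty")
    return np.array([tanimoto(query, d.fingerprint) for d in space], dtype=float)
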