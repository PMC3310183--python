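"""Atom-environment fingerprints and Tanimoto similarity of small molecules.

Builds fingerprints for a few molecules (SMILES) and prints pairwise
Tanimoto similarities: 1.0 means identical feature sets, 0.0 no shared
substructure environments.
"""

from netpharm import compute_fingerprint, tanimoto

molecules = {
    "ethanol": "CCO",
    "ethylamine": "CCN",
    "phenol": "c1ccccc1O",
    "aniline": "c1ccccc1N",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
}

fps = {name: compute_fingerprint(smi) for name, smi in molecules.items()}
for name, fp in fps.items():
    print(f"{name:12s} {len(fp):3d} features")

print("\npairwise Tanimoto (shared environments / union):")
names = list(molecules)
for i, a in enumerate(names):
    for b in names[i + 1:]:
        print(f"  {a:12s} vs {b:12s} {tanimoto(fps[a], fps[b]):.3f}")
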