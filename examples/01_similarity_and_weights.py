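"""Fingerprints, Tanimoto similarity and formula weights for a few standards.

Builds Compound objects from SMILES for five reference standards used to
calibrate the analysis, computes their 2048-bit circular fingerprints,
prints the pairwise Tanimoto coefficients and the conventional average
formula weights.
"""

from itertools import combinations

from bilayernet import Compound, compute_fingerprint, compute_molecular_weight, tanimoto

STANDARDS = {
    "baicalein": "C1=CC=C(C=C1)C2=CC(=O)C3=C(C(=C(C=C3O2)O)O)O",
    "luteolin": "C1=CC(=C(C=C1C2=CC(=O)C3=C(C=C(C=C3O2)O)O)O)O",
    "senkyunolide I": "CCCC=C1OC(=O)C2=C1CCC(O)C2O",
    "benzene": "c1ccccc1",
    "n-hexane": "CCCCCC",
}

compounds = [Compound(id=name, smiles=smi) for name, smi in STANDARDS.items()]
for c in compounds:
    compute_fingerprint(c)
    print(f"{c.id:16s} MW = {compute_molecular_weight(c):7.2f} g/mol")

print("\nPairwise Tanimoto coefficients (1.0 = identical bit sets;")
print("pairs at Tc >= 0.8 would share an edge in the CS network):")
for a, b in combinations(compounds, 2):
    print(f"  {a.id:16s} vs {b.id:16s}  Tc = {tanimoto(a.fingerprint, b.fingerprint):.3f}")
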