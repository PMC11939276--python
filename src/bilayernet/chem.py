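"""Compound structures, fingerprints and Tanimoto similarity.

This module owns the chemistry end of the bilayer analysis: parsing SMILES
or SDF records into :class:`Compound` objects, computing circular
fingerprints, pairwise Tanimoto coefficients, and the thresholded
similarity edge list that seeds the compound-similarity (CS) network.

Molecular weights are average (conventional) formula weights summed from an
explicit atomic-mass table so that printed reference values for common
natural products are reproduced to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import InputError

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")  # parse errors are reported by us, with line numbers

#: Conventional (2005 IUPAC) average atomic masses, g/mol.  Kept explicit so
#: formula weights match the values printed in vendor catalogues and papers,
#: which predate the most recent IUPAC revision.
ATOMIC_MASS = {
    "H": 1.00794, "B": 10.811, "C": 12.0107, "N": 14.0067, "O": 15.9994,
    "F": 18.9984032, "Na": 22.98976928, "Mg": 24.3050, "Si": 28.0855,
    "P": 30.973762, "S": 32.065, "Cl": 35.453, "K": 39.0983, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Se": 78.96, "Br": 79.904, "I": 126.90447,
}

FINGERPRINT_KINDS = ("morgan", "rdkit")


@dataclass
class Compound:
    """A chemical entity in the compound layer.

    ``fingerprint`` is a dense 0/1 ``uint8`` vector; in synthetic mode it is
    generated directly and ``smiles`` stays ``None``.
    """

    id: str
    name: str = ""
    smiles: str | None = None
    fingerprint: np.ndarray | None = None
    formula_weight: float | None = None
    mol: object = field(default=None, repr=False, compare=False)


class SimilarityEdge(NamedTuple):
    a: str
    b: str
    tc: float


def _mol_from_smiles(smiles: str):
    return Chem.MolFromSmiles(smiles)


def parse_structures(path: str | Path, fmt: str | None = None,
                     id_prop: str = "_Name") -> list[Compound]:
    """Read compounds from a SMILES list or an SDF file.

    SMILES dialect: one ``SMILES<TAB>id[<TAB>name]`` record per line
    (whitespace-separated also accepted); ``#`` lines are comments.  For SDF,
    ids come from ``id_prop`` (default: the molecule title).  Invalid records
    are logged with their position and skipped; zero valid records is fatal.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"structure file not found: {path}")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() == ".sdf" else "smiles"

    compounds: list[Compound] = []
    n_skipped = 0
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                log.warning("%s: record %d unparseable, skipped", path, i + 1)
                n_skipped += 1
                continue
            if id_prop == "_Name":
                cid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            else:
                cid = mol.GetProp(id_prop) if mol.HasProp(id_prop) else ""
            if not cid:
                log.warning("%s: record %d has no id (%s), skipped", path, i + 1, id_prop)
                n_skipped += 1
                continue
            compounds.append(Compound(id=cid, name=cid,
                                      smiles=Chem.MolToSmiles(mol), mol=mol))
    elif fmt == "smiles":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 2:
                    log.warning("%s:%d: missing id field, skipped", path, lineno)
                    n_skipped += 1
                    continue
                smi, cid = parts[0], parts[1]
                name = parts[2] if len(parts) > 2 else cid
                mol = _mol_from_smiles(smi)
                if mol is None:
                    log.warning("%s:%d: invalid SMILES %r, skipped", path, lineno, smi)
                    n_skipped += 1
                    continue
                # canonicalize so input dialects cannot change downstream results
                compounds.append(Compound(id=cid, name=name,
                                          smiles=Chem.MolToSmiles(mol), mol=mol))
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'smiles' or 'sdf')")

    if n_skipped:
        log.info("%s: skipped %d invalid record(s)", path, n_skipped)
    if not compounds:
        raise InputError(f"{path}: zero valid records")
    seen: set[str] = set()
    for c in compounds:
        if c.id in seen:
            raise InputError(f"{path}: duplicate compound id {c.id!r}")
        seen.add(c.id)
    return compounds


def compute_fingerprint(compound: Compound, fp_length: int = 2048,
                        fp_kind: str = "morgan", radius: int = 2) -> np.ndarray:
    """Compute a binary fingerprint and store it on the compound.

    Default is the 2048-bit circular (Morgan/ECFP4-like) fingerprint of
    radius 2, the standard choice for Tanimoto structural similarity.
    Deterministic for a fixed canonical structure and configuration.
    """
    if fp_kind not in FINGERPRINT_KINDS:
        raise ValueError(f"fp_kind must be one of {FINGERPRINT_KINDS}")
    mol = compound.mol
    if mol is None:
        if compound.smiles is None:
            raise InputError(
                f"compound {compound.id!r} has no structure; fingerprints require "
                "SMILES/SDF input (synthetic mode supplies fingerprints directly)")
        mol = _mol_from_smiles(compound.smiles)
        if mol is None:
            raise InputError(f"compound {compound.id!r}: unparseable SMILES")
        compound.mol = mol
    if fp_kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=fp_length)
    else:
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=fp_length)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(fp_length, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    compound.fingerprint = arr
    return arr


def tanimoto(fa: Sequence[int] | np.ndarray, fb: Sequence[int] | np.ndarray) -> float:
    """Tanimoto coefficient |fa AND fb| / |fa OR fb| of two 0/1 vectors.

    Two all-zero vectors are defined to have Tc = 0 (with a warning):
    featureless structures must never form similarity edges.
    """
    a = np.asarray(fa, dtype=bool)
    b = np.asarray(fb, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        log.warning("tanimoto of two all-zero fingerprints; returning 0.0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(fingerprints: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto matrix for an (n, L) 0/1 fingerprint matrix.

    Uses a float64 matmul for the intersection counts (bit counts are
    integers, so the result is exact); diagonal is 1 for any nonzero row,
    0 for all-zero rows (matching :func:`tanimoto`).
    """
    F = np.asarray(fingerprints, dtype=np.float64)
    inter = F @ F.T
    row = F.sum(axis=1)
    union = row[:, None] + row[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1e-9), 0.0)
    return tc


#: above this many compounds the O(n^2) pair scan gets noticeably slow
PAIR_SCAN_WARN_N = 20_000


def build_similarity_edges(compounds: Iterable[Compound],
                           threshold: float = 0.8) -> list[SimilarityEdge]:
    """All unordered compound pairs with Tanimoto >= ``threshold``.

    Each edge is stored once with ``a < b`` in input order; all O(n^2) pairs
    are scanned (vectorised), with a warning above ``PAIR_SCAN_WARN_N``.
    """
    comps = list(compounds)
    if not comps:
        return []
    if any(c.fingerprint is None for c in comps):
        raise InputError("fingerprints must be computed before building edges")
    if len(comps) > PAIR_SCAN_WARN_N:
        log.warning("similarity scan over %d compounds: %d pairs",
                    len(comps), len(comps) * (len(comps) - 1) // 2)
    F = np.stack([c.fingerprint for c in comps]).astype(np.uint8)
    tc = tanimoto_matrix(F)
    ii, jj = np.where(np.triu(tc >= threshold, k=1))
    return [SimilarityEdge(comps[i].id, comps[j].id, float(tc[i, j]))
            for i, j in zip(ii.tolist(), jj.tolist())]


def compute_molecular_weight(compound: Compound) -> float:
    """Average formula weight in g/mol, rounded half-up to 2 decimals.

    Sums conventional average atomic masses over all atoms including
    implicit hydrogens; the result is stored on ``compound.formula_weight``.
    """
    mol = compound.mol
    if mol is None:
        if compound.smiles is None:
            raise InputError(f"compound {compound.id!r} has no structure")
        mol = _mol_from_smiles(compound.smiles)
        if mol is None:
            raise InputError(f"compound {compound.id!r}: unparseable SMILES")
        compound.mol = mol
    pt = Chem.GetPeriodicTable()
    total = 0.0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        total += ATOMIC_MASS.get(sym, pt.GetAtomicWeight(sym))
        total += atom.GetTotalNumHs() * ATOMIC_MASS["H"]
    mw = float(Decimal(repr(total)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    compound.formula_weight = mw
    return mw


def write_edge_tsv(edges: Iterable[SimilarityEdge], path: str | Path) -> int:
    """Write the edge list as ``a<TAB>b<TAB>tc`` with 4-decimal tc."""
    n = 0
    with open(path, "w") as fh:
        fh.write("a\tb\ttc\n")
        for e in edges:
            fh.write(f"{e.a}\t{e.b}\t{e.tc:.4f}\n")
            n += 1
    return n
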