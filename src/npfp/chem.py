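"""Molecule parsing, canonicalization and featurization.

Structural featurization is the 2048-bit ECFP4 (Morgan radius-2 hashed
circular fingerprint), the representation the decoy search, the network
inputs and the classical similarity baseline all share.  Auxiliary
regression targets are a 48-dimensional vector of 2D surface descriptors
(VSA partitions of LogP, molar refractivity, partial charge and E-state,
plus TPSA).  Two similarity measures are provided: Tanimoto on bit
fingerprints and cosine on dense real vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .errors import (
    DescriptorError,
    LengthMismatchError,
    ParseError,
    ZeroVectorError,
)
from .records import MoleculeRecord

RDLogger.DisableLog("rdApp.*")

#: Default surface-descriptor set: the full VSA families (SlogP 12, SMR 10,
#: PEOE 14, EState 11) plus TPSA — exactly 48 descriptors, all 2D-computable.
#: This is a synthetic stand-in list assembled for this package; it can be
#: overridden wherever a ``descriptor_set`` argument is accepted.
DEFAULT_SURFACE_DESCRIPTORS: tuple[str, ...] = tuple(
    [f"SlogP_VSA{i}" for i in range(1, 13)]
    + [f"SMR_VSA{i}" for i in range(1, 11)]
    + [f"PEOE_VSA{i}" for i in range(1, 15)]
    + [f"EState_VSA{i}" for i in range(1, 12)]
    + ["TPSA"]
)

_DESCRIPTOR_FUNCS = dict(Descriptors.descList)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising :class:`ParseError` on failure."""
    if not smiles or not isinstance(smiles, str):
        raise ParseError(f"not a SMILES string: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse SMILES {smiles!r}")
    return mol


def canonicalize(smiles: str, strip_stereo: bool = False) -> str:
    """Return the unique canonical SMILES of a molecule.

    Identical molecules map to identical strings regardless of atom order
    or aromaticity notation.  With ``strip_stereo`` the stereo annotations
    are removed first — used when preparing synthetic screening libraries,
    whose stereo assignments are often unreliable.
    """
    mol = mol_from_smiles(smiles)
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary structural fingerprint (default ECFP4/2048)."""

    bits: np.ndarray  # uint8 0/1 vector
    length: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.shape[0] != self.length:
            raise ValueError("bits must be a 1-D vector of the stated length")
        object.__setattr__(self, "bits", bits)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def __eq__(self, other) -> bool:  # array field needs explicit eq
        return (
            isinstance(other, BitFingerprint)
            and self.length == other.length
            and self.radius == other.radius
            and bool(np.array_equal(self.bits, other.bits))
        )

    def __hash__(self) -> int:
        return hash((self.length, self.radius, self.bits.tobytes()))


def ecfp4(record: MoleculeRecord | str, length: int = 2048,
          radius: int = 2) -> BitFingerprint:
    """Hashed Morgan circular fingerprint (radius 2 = ECFP4) as a bit vector."""
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = mol_from_smiles(smiles)
    gen = _morgan_generator(radius, length)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(length, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return BitFingerprint(bits=arr, length=length, radius=radius)


_GENERATOR_CACHE: dict[tuple[int, int], object] = {}


def _morgan_generator(radius: int, length: int):
    key = (radius, length)
    if key not in _GENERATOR_CACHE:
        _GENERATOR_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=length
        )
    return _GENERATOR_CACHE[key]


def ecfp4_matrix(records: Sequence[MoleculeRecord], length: int = 2048,
                 radius: int = 2) -> np.ndarray:
    """Stack ECFP4 fingerprints of many molecules into an (n, length) array."""
    out = np.zeros((len(records), length), dtype=np.uint8)
    gen = _morgan_generator(radius, length)
    for i, rec in enumerate(records):
        mol = mol_from_smiles(rec.smiles)
        out[i, list(gen.GetFingerprint(mol).GetOnBits())] = 1
    return out


@dataclass(frozen=True)
class DescriptorVector:
    """Ordered real-valued descriptor vector with its descriptor names."""

    values: np.ndarray
    names: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(self.names),):
            raise ValueError("values and names must have equal length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))


def surface_descriptors(
    record: MoleculeRecord | str,
    descriptor_set: Sequence[str] = DEFAULT_SURFACE_DESCRIPTORS,
) -> DescriptorVector:
    """Compute 2D surface descriptors in the order of ``descriptor_set``.

    Non-finite values are left in place here; imputation against the
    fitting-set column median happens in :func:`descriptor_matrix`, where
    the fitting population is known.
    """
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = mol_from_smiles(smiles)
    values = np.empty(len(descriptor_set), dtype=np.float64)
    for i, name in enumerate(descriptor_set):
        func = _DESCRIPTOR_FUNCS.get(name)
        if func is None:
            raise DescriptorError(f"unknown descriptor {name!r}")
        try:
            values[i] = float(func(mol))
        except Exception as exc:  # descriptor backends raise many types
            raise DescriptorError(f"descriptor {name!r} failed: {exc}") from exc
    return DescriptorVector(values=values, names=tuple(descriptor_set))


def descriptor_matrix(
    records: Sequence[MoleculeRecord],
    descriptor_set: Sequence[str] = DEFAULT_SURFACE_DESCRIPTORS,
) -> np.ndarray:
    """Descriptor vectors for many molecules, NaN/inf imputed column-wise.

    Non-finite entries are replaced by the column median over the finite
    entries of this record set, which keeps every molecule usable as a
    regression target.  A column with no finite entry becomes all-zero.
    """
    mat = np.empty((len(records), len(descriptor_set)), dtype=np.float64)
    for i, rec in enumerate(records):
        mat[i] = surface_descriptors(rec, descriptor_set).values
    for j in range(mat.shape[1]):
        col = mat[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            finite = col[~bad]
            col[bad] = np.median(finite) if finite.size else 0.0
    return mat


def tanimoto(a: BitFingerprint, b: BitFingerprint,
             empty_value: float = 1.0) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two bit fingerprints.

    Two all-zero fingerprints are defined as identical patterns and score
    ``empty_value`` (default 1.0).
    """
    if a.length != b.length:
        raise LengthMismatchError(
            f"fingerprint lengths differ: {a.length} vs {b.length}")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return empty_value
    return inter / union


def tanimoto_matrix(query_bits: np.ndarray, library_bits: np.ndarray) -> np.ndarray:
    """Row-wise Tanimoto of each query against each library fingerprint.

    ``query_bits`` (q, L) and ``library_bits`` (n, L) are 0/1 arrays; the
    result is (q, n).  All-zero vs all-zero pairs score 1.0.
    """
    q = np.asarray(query_bits, dtype=np.float64)
    lib = np.asarray(library_bits, dtype=np.float64)
    inter = q @ lib.T
    pop_q = q.sum(axis=1, keepdims=True)
    pop_l = lib.sum(axis=1, keepdims=True).T
    union = pop_q + pop_l - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two dense vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise LengthMismatchError(f"vector shapes differ: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine similarity undefined for all-zero vector")
    return float(np.dot(u, v) / (nu * nv))


def cosine_matrix(queries: np.ndarray, library: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity, (q, d) x (n, d) -> (q, n)."""
    q = np.asarray(queries, dtype=np.float64)
    lib = np.asarray(library, dtype=np.float64)
    qn = np.linalg.norm(q, axis=1, keepdims=True)
    ln = np.linalg.norm(lib, axis=1, keepdims=True)
    if np.any(qn == 0) or np.any(ln == 0):
        raise ZeroVectorError("cosine similarity undefined for all-zero vector")
    return (q / qn) @ (lib / ln).T


def sp3_carbon_fraction(smiles: str) -> float:
    """Fraction of carbons that are sp3 — the rigidity/saturation contrast
    between natural-product-like and synthetic-like chemistry."""
    mol = mol_from_smiles(smiles)
    carbons = [a for a in mol.GetAtoms() if a.GetSymbol() == "C"]
    if not carbons:
        return 0.0
    sp3 = sum(1 for a in carbons
              if a.GetHybridization() == Chem.HybridizationType.SP3)
    return sp3 / len(carbons)
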