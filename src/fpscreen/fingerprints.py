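"""Molecular fingerprints as signed bit vectors.

Seven 1024-bit fingerprint types are supported (RDKit, Morgan, AtomPair,
Torsion, Layered, FeatMorgan, ECFP4).  A fingerprint is a fixed-length
binary vector: every substructure pattern found in the molecule is hashed
to a handful of bit positions which are OR-ed into the vector.  Hash
collisions mean a set bit does not prove a pattern is present, but a
pattern whose bits are all zero is certainly absent.

For classification the {0,1} vectors are recoded to {-1,+1} so that sparse
regions of the vector still carry signal into convolutional units, and
several fingerprints of one compound can be stacked into a k x 1024 matrix
(rows in the canonical type order) for two-dimensional convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.rdmolops import LayeredFingerprint as _LayeredFingerprint
from rdkit import RDLogger

_RDKIT_LOG_SILENCED = False


def _silence_rdkit() -> None:
    global _RDKIT_LOG_SILENCED
    if not _RDKIT_LOG_SILENCED:
        RDLogger.DisableLog("rdApp.error")
        _RDKIT_LOG_SILENCED = True


class FingerprintError(ValueError):
    """Base class for fingerprint-layer errors."""


class SmilesParseError(FingerprintError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class FingerprintType(Enum):
    """The seven supported fingerprint types, in canonical order.

    The enum listing order is the canonical order used wherever a row
    order is needed (matrix stacking, ensemble membership).
    """

    RDKIT = "rdkit"
    MORGAN = "morgan"
    ATOMPAIR = "atompair"
    TORSION = "torsion"
    LAYERED = "layered"
    FEATMORGAN = "featmorgan"
    ECFP4 = "ecfp4"

    @property
    def order(self) -> int:
        return _CANONICAL_ORDER[self]

    @classmethod
    def canonical(cls) -> tuple["FingerprintType", ...]:
        """All seven types in canonical order."""
        return tuple(cls)


_CANONICAL_ORDER = {t: i for i, t in enumerate(FingerprintType)}


@dataclass(frozen=True)
class BitFingerprint:
    """A 1024-bit {0,1} fingerprint of one compound."""

    bits: np.ndarray
    fp_type: FingerprintType
    compound_id: str = ""

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise FingerprintError("bits must be one-dimensional")
        if not np.isin(bits, (0, 1)).all():
            raise FingerprintError("bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    @property
    def n_bits(self) -> int:
        return self.bits.size

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class SignedFingerprint:
    """A fingerprint recoded to {-1,+1}: value = 2*bit - 1."""

    values: np.ndarray
    fp_type: FingerprintType
    compound_id: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.int8)
        if values.ndim != 1:
            raise FingerprintError("values must be one-dimensional")
        if not np.isin(values, (-1, 1)).all():
            raise FingerprintError("values must be -1/+1")
        object.__setattr__(self, "values", values)

    def to_bits(self) -> BitFingerprint:
        """Inverse recoding; lossless round trip."""
        return BitFingerprint(
            bits=((self.values + 1) // 2).astype(np.uint8),
            fp_type=self.fp_type,
            compound_id=self.compound_id,
        )


@dataclass(frozen=True)
class FingerprintMatrix:
    """k x 1024 signed matrix stacking distinct fingerprint types of one compound."""

    rows: tuple[SignedFingerprint, ...]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise FingerprintError("a fingerprint matrix needs at least 2 rows")
        types = [r.fp_type for r in self.rows]
        if len(set(types)) != len(types):
            raise FingerprintError("duplicate fingerprint type in matrix")
        ids = {r.compound_id for r in self.rows}
        if len(ids) != 1:
            raise FingerprintError(f"mixed compound ids in matrix: {sorted(ids)}")
        orders = [t.order for t in types]
        if orders != sorted(orders):
            raise FingerprintError("rows not in canonical type order")

    @property
    def compound_id(self) -> str:
        return self.rows[0].compound_id

    @property
    def fp_types(self) -> tuple[FingerprintType, ...]:
        return tuple(r.fp_type for r in self.rows)

    def to_array(self) -> np.ndarray:
        return np.stack([r.values for r in self.rows]).astype(np.int8)


# ---------------------------------------------------------------------------
# SMILES handling


def standardize_smiles(smiles: str, *, keep_largest_fragment: bool = True) -> Chem.Mol:
    """Parse and sanitize a SMILES string, optionally keeping the largest fragment.

    Salt/solvent fragments are dropped by default (largest fragment by heavy
    atom count); disable with ``keep_largest_fragment=False``.
    """
    _silence_rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if keep_largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
            Chem.SanitizeMol(mol)
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of the standardized molecule (used for deduplication)."""
    return Chem.MolToSmiles(standardize_smiles(smiles))


# ---------------------------------------------------------------------------
# Fingerprint computation


def _generator(fp_type: FingerprintType, n_bits: int):
    g = rdFingerprintGenerator
    if fp_type is FingerprintType.RDKIT:
        return g.GetRDKitFPGenerator(fpSize=n_bits)
    if fp_type is FingerprintType.MORGAN:
        return g.GetMorganGenerator(radius=2, fpSize=n_bits)
    if fp_type is FingerprintType.ATOMPAIR:
        return g.GetAtomPairGenerator(fpSize=n_bits)
    if fp_type is FingerprintType.TORSION:
        return g.GetTopologicalTorsionGenerator(fpSize=n_bits)
    if fp_type is FingerprintType.FEATMORGAN:
        return g.GetMorganGenerator(
            radius=2,
            fpSize=n_bits,
            atomInvariantsGenerator=g.GetMorganFeatureAtomInvGen(),
        )
    if fp_type is FingerprintType.ECFP4:
        # Same radius-2 circular scheme as MORGAN but with count simulation
        # and chirality switched on, so the folded bit vector differs from
        # the plain connectivity-invariant Morgan fingerprint.
        return g.GetMorganGenerator(
            radius=2,
            fpSize=n_bits,
            countSimulation=True,
            includeChirality=True,
        )
    raise FingerprintError(f"unknown fingerprint type: {fp_type!r}")


def compute_fingerprint(
    smiles: str,
    fp_type: FingerprintType,
    n_bits: int = 1024,
    *,
    compound_id: str = "",
    standardize: bool = True,
) -> BitFingerprint:
    """Compute one 1024-bit fingerprint of one molecule.

    Deterministic: identical inputs always yield identical bit vectors.

    Parameters
    ----------
    smiles : SMILES string of the molecule.
    fp_type : which of the seven fingerprint schemes to use.
    n_bits : folded vector length (default 1024; must be >= 64).
    standardize : sanitize and keep the largest fragment before hashing.
    """
    if not isinstance(fp_type, FingerprintType):
        raise FingerprintError(f"unknown fingerprint type: {fp_type!r}")
    if n_bits < 64:
        raise FingerprintError(f"n_bits must be >= 64, got {n_bits}")
    mol = standardize_smiles(smiles) if standardize else Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if fp_type is FingerprintType.LAYERED:
        ebv = _LayeredFingerprint(mol, fpSize=n_bits)
    else:
        ebv = _generator(fp_type, n_bits).GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(ebv.GetOnBits())] = 1
    return BitFingerprint(bits=bits, fp_type=fp_type, compound_id=compound_id)


def compute_all_fingerprints(
    smiles: str,
    n_bits: int = 1024,
    *,
    compound_id: str = "",
    types: Sequence[FingerprintType] | None = None,
) -> list[BitFingerprint]:
    """All requested fingerprint types for one molecule, canonical order."""
    chosen = sorted(types or FingerprintType.canonical(), key=lambda t: t.order)
    return [
        compute_fingerprint(smiles, t, n_bits, compound_id=compound_id)
        for t in chosen
    ]


def to_signed(fp: BitFingerprint) -> SignedFingerprint:
    """Recode {0,1} -> {-1,+1}.  sum(values) == 2*popcount - n_bits."""
    return SignedFingerprint(
        values=(2 * fp.bits.astype(np.int16) - 1).astype(np.int8),
        fp_type=fp.fp_type,
        compound_id=fp.compound_id,
    )


def stack(fps: Sequence[SignedFingerprint]) -> FingerprintMatrix:
    """Stack >=2 signed fingerprints of one compound into a k x 1024 matrix.

    Input order is irrelevant: rows are sorted into canonical type order.
    Duplicate types or mixed compound ids raise :class:`FingerprintError`.
    """
    if len(fps) < 2:
        raise FingerprintError("need at least 2 fingerprints to stack")
    ordered = sorted(fps, key=lambda f: f.fp_type.order)
    return FingerprintMatrix(rows=tuple(ordered))


def enumerate_combinations(
    types: Iterable[FingerprintType],
) -> list[tuple[FingerprintType, ...]]:
    """All subsets of size >= 2, each in canonical order.

    For the full seven types this yields 2^7 - 7 - 1 = 120 subsets.
    """
    uniq = sorted(set(types), key=lambda t: t.order)
    if len(uniq) < 2:
        raise FingerprintError("need at least 2 fingerprint types")
    out: list[tuple[FingerprintType, ...]] = []
    for k in range(2, len(uniq) + 1):
        out.extend(combinations(uniq, k))
    return out


# ---------------------------------------------------------------------------
# Readers


def read_smiles_file(path: str | Path) -> pd.DataFrame:
    """Read one-SMILES-per-line text (optional tab-separated id column).

    Returns a DataFrame with columns ``id`` and ``smiles``.
    """
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"cmpd{i}"
        rows.append({"id": cid, "smiles": smiles})
    return pd.DataFrame(rows, columns=["id", "smiles"])


def read_compound_csv(
    path: str | Path,
    *,
    smiles_col: str = "smiles",
    id_col: str = "id",
    ic50_col: str | None = "ic50_um",
) -> pd.DataFrame:
    """Read a compound table from CSV with configurable column names."""
    df = pd.read_csv(path)
    if smiles_col not in df.columns:
        raise FingerprintError(f"missing SMILES column {smiles_col!r} in {path}")
    out = pd.DataFrame()
    out["id"] = (
        df[id_col].astype(str)
        if id_col in df.columns
        else [f"cmpd{i}" for i in range(len(df))]
    )
    out["smiles"] = df[smiles_col].astype(str)
    if ic50_col and ic50_col in df.columns:
        out["ic50_um"] = pd.to_numeric(df[ic50_col], errors="coerce")
    return out


def read_sdf(path: str | Path, *, id_prop: str | None = None) -> pd.DataFrame:
    """Read an SDF file into an (id, smiles) DataFrame."""
    _silence_rdkit()
    rows = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        if id_prop and mol.HasProp(id_prop):
            cid = mol.GetProp(id_prop)
        elif mol.HasProp("_Name") and mol.GetProp("_Name"):
            cid = mol.GetProp("_Name")
        else:
            cid = f"cmpd{i}"
        rows.append({"id": cid, "smiles": Chem.MolToSmiles(mol)})
    return pd.DataFrame(rows, columns=["id", "smiles"])


# ---------------------------------------------------------------------------
# Writers


def write_fingerprints_csv(
    fps: Sequence[BitFingerprint | SignedFingerprint], path: str | Path
) -> None:
    """Wide CSV: id, type, then one column per bit position."""
    if not fps:
        raise FingerprintError("nothing to write")
    n = fps[0].bits.size if isinstance(fps[0], BitFingerprint) else fps[0].values.size
    cols = [f"b{i}" for i in range(n)]
    rows = []
    for fp in fps:
        vec = fp.bits if isinstance(fp, BitFingerprint) else fp.values
        rows.append([fp.compound_id, fp.fp_type.value, *vec.tolist()])
    pd.DataFrame(rows, columns=["id", "type", *cols]).to_csv(path, index=False)


def read_fingerprints_csv(path: str | Path, *, signed: bool | None = None) -> list:
    """Read fingerprints written by :func:`write_fingerprints_csv`.

    ``signed`` is inferred from the values when not given.
    """
    df = pd.read_csv(path)
    bit_cols = [c for c in df.columns if c.startswith("b")]
    out = []
    for _, row in df.iterrows():
        vec = row[bit_cols].to_numpy(dtype=np.int16)
        is_signed = signed if signed is not None else bool((vec < 0).any())
        fp_type = FingerprintType(row["type"])
        if is_signed:
            out.append(
                SignedFingerprint(values=vec.astype(np.int8), fp_type=fp_type,
                                  compound_id=str(row["id"]))
            )
        else:
            out.append(
                BitFingerprint(bits=vec.astype(np.uint8), fp_type=fp_type,
                               compound_id=str(row["id"]))
            )
    return out


def write_matrix_container(
    ids: Sequence[str],
    matrix: np.ndarray,
    fp_types: Sequence[FingerprintType],
    path: str | Path,
) -> None:
    """Compact binary container (.npy) with a JSON sidecar describing layout.

    ``matrix`` has shape (n_compounds, k_types, n_bits) or (n_compounds, n_bits).
    """
    path = Path(path)
    matrix = np.asarray(matrix, dtype=np.int8)
    np.save(path, matrix)
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    sidecar = {
        "shape": list(matrix.shape),
        "dtype": "int8",
        "encoding": "signed" if (matrix < 0).any() else "bits",
        "fp_types": [t.value for t in fp_types],
        "ids": list(map(str, ids)),
    }
    npy.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix_container(path: str | Path):
    """Read the (matrix, ids, fp_types) triple written by write_matrix_container."""
    path = Path(path)
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    matrix = np.load(npy)
    meta = json.loads(npy.with_suffix(".json").read_text())
    return matrix, meta["ids"], [FingerprintType(v) for v in meta["fp_types"]]
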