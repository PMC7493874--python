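"""Synthetic fingerprint datasets with known ground truth.

Real fingerprints hash every substructure pattern of a molecule to 4-5
bit positions and OR the results together, so collisions can fake
presence but all-zero positions prove absence.  The generator reproduces
exactly that mechanism over an abstract pattern universe: each pseudo
fingerprint type has its own hash map from pattern ids to bit positions,
compounds are random pattern sets, and active compounds additionally
carry designated active-motif patterns with probability ``q_signal``
(inactives carry them at a small ``noise_rate``).  IC50 values are drawn
from a bimodal lognormal mixture whose components straddle the activity
threshold (medians near 0.92 and 13.9 uM), so threshold fitting can be
exercised end to end.

Synthetic compounds are abstract pattern sets, not molecules: there is no
chemistry here, only the statistical structure the classifiers assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .fingerprints import BitFingerprint, FingerprintType
from .labeling import Activity, ActivityRecord


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class PatternLibrary:
    """Hash maps from pattern ids to bit positions, one map per pseudo-type.

    ``hash_maps[fp_type][pattern_id]`` is the tuple of ``bits_per_pattern``
    positions that pattern sets in that pseudo-type's fingerprint.  The
    maps use independent hash seeds, so the same pattern collides
    differently in every pseudo-type.
    """

    n_patterns: int
    n_bits: int
    bits_per_pattern: int
    hash_maps: dict[FingerprintType, tuple[tuple[int, ...], ...]]
    seed: int

    def positions(self, fp_type: FingerprintType, pattern_id: int) -> tuple[int, ...]:
        if not 0 <= pattern_id < self.n_patterns:
            raise SynthError(f"unknown pattern id {pattern_id}")
        return self.hash_maps[fp_type][pattern_id]

    def collision_count(self, fp_type: FingerprintType) -> int:
        """Number of bit positions claimed by more than one pattern."""
        counts = np.zeros(self.n_bits, dtype=int)
        for positions in self.hash_maps[fp_type]:
            counts[list(positions)] += 1
        return int((counts > 1).sum())


@dataclass
class SyntheticCompound:
    """An abstract compound: a set of pattern ids plus ground truth."""

    compound_id: str
    pattern_set: frozenset[int]
    is_active: bool
    ic50: float


@dataclass(frozen=True)
class Ic50MixtureParams:
    """Lognormal components for the bimodal IC50 distribution (uM).

    Defaults put the component medians at 0.92 and 13.9 uM with a log-sd
    small enough that under 2% of each component's mass crosses the
    mid-centroid threshold near 7.4 uM (for sigma_log 0.3 the inactive
    component puts ~1.8% of its mass below 7.414, the active component
    essentially none above it).
    """

    median_active: float = 0.92
    median_inactive: float = 13.9
    sigma_log: float = 0.3


def build_library(
    n_patterns: int,
    n_bits: int = 1024,
    bits_per_pattern: int = 4,
    n_pseudotypes: int = 7,
    seed: int = 0,
) -> PatternLibrary:
    """Draw the per-pseudo-type hash maps; collisions are expected and allowed."""
    if bits_per_pattern not in (4, 5):
        raise SynthError("bits_per_pattern must be 4 or 5")
    if n_patterns < 1:
        raise SynthError("need at least one pattern")
    if n_pseudotypes < 1 or n_pseudotypes > 7:
        raise SynthError("n_pseudotypes must be in 1..7")
    rng = np.random.default_rng(seed)
    types = FingerprintType.canonical()[:n_pseudotypes]
    hash_maps = {}
    for fp_type in types:
        rows = tuple(
            tuple(sorted(rng.choice(n_bits, size=bits_per_pattern, replace=False)))
            for _ in range(n_patterns)
        )
        hash_maps[fp_type] = rows
    return PatternLibrary(
        n_patterns=n_patterns,
        n_bits=n_bits,
        bits_per_pattern=bits_per_pattern,
        hash_maps=hash_maps,
        seed=seed,
    )


def render_fingerprint(
    compound: SyntheticCompound,
    fp_type: FingerprintType,
    library: PatternLibrary,
) -> BitFingerprint:
    """OR together the hash positions of every pattern in the compound.

    Monotone by construction: a superset of patterns can only set a
    superset of bits.
    """
    if fp_type not in library.hash_maps:
        raise SynthError(f"library has no map for {fp_type.value}")
    bits = np.zeros(library.n_bits, dtype=np.uint8)
    for pid in compound.pattern_set:
        bits[list(library.positions(fp_type, pid))] = 1
    return BitFingerprint(bits=bits, fp_type=fp_type,
                          compound_id=compound.compound_id)


@dataclass
class SyntheticDataset:
    """Compounds, their rendered fingerprints, labels and ground truth."""

    compounds: list[SyntheticCompound]
    library: PatternLibrary
    active_motifs: tuple[int, ...]
    fingerprints: dict[FingerprintType, np.ndarray]  # (n, n_bits) uint8
    records: list[ActivityRecord]
    seed: int

    @property
    def ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    @property
    def labels(self) -> np.ndarray:
        return np.array([int(c.is_active) for c in self.compounds])

    @property
    def ic50(self) -> np.ndarray:
        return np.array([c.ic50 for c in self.compounds])

    def signed(self, fp_type: FingerprintType) -> np.ndarray:
        """(n, n_bits) float32 matrix of {-1,+1} values for one pseudo-type."""
        return (2.0 * self.fingerprints[fp_type] - 1.0).astype(np.float32)

    def signed_by_type(self) -> dict[FingerprintType, np.ndarray]:
        return {t: self.signed(t) for t in self.fingerprints}

    def ground_truth_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "library_seed": self.library.seed,
            "active_motifs": list(self.active_motifs),
            "compounds": {
                c.compound_id: {
                    "patterns": sorted(c.pattern_set),
                    "is_active": c.is_active,
                    "ic50_um": c.ic50,
                }
                for c in self.compounds
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_dataset(
    n_active: int = 500,
    n_inactive: int = 5000,
    q_signal: float = 0.9,
    noise_rate: float = 0.05,
    ic50_params: Ic50MixtureParams | None = None,
    *,
    n_patterns: int = 400,
    n_motifs: int = 8,
    patterns_per_compound: tuple[int, int] = (10, 30),
    bits_per_pattern: int = 4,
    n_bits: int = 1024,
    n_pseudotypes: int = 7,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a labeled synthetic screening set with planted active motifs.

    Actives carry at least one of ``n_motifs`` designated motif patterns
    with probability ``q_signal``; a carrying active draws several motifs
    (uniformly 2..n_motifs), the way a true binder presents multiple
    pharmacophore features at once.  Inactives carry a single motif at
    ``noise_rate`` — a decoy-like partial match, never the full signature.
    Every compound also gets a random background pattern set, and each of
    the seven pseudo-types renders the same pattern sets through its own
    hash map.  IC50 values come from the lognormal component matching the
    activity flag.
    """
    if not 0.5 < q_signal <= 1.0:
        raise SynthError("q_signal must be in (0.5, 1]")
    if not 0.0 <= noise_rate <= 0.2:
        raise SynthError("noise_rate must be in [0, 0.2]")
    if n_active < 1 or n_inactive < 1:
        raise SynthError("need at least one compound per class")
    if n_motifs >= n_patterns:
        raise SynthError("n_motifs must be smaller than n_patterns")
    params = ic50_params or Ic50MixtureParams()
    rng = np.random.default_rng(seed)
    library = build_library(
        n_patterns, n_bits, bits_per_pattern, n_pseudotypes,
        seed=int(rng.integers(2**31)),
    )
    motifs = tuple(rng.choice(n_patterns, size=n_motifs, replace=False).tolist())
    background = np.setdiff1d(np.arange(n_patterns), motifs)

    compounds: list[SyntheticCompound] = []
    lo, hi = patterns_per_compound
    for i in range(n_active + n_inactive):
        is_active = i < n_active
        n_bg = int(rng.integers(lo, hi + 1))
        patterns = set(rng.choice(background, size=n_bg, replace=False).tolist())
        carry = q_signal if is_active else noise_rate
        if rng.random() < carry:
            if is_active:
                n_carry = int(rng.integers(min(2, len(motifs)), len(motifs) + 1))
            else:
                n_carry = 1
            patterns |= set(rng.choice(motifs, size=n_carry, replace=False).tolist())
        median = params.median_active if is_active else params.median_inactive
        ic50 = float(np.exp(np.log(median) + params.sigma_log * rng.standard_normal()))
        compounds.append(
            SyntheticCompound(
                compound_id=f"syn{i:05d}",
                pattern_set=frozenset(patterns),
                is_active=is_active,
                ic50=ic50,
            )
        )
    order = rng.permutation(len(compounds))
    compounds = [compounds[j] for j in order]

    fingerprints = {}
    for fp_type in library.hash_maps:
        mat = np.zeros((len(compounds), n_bits), dtype=np.uint8)
        for row, c in enumerate(compounds):
            mat[row] = render_fingerprint(c, fp_type, library).bits
        fingerprints[fp_type] = mat

    records = [
        ActivityRecord(
            compound_id=c.compound_id,
            ic50=c.ic50,
            label=Activity.ACTIVE if c.is_active else Activity.INACTIVE,
        )
        for c in compounds
    ]
    return SyntheticDataset(
        compounds=compounds,
        library=library,
        active_motifs=motifs,
        fingerprints=fingerprints,
        records=records,
        seed=seed,
    )
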