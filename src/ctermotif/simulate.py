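"""Synthetic ortholog families and decoy proteomes.

The generator emulates what a C-terminal motif pipeline actually sees:
a family of orthologous proteins whose variable bodies are i.i.d. draws
from a background composition, with a planted C-terminal motif whose
positions are fixed residues, weighted residue pools, or free positions
with excluded residues (e.g. proline). Decoy proteomes are plain i.i.d.
sequence sets for calibrating expected-hit statistics. All generators are
pure functions of (configuration, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .alphabet import AMINO_ACIDS, AA_INDEX, AA_SET
from .patterns import AnchoredPattern, Exclusion, Fixed as FixedElement, Inclusion, Wildcard
from .seqio import OrthologGroup, SequenceRecord

__all__ = [
    "FixedPos",
    "PoolPos",
    "FreePos",
    "MotifSpec",
    "FamilyConfig",
    "ddx3eq_motif_spec",
    "DEFAULT_BODY_COMPOSITION",
    "generate_family",
    "generate_decoy_proteome",
    "degrade_motif",
    "write_ground_truth",
]

_TOL = 1e-9


@dataclass(frozen=True)
class FixedPos:
    """A strictly conserved motif position."""

    residue: str

    def __post_init__(self):
        if self.residue not in AA_SET:
            raise ValueError(f"fixed position residue {self.residue!r} not in alphabet")


@dataclass(frozen=True)
class PoolPos:
    """A position drawing from a weighted residue pool (weights sum to 1)."""

    weights: Mapping[str, float]

    def __post_init__(self):
        weights = dict(self.weights)
        if not weights or not set(weights) <= AA_SET:
            raise ValueError("pool must map alphabet residues to weights")
        vals = np.array(list(weights.values()))
        if (vals <= 0).any():
            raise ValueError("pool weights must be positive")
        if abs(vals.sum() - 1.0) > _TOL:
            raise ValueError(f"pool weights sum to {vals.sum():.12f}, not 1")
        object.__setattr__(self, "weights", weights)


@dataclass(frozen=True)
class FreePos:
    """A variable position that never emits the excluded residues."""

    excluded: frozenset[str] = frozenset()

    def __post_init__(self):
        excluded = frozenset(self.excluded)
        if not excluded <= AA_SET:
            raise ValueError("excluded residues must be in the alphabet")
        if len(excluded) >= 20:
            raise ValueError("a free position must allow at least one residue")
        object.__setattr__(self, "excluded", excluded)


MotifPosition = Union[FixedPos, PoolPos, FreePos]


@dataclass(frozen=True)
class MotifSpec:
    """Per-position generative spec of a planted C-terminal motif."""

    positions: tuple[MotifPosition, ...]

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(self.positions))
        if not self.positions:
            raise ValueError("motif spec needs at least one position")

    def __len__(self) -> int:
        return len(self.positions)

    def to_pattern(self) -> AnchoredPattern:
        """The anchored pattern this spec plants (pools -> inclusion classes)."""
        elements = []
        for p in self.positions:
            if isinstance(p, FixedPos):
                elements.append(FixedElement(p.residue))
            elif isinstance(p, PoolPos):
                if len(p.weights) == 1:
                    elements.append(FixedElement(next(iter(p.weights))))
                else:
                    elements.append(Inclusion(frozenset(p.weights)))
            else:
                elements.append(Exclusion(p.excluded) if p.excluded else Wildcard())
        return AnchoredPattern(tuple(elements), anchored=True)


def ddx3eq_motif_spec() -> MotifSpec:
    """The default planted motif: DDx3EQ-like conservation structure.

    Position 1 is a weighted [D/E/P] pool (D 0.90, E 0.07, P 0.03);
    positions 2, 6, 7 are strict D, E, Q; positions 3-5 are free with
    proline excluded, position 4 additionally excluding the positively
    charged K and R.
    """
    return MotifSpec((
        PoolPos({"D": 0.90, "E": 0.07, "P": 0.03}),
        FixedPos("D"),
        FreePos(frozenset("P")),
        FreePos(frozenset("PKR")),
        FreePos(frozenset("P")),
        FixedPos("E"),
        FixedPos("Q"),
    ))


#: Default body composition: near-flat with proline mildly enriched and the
#: order-promoting residues (aromatics, C, M, H) mildly depleted — a generic
#: disordered/variable-region-like composition. With the default family size
#: (n=50) and exclusion threshold (e_min=3), only proline's expected count
#: clears the conserved-absence bar (50*0.07 = 3.5 >= 3; every other residue
#: is at <= 0.055, 50*0.055 = 2.75 < 3), so conserved absences found by the
#: classifier are attributable to the planted motif rather than to sampling
#: noise in the family bodies.
DEFAULT_BODY_COMPOSITION: dict[str, float] = {
    **{a: 0.055 for a in "ADEGKLNQRSTV"},
    "P": 0.070,
    "F": 0.048, "I": 0.052, "Y": 0.038, "H": 0.036,
    "M": 0.034, "C": 0.032, "W": 0.030,
}


@dataclass(frozen=True)
class FamilyConfig:
    """Configuration of a synthetic ortholog family."""

    seed: int
    n_species: int = 50
    length_range: tuple[int, int] = (450, 650)
    body_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BODY_COMPOSITION)
    )
    motif: MotifSpec = field(default_factory=ddx3eq_motif_spec)
    noise_rate: float = 0.0
    group_id: str = "family1"

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError("length_range must be (min, max) with min <= max")
        if lo < len(self.motif):
            raise ValueError(
                f"length_range minimum {lo} is shorter than the motif (k={len(self.motif)})"
            )
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        comp = dict(self.body_composition)
        vals = np.array([comp.get(a, 0.0) for a in AMINO_ACIDS])
        if (vals < 0).any() or abs(vals.sum() - 1.0) > _TOL:
            raise ValueError("body_composition must be non-negative and sum to 1")
        object.__setattr__(self, "body_composition", comp)


def _comp_vector(composition: Mapping[str, float]) -> np.ndarray:
    v = np.array([composition.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    return v / v.sum()


_ALPHABET_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def _codes_to_strings(codes: np.ndarray, lengths: np.ndarray) -> list[str]:
    buf = _ALPHABET_BYTES[codes].tobytes()
    out = []
    off = 0
    for L in lengths:
        out.append(buf[off:off + L].decode("ascii"))
        off += L
    return out


def _sample_motif_windows(
    spec: MotifSpec, n: int, body: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """n x k residue-code matrix of planted motif windows."""
    k = len(spec)
    out = np.empty((n, k), dtype=np.int64)
    for j, pos in enumerate(spec.positions):
        if isinstance(pos, FixedPos):
            out[:, j] = AA_INDEX[pos.residue]
        elif isinstance(pos, PoolPos):
            idx = np.array([AA_INDEX[a] for a in pos.weights])
            w = np.array(list(pos.weights.values()))
            out[:, j] = rng.choice(idx, size=n, p=w / w.sum())
        else:
            p = body.copy()
            for a in pos.excluded:
                p[AA_INDEX[a]] = 0.0
            p /= p.sum()
            out[:, j] = rng.choice(20, size=n, p=p)
    return out


def generate_family(
    config: FamilyConfig,
) -> tuple[list[SequenceRecord], OrthologGroup, MotifSpec]:
    """Generate an ortholog family with a planted C-terminal motif.

    Each member is an i.i.d. body drawn from the body composition at a
    seeded length within ``length_range``, followed by a motif window drawn
    from the :class:`MotifSpec`; each motif position is then independently
    replaced by a uniform random residue with probability ``noise_rate``.
    Deterministic given the seed. Returns the records, the group manifest
    and the planted spec (ground truth).
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_species, len(config.motif)
    body = _comp_vector(config.body_composition)
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n)
    body_lengths = lengths - k
    body_codes = rng.choice(20, size=int(body_lengths.sum()), p=body)
    motif_codes = _sample_motif_windows(config.motif, n, body, rng)
    if config.noise_rate > 0:
        flip = rng.random(size=motif_codes.shape) < config.noise_rate
        motif_codes[flip] = rng.integers(0, 20, size=int(flip.sum()))
    bodies = _codes_to_strings(body_codes, body_lengths)
    windows = _codes_to_strings(motif_codes.ravel(), np.full(n, k))
    width = len(str(n))
    records, members = [], []
    for i in range(n):
        species = f"species_{i + 1:0{width}d}"
        sid = f"{config.group_id}_{species}"
        records.append(SequenceRecord(sid, bodies[i] + windows[i],
                                      description=f"synthetic ortholog {species}"))
        members.append((sid, species))
    group = OrthologGroup(config.group_id, tuple(members))
    return records, group, config.motif


def generate_decoy_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    composition: Mapping[str, float],
    seed: int,
    id_prefix: str = "decoy",
) -> list[SequenceRecord]:
    """An i.i.d. decoy proteome with the given composition and length range."""
    if n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    lo, hi = length_range
    if lo < 1 or lo > hi:
        raise ValueError("length_range must be (min, max) with 1 <= min <= max")
    if n_proteins == 0:
        return []
    rng = np.random.default_rng(seed)
    p = _comp_vector(composition)
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    codes = rng.choice(20, size=int(lengths.sum()), p=p)
    seqs = _codes_to_strings(codes, lengths)
    width = len(str(n_proteins))
    return [
        SequenceRecord(f"{id_prefix}_{i + 1:0{width}d}", seqs[i])
        for i in range(n_proteins)
    ]


def degrade_motif(
    records: Sequence[SequenceRecord],
    spec: MotifSpec,
    positions: Sequence[int],
    seed: int,
    n_records: int | None = None,
    record_ids: Sequence[str] | None = None,
) -> list[SequenceRecord]:
    """Plant pattern-violating residues in selected records.

    Each selected record gets, at one randomly chosen position among
    ``positions`` (1-based motif coordinates), a residue its spec element
    forbids: another residue for a fixed position, a residue outside the
    pool for a pool position, an excluded residue for a free position
    (e.g. E at a strict-D position — the classic degeneracy — or P at a
    proline-excluded one). Records are selected by id, or as ``n_records``
    random ones; all records are returned, selected ones modified.
    """
    k = len(spec)
    if any(not 1 <= p <= k for p in positions):
        raise ValueError(f"positions must lie in 1..{k}")
    rng = np.random.default_rng(seed)
    if record_ids is None:
        if n_records is None:
            raise ValueError("give either record_ids or n_records")
        chosen_idx = rng.choice(len(records), size=n_records, replace=False)
        chosen = {records[int(i)].id for i in chosen_idx}
    else:
        chosen = set(record_ids)
        unknown = chosen - {r.id for r in records}
        if unknown:
            raise ValueError(f"unknown record id(s): {sorted(unknown)}")
    out: list[SequenceRecord] = []
    for rec in records:
        if rec.id not in chosen:
            out.append(rec)
            continue
        pos = int(rng.choice(list(positions)))
        elem = spec.positions[pos - 1]
        if isinstance(elem, FixedPos):
            candidates = sorted(AA_SET - {elem.residue})
            # Prefer the conservative same-charge swap D<->E when available.
            swap = {"D": "E", "E": "D"}.get(elem.residue)
            violator = swap if swap else candidates[int(rng.integers(len(candidates)))]
        elif isinstance(elem, PoolPos):
            candidates = sorted(AA_SET - set(elem.weights))
            violator = candidates[int(rng.integers(len(candidates)))]
        else:
            if not elem.excluded:
                raise ValueError(
                    f"position {pos} is unconstrained; nothing can violate it"
                )
            violator = sorted(elem.excluded)[int(rng.integers(len(elem.excluded)))]
        L = len(rec)
        offset = L - k + pos - 1
        residues = rec.residues[:offset] + violator + rec.residues[offset + 1:]
        out.append(SequenceRecord(rec.id, residues, rec.description))
    return out


def write_ground_truth(
    path: str | Path,
    spec: MotifSpec,
    records: Sequence[SequenceRecord],
) -> None:
    """Write the planted spec and each record's true motif window as text."""
    k = len(spec)
    lines = [f"# planted_pattern\t{spec.to_pattern().prosite}"]
    lines += [f"{r.id}\t{r.residues[-k:]}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n")
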