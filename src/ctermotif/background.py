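"""Background amino-acid compositions.

A :class:`BackgroundComposition` carries the 20 residue frequencies of a
reference sequence set together with its protein count and mean length; it
feeds both the expected-hit arithmetic of the anchored scanner and the
enrichment null of the composition statistics.

The shipped file ``data/swissprot_background.tsv`` holds the average
composition of a large general protein database (UniProtKB/Swiss-Prot scale
averages) as an editable structured text file.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .alphabet import AMINO_ACIDS, AA_SET

__all__ = [
    "BackgroundComposition",
    "read_background",
    "write_background",
    "swissprot_background",
]

_TOL = 1e-9


@dataclass(frozen=True)
class BackgroundComposition:
    """Residue frequencies (summing to 1) plus protein count and mean length."""

    freqs: Mapping[str, float]
    n_proteins: int
    mean_length: float
    name: str = "background"

    def __post_init__(self):
        freqs = dict(self.freqs)
        missing = AA_SET - freqs.keys()
        if missing:
            raise ValueError(f"background is missing residue(s) {''.join(sorted(missing))}")
        extra = freqs.keys() - AA_SET
        if extra:
            raise ValueError(f"background has non-alphabet key(s) {''.join(sorted(extra))}")
        vals = np.array([freqs[a] for a in AMINO_ACIDS], dtype=float)
        if (vals < 0).any():
            raise ValueError("background frequencies must be non-negative")
        if abs(vals.sum() - 1.0) > _TOL:
            raise ValueError(f"background frequencies sum to {vals.sum():.12f}, not 1")
        if self.n_proteins < 0 or self.mean_length <= 0:
            raise ValueError("n_proteins must be >= 0 and mean_length > 0")
        object.__setattr__(self, "freqs", freqs)

    @property
    def freq_vector(self) -> np.ndarray:
        """Frequencies as a length-20 vector in alphabet order."""
        return np.array([self.freqs[a] for a in AMINO_ACIDS], dtype=float)

    def frequency_of(self, residues: Iterable[str]) -> float:
        """Total background frequency of a residue set."""
        return float(sum(self.freqs[r] for r in set(residues)))

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        n_proteins: int,
        mean_length: float,
        name: str = "background",
    ) -> "BackgroundComposition":
        total = sum(counts.get(a, 0) for a in AMINO_ACIDS)
        if total == 0:
            raise ValueError("cannot derive a composition from zero residues")
        freqs = {a: counts.get(a, 0) / total for a in AMINO_ACIDS}
        # Remove the rounding residue so the sum-to-1 invariant holds exactly.
        drift = 1.0 - sum(freqs.values())
        top = max(freqs, key=freqs.get)
        freqs[top] += drift
        return cls(freqs, n_proteins, mean_length, name=name)

    @classmethod
    def uniform(cls, n_proteins: int = 1, mean_length: float = 100.0,
                name: str = "uniform") -> "BackgroundComposition":
        return cls({a: 1 / 20 for a in AMINO_ACIDS}, n_proteins, mean_length, name=name)


def read_background(path: str | Path, name: str | None = None) -> BackgroundComposition:
    """Read a background composition config.

    Format: TSV lines ``residue<TAB>frequency``; optional metadata lines
    ``#meta n_proteins <int>`` and ``#meta mean_length <float>``; other
    ``#`` lines are comments. Frequencies are renormalized to sum exactly
    to 1 (so hand-edited tables summing to ~100% are accepted).
    """
    path = Path(path)
    freqs: dict[str, float] = {}
    meta = {"n_proteins": 1, "mean_length": 400.0}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.lstrip("#").split()
            if len(parts) == 3 and parts[0] == "meta" and parts[1] in meta:
                meta[parts[1]] = float(parts[2]) if parts[1] == "mean_length" else int(parts[2])
            continue
        fields = line.split()
        if len(fields) != 2 or fields[0] not in AA_SET:
            raise ValueError(f"bad background line in {path}: {line!r}")
        freqs[fields[0]] = float(fields[1])
    total = sum(freqs.values())
    if total <= 0:
        raise ValueError(f"background {path} has no positive frequencies")
    counts_like = {a: f / total for a, f in freqs.items()}
    drift = 1.0 - sum(counts_like.get(a, 0.0) for a in AMINO_ACIDS)
    if counts_like:
        top = max(counts_like, key=counts_like.get)
        counts_like[top] += drift
    return BackgroundComposition(
        counts_like, meta["n_proteins"], meta["mean_length"],
        name=name or path.stem,
    )


def write_background(bg: BackgroundComposition, path: str | Path) -> None:
    lines = [
        f"#meta n_proteins {bg.n_proteins}",
        f"#meta mean_length {bg.mean_length:g}",
    ]
    lines += [f"{a}\t{bg.freqs[a]:.6f}" for a in AMINO_ACIDS]
    Path(path).write_text("\n".join(lines) + "\n")


def swissprot_background() -> BackgroundComposition:
    """The shipped general-protein-database average composition."""
    ref = resources.files("ctermotif").joinpath("data/swissprot_background.tsv")
    with resources.as_file(ref) as path:
        return read_background(path, name="swissprot")
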