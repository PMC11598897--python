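"""C-terminal window profiling and anchored pattern induction.

Given an ortholog family, the last ``k`` residues of every member are the
motif candidates: no alignment is needed because a strictly C-terminal motif
is anchored by construction. The module builds the position frequency matrix
over those windows, derives per-position information content (the height
basis of sequence logos), classifies each position by its conservation type
(strict / dominant / class-enriched / wildcard, with conserved absences
recorded as exclusions), and induces a Prosite-syntax anchored pattern.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, AA_INDEX
from .background import BackgroundComposition
from .patterns import (
    AnchoredPattern,
    Exclusion,
    Fixed,
    Inclusion,
    Wildcard,
)
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CTermWindow",
    "PositionProfile",
    "PositionClass",
    "ClassifierThresholds",
    "extract_cterm_window",
    "strip_cterm",
    "build_profile",
    "classify_positions",
    "induce_pattern",
    "logo_matrix",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_meme",
    "read_meme",
]

LOG2_20 = float(np.log2(20.0))


@dataclass(frozen=True)
class CTermWindow:
    """The last ``k`` residues of a source sequence, with 1-based coordinates."""

    source_id: str
    residues: str
    start: int  # = L - k + 1
    end: int    # = L

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.residues):
            raise ValueError("window coordinates inconsistent with residue length")

    def __len__(self) -> int:
        return len(self.residues)


def extract_cterm_window(record: SequenceRecord, k: int) -> CTermWindow:
    """Extract the C-terminal window of length ``k`` (1-based coordinates)."""
    if k < 1:
        raise ValueError("window length k must be >= 1")
    L = len(record)
    if L < k:
        raise ValueError(
            f"record {record.id!r} is shorter ({L} aa) than the window length k={k}"
        )
    return CTermWindow(record.id, record.residues[-k:], start=L - k + 1, end=L)


def strip_cterm(records: Sequence[SequenceRecord], k: int) -> list[SequenceRecord]:
    """Remove the last ``k`` residues from each record.

    Records of length <= k (which would leave nothing) are skipped with a
    logged warning. For every kept record, stripped body + C-terminal window
    reconstructs the input exactly.
    """
    out: list[SequenceRecord] = []
    for r in records:
        if len(r) <= k:
            logger.warning(
                "record %s (%d aa) is too short to strip a %d-aa C-terminus; skipped",
                r.id, len(r), k,
            )
            continue
        out.append(SequenceRecord(r.id, r.residues[:-k], r.description))
    return out


@dataclass(frozen=True)
class PositionProfile:
    """Position frequency matrix over C-terminal windows.

    ``counts`` is a 20 x k integer matrix (rows in alphabet order); every
    column sums to ``n``. ``info_bits[j] = log2(20) - H_j`` where ``H_j`` is
    the Shannon entropy of column j's frequencies.
    """

    k: int
    n: int
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (20, self.k):
            raise ValueError(f"counts must be 20 x {self.k}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (counts.sum(axis=0) == self.n).all():
            raise ValueError("every profile column must sum to n")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def info_bits(self) -> np.ndarray:
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        entropy = -plogp.sum(axis=0)
        return np.clip(LOG2_20 - entropy, 0.0, LOG2_20)


def build_profile(windows: Sequence[CTermWindow]) -> PositionProfile:
    """Count residues per position across same-length windows."""
    if not windows:
        raise ValueError("need at least one window to build a profile")
    k = len(windows[0])
    lengths = {len(w) for w in windows}
    if lengths != {k}:
        raise ValueError(f"windows have mixed lengths {sorted(lengths)}")
    counts = np.zeros((20, k), dtype=int)
    for w in windows:
        for j, ch in enumerate(w.residues):
            if ch not in AA_INDEX:
                raise ValueError(
                    f"window from {w.source_id!r} has unknown residue {ch!r}; "
                    "profiles require fully determined residues"
                )
            counts[AA_INDEX[ch], j] += 1
    return PositionProfile(k=k, n=len(windows), counts=counts)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable thresholds of the per-position conservation classifier.

    theta_dom
        Minimum top-residue frequency for a 'dominant' call (default 0.95).
    theta_cov
        Cumulative frequency a small residue set must reach for a
        'class_enriched' call (default 0.99).
    c_max
        Maximum size of that covering set (default 4).
    e_min
        Minimum expected count ``n * bg(r)`` for a zero-count residue to be
        called a conserved absence (exclusion) (default 3).
    n_min
        Minimum number of windows required to classify at all (default 5).
    """

    theta_dom: float = 0.95
    theta_cov: float = 0.99
    c_max: int = 4
    e_min: float = 3.0
    n_min: int = 5


@dataclass(frozen=True)
class PositionClass:
    """Conservation call for one motif position (1-based)."""

    position: int
    kind: str  # strict | dominant | class_enriched | wildcard
    allowed: frozenset[str] = frozenset()
    excluded: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.kind not in {"strict", "dominant", "class_enriched", "wildcard"}:
            raise ValueError(f"unknown position class kind {self.kind!r}")
        if self.kind == "strict" and len(self.allowed) != 1:
            raise ValueError("a strict position has exactly one allowed residue")
        if self.allowed & self.excluded:
            raise ValueError("allowed and excluded residue sets must be disjoint")


def classify_positions(
    profile: PositionProfile,
    bg: BackgroundComposition,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> list[PositionClass]:
    """Classify each profile position by conservation type.

    strict: one residue at frequency 1.0. dominant: top residue frequency
    >= theta_dom. class_enriched: the smallest residue set whose cumulative
    frequency reaches theta_cov has size <= c_max. Otherwise wildcard.
    Independently of the kind, any residue with zero observed count whose
    expected count ``n * bg(r)`` is at least ``e_min`` is recorded as a
    conserved absence (exclusion).
    """
    t = thresholds
    if profile.n < t.n_min:
        raise ValueError(
            f"too few sequences to classify: n={profile.n} < n_min={t.n_min}"
        )
    classes: list[PositionClass] = []
    freqs = profile.frequencies
    for j in range(profile.k):
        col = freqs[:, j]
        # Descending frequency, ties broken alphabetically (stable sort on
        # the already-alphabetical row order).
        order = np.argsort(-col, kind="stable")
        excluded = frozenset(
            a for i, a in enumerate(AMINO_ACIDS)
            if profile.counts[i, j] == 0 and profile.n * bg.freqs[a] >= t.e_min
        )
        top = order[0]
        if profile.counts[top, j] == profile.n:
            cls = PositionClass(j + 1, "strict",
                                frozenset({AMINO_ACIDS[top]}), excluded)
        elif col[top] >= t.theta_dom:
            cls = PositionClass(j + 1, "dominant",
                                frozenset({AMINO_ACIDS[top]}), excluded)
        else:
            cum = np.cumsum(col[order])
            reach = int(np.searchsorted(cum, t.theta_cov - 1e-12)) + 1
            if reach <= t.c_max:
                allowed = frozenset(AMINO_ACIDS[i] for i in order[:reach])
                cls = PositionClass(j + 1, "class_enriched", allowed, excluded - allowed)
            else:
                cls = PositionClass(j + 1, "wildcard", frozenset(), excluded)
        classes.append(cls)
    return classes


def induce_pattern(classes: Sequence[PositionClass]) -> AnchoredPattern:
    """Turn position classes into a C-terminally anchored Prosite pattern.

    strict/dominant -> fixed element; class_enriched -> inclusion class;
    wildcard -> exclusion class when conserved absences were recorded, else
    a bare wildcard. The result is always anchored: the profile was built
    from C-terminal windows.
    """
    if [c.position for c in classes] != list(range(1, len(classes) + 1)):
        raise ValueError("classes must cover positions 1..k in order")
    elements = []
    for c in classes:
        if c.kind in ("strict", "dominant"):
            elements.append(Fixed(next(iter(c.allowed))))
        elif c.kind == "class_enriched":
            elements.append(Inclusion(c.allowed))
        elif c.excluded:
            elements.append(Exclusion(c.excluded))
        else:
            elements.append(Wildcard())
    return AnchoredPattern(tuple(elements), anchored=True)


def logo_matrix(profile: PositionProfile) -> tuple[pd.DataFrame, pd.Series]:
    """Per-position residue frequencies and information content.

    Returns a (20 x k) DataFrame (rows = residues in alphabet order,
    columns = positions 1..k) and a Series of information content in bits —
    the numbers behind a sequence logo.
    """
    cols = list(range(1, profile.k + 1))
    freq = pd.DataFrame(profile.frequencies, index=list(AMINO_ACIDS), columns=cols)
    info = pd.Series(profile.info_bits, index=cols, name="info_bits")
    return freq, info


def write_counts_tsv(profile: PositionProfile, path: str | Path) -> None:
    """Write the counts matrix as TSV (rows = residues, columns = positions)."""
    df = pd.DataFrame(
        profile.counts, index=list(AMINO_ACIDS),
        columns=[str(j) for j in range(1, profile.k + 1)],
    )
    df.to_csv(path, sep="\t", index_label="residue")


def read_counts_tsv(path: str | Path) -> PositionProfile:
    df = pd.read_csv(path, sep="\t", index_col="residue")
    counts = df.loc[list(AMINO_ACIDS)].to_numpy(dtype=int)
    n = int(counts[:, 0].sum())
    return PositionProfile(k=counts.shape[1], n=n, counts=counts)


def write_meme(
    profile: PositionProfile,
    path: str | Path,
    name: str = "motif",
    bg: BackgroundComposition | None = None,
) -> None:
    """Write the profile in MEME minimal motif format (letter-probability matrix)."""
    lines = ["MEME version 4", "", f"ALPHABET= {AMINO_ACIDS}", ""]
    if bg is not None:
        lines.append("Background letter frequencies")
        lines.append(" ".join(f"{a} {bg.freqs[a]:.6f}" for a in AMINO_ACIDS))
        lines.append("")
    lines.append(f"MOTIF {name}")
    lines.append(
        f"letter-probability matrix: alength= 20 w= {profile.k} nsites= {profile.n} E= 0"
    )
    freq = profile.frequencies
    for j in range(profile.k):
        lines.append(" " + " ".join(f"{freq[i, j]:.6f}" for i in range(20)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme(path: str | Path) -> pd.DataFrame:
    """Read back a MEME minimal motif as a (20 x k) frequency DataFrame."""
    lines = Path(path).read_text().splitlines()
    rows: list[list[float]] = []
    w = None
    for i, line in enumerate(lines):
        if line.startswith("letter-probability matrix"):
            for tok, nxt in zip(line.replace(":", " ").split(), line.replace(":", " ").split()[1:]):
                if tok == "w=":
                    w = int(nxt)
            for data in lines[i + 1:]:
                data = data.strip()
                if not data:
                    break
                rows.append([float(x) for x in data.split()])
            break
    if w is None or len(rows) != w:
        raise ValueError(f"no letter-probability matrix of full width found in {path}")
    mat = np.array(rows, dtype=float).T  # -> 20 x k
    return pd.DataFrame(mat, index=list(AMINO_ACIDS),
                        columns=list(range(1, w + 1)))
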