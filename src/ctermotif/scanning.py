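"""Anchored pattern scanning, expected-hit arithmetic, conservation filter.

The matcher is a direct position-wise evaluator of the pattern elements (no
regex engine): a C-terminally anchored pattern of length m is tested against
the last m residues only, which is what gives strictly C-terminal motifs
their specificity — a protein has exactly one free-carboxy position, versus
L - m + 1 internal placements.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .background import BackgroundComposition
from .patterns import AnchoredPattern, Exclusion, Fixed, Inclusion, Wildcard, element_matches
from .seqio import OrthologGroup, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MatchRecord",
    "match_at_cterm",
    "scan_database",
    "expected_hits",
    "anchoring_specificity_factor",
    "conserved_occurrence_filter",
    "hits_to_dataframe",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class MatchRecord:
    """A located pattern occurrence; coordinates are 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    peptide: str
    anchored: bool

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError("match coordinates inconsistent with peptide length")


def _matches_at(pattern: AnchoredPattern, residues: str, offset: int) -> bool:
    return all(
        element_matches(e, residues[offset + j])
        for j, e in enumerate(pattern.elements)
    )


def match_at_cterm(pattern: AnchoredPattern, record: SequenceRecord) -> MatchRecord | None:
    """Test the last m residues of a record against an anchored pattern.

    A record shorter than the pattern simply does not match (no error).
    """
    m = len(pattern)
    L = len(record)
    if L < m:
        return None
    if not _matches_at(pattern, record.residues, L - m):
        return None
    return MatchRecord(record.id, start=L - m + 1, end=L,
                       peptide=record.residues[-m:], anchored=True)


def scan_database(
    pattern: AnchoredPattern, records: Sequence[SequenceRecord]
) -> list[MatchRecord]:
    """Scan records in order.

    Anchored patterns yield at most one hit per record (at the C-terminus).
    Unanchored patterns report all leftmost non-overlapping occurrences.
    """
    hits: list[MatchRecord] = []
    m = len(pattern)
    for rec in records:
        if pattern.anchored:
            hit = match_at_cterm(pattern, rec)
            if hit is not None:
                hits.append(hit)
            continue
        i = 0
        L = len(rec)
        while i + m <= L:
            if _matches_at(pattern, rec.residues, i):
                hits.append(MatchRecord(rec.id, start=i + 1, end=i + m,
                                        peptide=rec.residues[i:i + m],
                                        anchored=(i + m == L)))
                i += m
            else:
                i += 1
    return hits


def _position_probability(element, bg: BackgroundComposition) -> float:
    if isinstance(element, Wildcard):
        return 1.0
    if isinstance(element, Fixed):
        return bg.freqs[element.residue]
    if isinstance(element, Inclusion):
        return bg.frequency_of(element.residues)
    return 1.0 - bg.frequency_of(element.residues)


def expected_hits(
    pattern: AnchoredPattern,
    bg: BackgroundComposition,
    anchored: bool | None = None,
    lengths: Sequence[int] | None = None,
) -> float:
    """Expected number of pattern occurrences in a random database.

    Per-position match probabilities are summed background frequencies
    (1 - sum for exclusions, 1 for wildcards); their product P is the
    probability that a random m-mer matches. Anchored: ``n_proteins * P``
    (one placement per protein). Unanchored: ``n_proteins *
    (mean_length - m + 1) * P``. When ``lengths`` is given, the exact
    per-protein sum ``sum_j (L_j - m + 1) * P`` is used instead of the
    mean-length approximation (anchored mode then counts proteins with
    L_j >= m).
    """
    if anchored is None:
        anchored = pattern.anchored
    m = len(pattern)
    P = 1.0
    for e in pattern.elements:
        P *= _position_probability(e, bg)
    if lengths is not None:
        arr = np.asarray(lengths)
        if anchored:
            return float((arr >= m).sum() * P)
        return float(np.clip(arr - m + 1, 0, None).sum() * P)
    if bg.mean_length < m:
        raise ValueError(
            f"mean_length {bg.mean_length} is shorter than the pattern (m={m})"
        )
    if anchored:
        return bg.n_proteins * P
    return bg.n_proteins * (bg.mean_length - m + 1) * P


def anchoring_specificity_factor(mean_length: float, m: int) -> float:
    """Fold-reduction in expected occurrences from requiring C-terminal anchoring.

    A length-m motif has ``mean_length - m + 1`` unanchored placements in an
    average protein but only one C-terminal placement, so anchoring reduces
    the expected occurrence frequency by ``(mean_length - m + 1) / 1``.
    """
    if m < 1:
        raise ValueError("pattern length m must be >= 1")
    if mean_length < m:
        raise ValueError(f"mean_length {mean_length} is shorter than the pattern (m={m})")
    return float(mean_length - m + 1)


def conserved_occurrence_filter(
    hits: Sequence[MatchRecord],
    groups: Sequence[OrthologGroup],
    min_others: int = 1,
) -> list[MatchRecord]:
    """Keep hits whose motif is conserved in other members of the ortholog group.

    A hit is retained iff at least ``min_others`` *other* members of its
    group also carry a hit. Hits on sequences absent from every group are
    dropped with a logged warning; a sequence assigned to two groups is an
    error. The filter is idempotent.
    """
    seq_to_group: dict[str, str] = {}
    for g in groups:
        for sid in g.member_ids:
            if sid in seq_to_group and seq_to_group[sid] != g.group_id:
                raise ValueError(
                    f"sequence {sid!r} appears in groups "
                    f"{seq_to_group[sid]!r} and {g.group_id!r}"
                )
            seq_to_group[sid] = g.group_id
    hit_members: dict[str, set[str]] = {}
    for h in hits:
        gid = seq_to_group.get(h.seq_id)
        if gid is not None:
            hit_members.setdefault(gid, set()).add(h.seq_id)
    retained: list[MatchRecord] = []
    for h in hits:
        gid = seq_to_group.get(h.seq_id)
        if gid is None:
            logger.warning("hit on %s dropped: sequence is in no ortholog group", h.seq_id)
            continue
        if len(hit_members[gid] - {h.seq_id}) >= min_others:
            retained.append(h)
    return retained


def hits_to_dataframe(
    hits: Sequence[MatchRecord],
    groups: Sequence[OrthologGroup] = (),
    retained: Iterable[MatchRecord] | None = None,
) -> pd.DataFrame:
    """Hits as a table: seq_id, start, end, peptide, group_id, retained flag."""
    seq_to_group = {sid: g.group_id for g in groups for sid in g.member_ids}
    kept = {(h.seq_id, h.start) for h in retained} if retained is not None else None
    rows = [
        {
            "seq_id": h.seq_id,
            "start": h.start,
            "end": h.end,
            "peptide": h.peptide,
            "group_id": seq_to_group.get(h.seq_id, ""),
            "retained_by_conservation_filter": (
                1 if kept is None or (h.seq_id, h.start) in kept else 0
            ),
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["seq_id", "start", "end", "peptide", "group_id",
                 "retained_by_conservation_filter"],
    )


def write_hits_tsv(
    hits: Sequence[MatchRecord],
    path: str | Path,
    groups: Sequence[OrthologGroup] = (),
    retained: Iterable[MatchRecord] | None = None,
) -> None:
    hits_to_dataframe(hits, groups, retained).to_csv(path, sep="\t", index=False)
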