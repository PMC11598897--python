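"""Protein FASTA and ortholog-manifest I/O.

Reading and writing go through Biopython's ``SeqIO``; this module adds the
validation layer (alphabet checks, unknown-residue policy) and the ortholog
group manifest used by the conservation filter.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import AA_SET, EXTENDED_SET, UNKNOWN

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "OrthologGroup",
    "read_fasta",
    "write_fasta",
    "read_group_manifest",
    "write_group_manifest",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence over the 20-residue alphabet (plus optional 'X').

    Residues are stored uppercased; construction fails on an empty sequence,
    a whitespace-containing id, or a character outside the alphabet.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}: must be a non-empty token")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - EXTENDED_SET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-amino-acid character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OrthologGroup:
    """A set of orthologous sequences: (sequence id, species label) pairs."""

    group_id: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"ortholog group {self.group_id!r} has no members")
        ids = [sid for sid, _ in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sequence id in group {self.group_id!r}")

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.members)


def read_fasta(
    path: str | Path,
    on_unknown: Literal["error", "mask"] = "error",
) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        FASTA file, one or more records.
    on_unknown
        ``"error"`` (default): a residue outside ``ACDEFGHIKLMNPQRSTVWYX``
        raises, naming the record and the character. ``"mask"``: such residues
        are mapped to ``'X'`` instead.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        residues = str(entry.seq).upper()
        bad = sorted(set(residues) - EXTENDED_SET)
        if bad:
            if on_unknown == "mask":
                table = str.maketrans({c: UNKNOWN for c in bad})
                residues = residues.translate(table)
                logger.warning(
                    "record %s: mapped unknown character(s) %s to 'X'",
                    entry.id, "".join(bad),
                )
            else:
                raise ValueError(
                    f"record {entry.id!r} contains non-amino-acid character(s) "
                    f"{''.join(bad)!r} (use on_unknown='mask' to map them to 'X')"
                )
        records.append(SequenceRecord(id=entry.id, residues=residues,
                                      description=entry.description.partition(" ")[2]))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


_MANIFEST_COLUMNS = ["group_id", "seq_id", "species"]


def read_group_manifest(path: str | Path) -> list[OrthologGroup]:
    """Read a TSV ortholog manifest (columns group_id, seq_id, species).

    Groups come back in first-appearance order; a duplicated
    (group_id, seq_id) row is an error. Whether every seq_id has a FASTA
    record is checked at pipeline assembly, not here.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["group_id", "seq_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate manifest row for group {row.group_id!r}, sequence {row.seq_id!r}"
        )
    groups: dict[str, list[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(row.group_id, []).append((row.seq_id, row.species))
    return [OrthologGroup(gid, tuple(members)) for gid, members in groups.items()]


def write_group_manifest(groups: Iterable[OrthologGroup], path: str | Path) -> None:
    rows = [
        {"group_id": g.group_id, "seq_id": sid, "species": sp}
        for g in groups
        for sid, sp in g.members
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
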