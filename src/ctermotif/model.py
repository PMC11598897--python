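"""Model/Results interface over the C-terminal motif pipeline.

``CTermMotifModel`` holds an ortholog family (and optionally its group
manifest); ``fit()`` extracts the C-terminal windows, builds the position
profile, classifies positions against a background and induces the anchored
pattern, returning a ``CTermMotifResults`` that carries the estimates and
offers a ``summary()`` table, enrichment testing, logo matrices and
convenience plotting.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alphabet import AMINO_ACIDS
from .background import BackgroundComposition
from .composition import (
    PropertyClassTable,
    composition_report,
    results_to_dataframe,
    background_from_stripped,
)
from .patterns import AnchoredPattern
from .profile import (
    ClassifierThresholds,
    CTermWindow,
    PositionClass,
    PositionProfile,
    build_profile,
    classify_positions,
    extract_cterm_window,
    induce_pattern,
    logo_matrix,
    write_meme,
)
from .seqio import OrthologGroup, SequenceRecord, read_fasta, read_group_manifest

__all__ = ["CTermMotifModel", "CTermMotifResults"]


class CTermMotifModel:
    """C-terminal motif model of an ortholog family.

    Parameters
    ----------
    records
        The family's protein sequences.
    groups
        Optional ortholog groups (used by downstream conservation filtering;
        carried through for provenance).
    k
        Window length: the number of C-terminal residues profiled
        (default 7).
    """

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        groups: Sequence[OrthologGroup] = (),
        k: int = 7,
    ):
        if not records:
            raise ValueError("need at least one sequence")
        self.records = list(records)
        self.groups = list(groups)
        self.k = k

    @classmethod
    def from_fasta(
        cls, fasta: str | Path, manifest: str | Path | None = None, k: int = 7
    ) -> "CTermMotifModel":
        records = read_fasta(fasta)
        groups = read_group_manifest(manifest) if manifest else []
        if groups:
            known = {r.id for r in records}
            missing = [sid for g in groups for sid in g.member_ids if sid not in known]
            if missing:
                raise ValueError(
                    f"manifest names sequence(s) absent from the FASTA: {missing[:5]}"
                )
        return cls(records, groups, k=k)

    def fit(
        self,
        background: BackgroundComposition | None = None,
        thresholds: ClassifierThresholds = ClassifierThresholds(),
    ) -> "CTermMotifResults":
        """Profile the C-terminal windows and induce the anchored pattern.

        When no background is given, the family's own stripped bodies (the
        sequences minus their last k residues) provide it.
        """
        windows = [extract_cterm_window(r, self.k) for r in self.records]
        profile = build_profile(windows)
        if background is None:
            background = background_from_stripped(self.records, self.k)
        classes = classify_positions(profile, background, thresholds)
        pattern = induce_pattern(classes)
        return CTermMotifResults(self, windows, profile, background, classes,
                                 pattern, thresholds)


@dataclass
class CTermMotifResults:
    """Fitted C-terminal motif: profile, position classes, induced pattern."""

    model: CTermMotifModel
    windows: list[CTermWindow]
    profile: PositionProfile
    background: BackgroundComposition
    position_classes: list[PositionClass]
    pattern: AnchoredPattern
    thresholds: ClassifierThresholds

    def summary(self) -> str:
        """Human-readable per-position summary table."""
        freq, info = logo_matrix(self.profile)
        lines = [
            "C-terminal motif profile",
            f"  sequences: {self.profile.n}    window length k: {self.profile.k}",
            f"  background: {self.background.name}",
            f"  induced pattern: {self.pattern.prosite}",
            f"  regex rendering: {self.pattern.regex}",
            "",
            f"  {'pos':>3}  {'class':<14}  {'info(bits)':>10}  {'top residues':<24}  excluded",
        ]
        for c in self.position_classes:
            col = freq[c.position].sort_values(ascending=False)
            top = ", ".join(f"{a}:{f:.2f}" for a, f in col.head(3).items() if f > 0)
            excl = "".join(sorted(c.excluded)) or "-"
            lines.append(
                f"  {c.position:>3}  {c.kind:<14}  {info[c.position]:>10.2f}  {top:<24}  {excl}"
            )
        return "\n".join(lines)

    def logo_dataframe(self) -> pd.DataFrame:
        """Frequencies with an info_bits row appended (tabular logo export)."""
        freq, info = logo_matrix(self.profile)
        out = freq.copy()
        out.loc["info_bits"] = info
        return out

    def enrichment(
        self,
        backgrounds: Sequence[BackgroundComposition] | None = None,
        classes: PropertyClassTable | None = None,
        n_boot: int = 10_000,
        seed: int | None = None,
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Compositional enrichment of the motif windows vs backgrounds.

        Defaults to the fit's own background; returns (per-class test table,
        per-position descriptive class fractions).
        """
        if backgrounds is None:
            backgrounds = [self.background]
        results, per_pos = composition_report(
            self.windows, backgrounds, classes=classes, n_boot=n_boot, seed=seed
        )
        return results_to_dataframe(results), per_pos

    def to_meme(self, path: str | Path, name: str = "motif") -> None:
        write_meme(self.profile, path, name=name, bg=self.background)

    def classification_records(self) -> list[dict]:
        """Position classes as plain dicts (JSON-ready)."""
        return [
            {
                "position": c.position,
                "kind": c.kind,
                "allowed": "".join(sorted(c.allowed)),
                "excluded": "".join(sorted(c.excluded)),
            }
            for c in self.position_classes
        ]

    def plot_logo(self, ax=None):
        """Stacked-bar sequence logo (information-scaled). Convenience only."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.0 * self.profile.k + 1, 3))
        freq, info = logo_matrix(self.profile)
        for j in freq.columns:
            bottom = 0.0
            col = freq[j].sort_values()
            for aa, f in col.items():
                if f <= 0:
                    continue
                h = f * info[j]
                ax.bar(j, h, bottom=bottom, width=0.8, label=None)
                if h > 0.25:
                    ax.text(j, bottom + h / 2, aa, ha="center", va="center", fontsize=8)
                bottom += h
        ax.set_xlabel("motif position")
        ax.set_ylabel("bits")
        ax.set_xticks(list(freq.columns))
        return ax
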