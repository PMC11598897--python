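"""Compositional-bias statistics for motif instances.

The question: is a motif's residue-class content (e.g. the negatively
charged residues D/E) over- or under-represented relative to a background
set — either a general protein database or the motif-bearing proteins
themselves with the motif removed? The null model draws residues i.i.d.
from the background composition; because the statistic is a class fraction,
the in-class count of each bootstrap sample is exactly Binomial(n, p_class)
and is sampled directly. An exact binomial tail computation is provided as
an independent cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .alphabet import AA_SET
from .background import BackgroundComposition
from .profile import CTermWindow, strip_cterm
from .seqio import SequenceRecord

__all__ = [
    "PropertyClassTable",
    "EnrichmentResult",
    "class_fraction",
    "background_from_stripped",
    "enrichment_test",
    "binomial_enrichment_pvalue",
    "composition_report",
    "results_to_dataframe",
]

#: Default residue property classes. Histidine sits in 'polar' by default and
#: joins 'positive' only on request (its charge is pH-dependent).
DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "negative": frozenset("DE"),
    "positive": frozenset("KR"),
    "hydrophobic": frozenset("ACFILMV"),
    "polar": frozenset("NQSTYHC"),
    "proline": frozenset("P"),
}


@dataclass(frozen=True)
class PropertyClassTable:
    """Named residue sets used for compositional enrichment."""

    classes: Mapping[str, frozenset[str]]

    def __post_init__(self):
        classes = {k: frozenset(v) for k, v in self.classes.items()}
        for name, residues in classes.items():
            if not residues:
                raise ValueError(f"property class {name!r} is empty")
            if not residues <= AA_SET:
                raise ValueError(f"property class {name!r} contains non-alphabet residues")
        object.__setattr__(self, "classes", classes)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.classes[name]

    def items(self):
        return self.classes.items()

    @classmethod
    def default(cls, histidine_positive: bool = False) -> "PropertyClassTable":
        classes = dict(DEFAULT_CLASSES)
        if histidine_positive:
            classes["positive"] = classes["positive"] | {"H"}
        return cls(classes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PropertyClassTable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls({name: frozenset(str(v)) for name, v in raw.items()})


def class_fraction(residues: str, residue_class: Iterable[str]) -> float:
    """Fraction of the residues belonging to the class."""
    if not residues:
        raise ValueError("cannot compute a class fraction of an empty residue string")
    cls = set(residue_class)
    return sum(ch in cls for ch in residues) / len(residues)


def background_from_stripped(
    records: Sequence[SequenceRecord], k: int, name: str = "stripped"
) -> BackgroundComposition:
    """Background composition of the sequences with their last k residues removed.

    This is the 'rest of the protein' background: the motif under test is
    excised so it cannot dilute its own signal.
    """
    stripped = strip_cterm(records, k)
    if not stripped:
        raise ValueError(f"no record is longer than k={k}; cannot derive a background")
    counts: dict[str, int] = {}
    total = 0
    for r in stripped:
        total += len(r)
        for ch in set(r.residues):
            counts[ch] = counts.get(ch, 0) + r.residues.count(ch)
    counts.pop("X", None)
    mean_length = total / len(stripped)
    return BackgroundComposition.from_counts(counts, len(stripped), mean_length, name=name)


@dataclass(frozen=True)
class EnrichmentResult:
    """Bootstrap enrichment of one residue class against one background."""

    class_name: str
    background_name: str
    query_fraction: float
    background_fraction: float
    relative_enrichment: float
    p_value: float
    n_boot: int
    seed: int

    def __post_init__(self):
        if not (0 <= self.query_fraction <= 1 and 0 <= self.background_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


def enrichment_test(
    query: str,
    bg: BackgroundComposition,
    residue_class: Iterable[str],
    n_boot: int = 10_000,
    seed: int | None = None,
    class_name: str = "class",
) -> EnrichmentResult:
    """Two-sided bootstrap test of a class fraction against a background.

    Null samples are n_boot i.i.d. residue draws of the query's size from
    the background; the p-value is
    ``(1 + #{samples at least as far from the background fraction}) /
    (n_boot + 1)``, deterministic given the (mandatory) seed.
    """
    if seed is None:
        raise ValueError("enrichment_test requires an explicit seed")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    cls = set(residue_class)
    if not cls:
        raise ValueError("residue class is empty")
    nq = len(query)
    q_frac = class_fraction(query, cls)
    p0 = bg.frequency_of(cls)
    rng = np.random.default_rng(seed)
    # In-class count of an i.i.d. residue sample is Binomial(nq, p0); the
    # class fraction is a function of that count only, so sample it directly.
    boot_frac = rng.binomial(nq, p0, size=n_boot) / nq
    observed_dev = abs(q_frac - p0)
    extreme = int(np.sum(np.abs(boot_frac - p0) >= observed_dev - 1e-15))
    p_value = (1 + extreme) / (n_boot + 1)
    rel = (q_frac - p0) / p0 if p0 > 0 else np.inf
    return EnrichmentResult(
        class_name=class_name,
        background_name=bg.name,
        query_fraction=q_frac,
        background_fraction=p0,
        relative_enrichment=rel,
        p_value=p_value,
        n_boot=n_boot,
        seed=seed,
    )


def binomial_enrichment_pvalue(n: int, k_in_class: int, p0: float) -> float:
    """Exact two-sided tail P(|X/n - p0| >= |k/n - p0|), X ~ Binomial(n, p0).

    Independent cross-check for the bootstrap p-value (the bootstrap
    estimates exactly this tail, up to the +1 finite-sample correction).
    """
    dev = abs(k_in_class / n - p0)
    x = np.arange(n + 1)
    mask = np.abs(x / n - p0) >= dev - 1e-15
    return float(stats.binom.pmf(x[mask], n, p0).sum())


def composition_report(
    windows: Sequence[CTermWindow],
    backgrounds: Sequence[BackgroundComposition],
    classes: PropertyClassTable | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> tuple[list[EnrichmentResult], pd.DataFrame]:
    """Full compositional characterization of a set of motif windows.

    Runs one bootstrap enrichment test per (class, background) pair on the
    concatenated window residues, and reports descriptive per-position class
    fractions (no test) for position-level statements such as 'position 3 is
    enriched in hydrophobic residues'.

    Each (class, background) test gets an independent child seed spawned
    deterministically from ``seed``.
    """
    if seed is None:
        raise ValueError("composition_report requires an explicit seed")
    if classes is None:
        classes = PropertyClassTable.default()
    if not windows:
        raise ValueError("no windows given")
    query = "".join(w.residues for w in windows)
    k = len(windows[0])
    results: list[EnrichmentResult] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(classes.classes) * len(backgrounds))
    i = 0
    for name, residue_class in classes.items():
        for bg in backgrounds:
            child_seed = int(children[i].generate_state(1, dtype=np.uint32)[0])
            i += 1
            results.append(
                enrichment_test(query, bg, residue_class, n_boot=n_boot,
                                seed=child_seed, class_name=name)
            )
    per_pos = pd.DataFrame(
        {
            name: [
                class_fraction("".join(w.residues[j] for w in windows), residue_class)
                for j in range(k)
            ]
            for name, residue_class in classes.items()
        },
        index=pd.Index(range(1, k + 1), name="position"),
    )
    return results, per_pos


def results_to_dataframe(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as the report table."""
    return pd.DataFrame(
        [
            {
                "class": r.class_name,
                "background_name": r.background_name,
                "query_fraction": r.query_fraction,
                "background_fraction": r.background_fraction,
                "relative_enrichment": r.relative_enrichment,
                "p_value": r.p_value,
                "n_boot": r.n_boot,
                "seed": r.seed,
            }
            for r in results
        ]
    )
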