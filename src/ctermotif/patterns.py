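"""Prosite-syntax anchored patterns.

The supported dialect is the subset needed for C-terminal motif work:
dash-separated elements that are a fixed residue (``D``), an inclusion class
(``[DEP]``, at least two residues), an exclusion class (``{P}``), or a
wildcard (``x``, with the ``x(3)`` repetition shorthand expanded at parse
time), optionally followed by a trailing ``>`` anchoring the match to the
C-terminus. The N-terminal anchor ``<`` is rejected. Patterns render both
back to Prosite text and to an anchored textual regular expression
(``[DEP]-D-{P}-{P}-{P}-E-Q>`` <-> ``[DEP]D[^P][^P][^P]EQ$``).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .alphabet import AA_SET, UNKNOWN

__all__ = [
    "Fixed",
    "Inclusion",
    "Exclusion",
    "Wildcard",
    "PatternElement",
    "AnchoredPattern",
    "PrositeParseError",
    "parse_prosite",
    "serialize_prosite",
    "pattern_to_regex_text",
    "read_pattern_file",
    "element_matches",
]


class PrositeParseError(ValueError):
    """Raised on a malformed Prosite pattern; carries the element position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"element {position}: {message}")
        self.position = position


@dataclass(frozen=True)
class Fixed:
    residue: str

    def __post_init__(self):
        if self.residue not in AA_SET:
            raise ValueError(f"fixed element residue {self.residue!r} not in alphabet")


@dataclass(frozen=True)
class Inclusion:
    residues: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "residues", frozenset(self.residues))
        if len(self.residues) < 2:
            raise ValueError("inclusion class needs >= 2 residues (write a fixed element instead)")
        if not self.residues <= AA_SET:
            raise ValueError("inclusion class contains non-alphabet characters")


@dataclass(frozen=True)
class Exclusion:
    residues: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "residues", frozenset(self.residues))
        if not self.residues:
            raise ValueError("exclusion class must name at least one residue")
        if not self.residues <= AA_SET:
            raise ValueError("exclusion class contains non-alphabet characters")


@dataclass(frozen=True)
class Wildcard:
    pass


PatternElement = Union[Fixed, Inclusion, Exclusion, Wildcard]


def element_matches(element: PatternElement, ch: str) -> bool:
    """Position-wise element test, with the conservative 'X' policy.

    'X' satisfies only wildcards: it cannot prove identity (fixed/inclusion)
    and cannot prove it is outside an exclusion class.
    """
    if isinstance(element, Wildcard):
        return True
    if ch == UNKNOWN:
        return False
    if isinstance(element, Fixed):
        return ch == element.residue
    if isinstance(element, Inclusion):
        return ch in element.residues
    return ch not in element.residues


@dataclass(frozen=True)
class AnchoredPattern:
    """An ordered list of position elements plus a C-terminal anchor flag."""

    elements: tuple[PatternElement, ...]
    anchored: bool
    source_text: str | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))
        if not self.elements:
            raise ValueError("pattern must have at least one element")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def prosite(self) -> str:
        return serialize_prosite(self)

    @property
    def regex(self) -> str:
        return pattern_to_regex_text(self)


_REPEAT_RE = re.compile(r"^(.*)\((\d+)\)$")


def _parse_element(token: str, position: int) -> list[PatternElement]:
    repeat = 1
    m = _REPEAT_RE.match(token)
    if m:
        token, repeat = m.group(1), int(m.group(2))
        if token != "x":
            raise PrositeParseError(
                f"repetition shorthand '(n)' is only supported on 'x', got {token!r}", position
            )
        if repeat < 1:
            raise PrositeParseError("repetition count must be >= 1", position)
    if token == "x":
        return [Wildcard()] * repeat
    if token.startswith("["):
        if not token.endswith("]"):
            raise PrositeParseError(f"unbalanced '[' in {token!r}", position)
        body = token[1:-1]
        if not body:
            raise PrositeParseError("empty inclusion class '[]'", position)
        try:
            return [Inclusion(frozenset(body))]
        except ValueError as exc:
            raise PrositeParseError(str(exc), position) from None
    if token.startswith("{"):
        if not token.endswith("}"):
            raise PrositeParseError(f"unbalanced '{{' in {token!r}", position)
        body = token[1:-1]
        if not body:
            raise PrositeParseError("empty exclusion class '{}'", position)
        try:
            return [Exclusion(frozenset(body))]
        except ValueError as exc:
            raise PrositeParseError(str(exc), position) from None
    if len(token) == 1 and token in AA_SET:
        return [Fixed(token)]
    raise PrositeParseError(f"unknown element {token!r}", position)


def parse_prosite(text: str) -> AnchoredPattern:
    """Parse a Prosite-syntax pattern string into an :class:`AnchoredPattern`."""
    source = text
    text = text.strip().rstrip(".")
    if not text:
        raise PrositeParseError("empty pattern", 0)
    if text.startswith("<"):
        raise PrositeParseError(
            "N-terminal anchor '<' is not supported (only C-terminal patterns)", 1
        )
    anchored = text.endswith(">")
    if anchored:
        text = text[:-1]
    if not text:
        raise PrositeParseError("pattern has an anchor but no elements", 0)
    elements: list[PatternElement] = []
    for position, token in enumerate(text.split("-"), start=1):
        if not token:
            raise PrositeParseError("empty element (stray '-')", position)
        if "<" in token or ">" in token:
            raise PrositeParseError(f"misplaced anchor character in {token!r}", position)
        elements.extend(_parse_element(token, position))
    return AnchoredPattern(tuple(elements), anchored, source_text=source)


def _render(element: PatternElement) -> str:
    # Class residues render in alphabetical order (the canonical order here).
    if isinstance(element, Fixed):
        return element.residue
    if isinstance(element, Inclusion):
        return "[" + "".join(sorted(element.residues)) + "]"
    if isinstance(element, Exclusion):
        return "{" + "".join(sorted(element.residues)) + "}"
    return "x"


def serialize_prosite(pattern: AnchoredPattern) -> str:
    """Render a pattern as Prosite text (expanded, no '(n)' shorthand)."""
    out = "-".join(_render(e) for e in pattern.elements)
    return out + ">" if pattern.anchored else out


def pattern_to_regex_text(pattern: AnchoredPattern) -> str:
    """Render a pattern as an anchored textual regular expression."""
    parts: list[str] = []
    for e in pattern.elements:
        if isinstance(e, Fixed):
            parts.append(e.residue)
        elif isinstance(e, Inclusion):
            parts.append("[" + "".join(sorted(e.residues)) + "]")
        elif isinstance(e, Exclusion):
            parts.append("[^" + "".join(sorted(e.residues)) + "]")
        else:
            parts.append(".")
    return "".join(parts) + ("$" if pattern.anchored else "")


def read_pattern_file(path: str | Path) -> list[AnchoredPattern]:
    """Read patterns from a text file: one Prosite pattern per line, '#' comments."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append(parse_prosite(line))
    return patterns
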