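"""NtC-string motif patterns and the tetraloop scanner.

Motif patterns are hyphen-separated elements, one per step; each element
is a slash-separated list of alternatives.  A token is either an exact
four-character class name (``OP03``), a two-letter family wildcard
(``AAxx`` — any class starting with those two letters), or ``NANT``.
Example: ``OP03/OP04-AAxx-AAxx-AA05`` matches a four-step window opening
with an open conformer and closing with AA05, the pattern characteristic
of GNRA tetraloops plus their closing step.

An optional IUPAC base-sequence constraint (alphabet A, C, G, U/T, R, Y,
N; U and T equivalent) applies to the n+1 bases underlying an n-step
window — e.g. ``NGNRAN`` selects the hexanucleotides embedding a GNRA
tetraloop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .classify import AssignmentResult

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "SequenceConstraint",
    "PatternSyntaxError",
    "parse_pattern",
    "find_motifs",
    "tetraloop_scan",
    "HELICAL_FAMILIES",
]

#: NtC families whose steps build ordinary double helix.
HELICAL_FAMILIES = ("AA", "AB", "BA", "BB")

_EXACT_RE = re.compile(r"^[A-Z0-9]{4}$")
_WILD_RE = re.compile(r"^([A-Z]{2})xx$")

_IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("UT"), "T": frozenset("UT"),
    "R": frozenset("AG"), "Y": frozenset("CUT"),
    "N": frozenset("ACGUT"),
}


class PatternSyntaxError(ValueError):
    """Raised for malformed motif-pattern text."""


@dataclass(frozen=True)
class MotifToken:
    """One admissible token: exact class name or two-letter family."""

    text: str
    family: Optional[str] = None  # set for wildcard tokens

    def matches(self, ntc: str) -> bool:
        if self.family is not None:
            return ntc.startswith(self.family)
        return ntc == self.text


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of elements, each a tuple of alternative tokens."""

    elements: Tuple[Tuple[MotifToken, ...], ...]
    text: str = ""

    def __len__(self) -> int:
        return len(self.elements)

    def element_matches(self, index: int, ntc: str) -> bool:
        return any(tok.matches(ntc) for tok in self.elements[index])


@dataclass(frozen=True)
class SequenceConstraint:
    """IUPAC base pattern over the n+1 bases of an n-step window."""

    pattern: str

    def __post_init__(self) -> None:
        bad = [c for c in self.pattern if c.upper() not in _IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC symbols in sequence constraint: {bad}")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, bases: str) -> bool:
        if len(bases) != len(self.pattern):
            return False
        return all(
            b.upper() in _IUPAC[p.upper()]
            for b, p in zip(bases, self.pattern)
        )


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence along a chain annotation."""

    chain_id: str
    start_index: int
    matched_classes: Tuple[str, ...]
    matched_sequence: str


def _parse_token(token: str, position: int) -> MotifToken:
    m = _WILD_RE.match(token)
    if m:
        return MotifToken(text=token, family=m.group(1))
    if token == "NANT" or _EXACT_RE.match(token):
        return MotifToken(text=token)
    raise PatternSyntaxError(f"malformed token {token!r} at element {position}")


def parse_pattern(text: str) -> MotifPattern:
    """Parse motif text like ``OP03/OP04-AAxx-AAxx-AA05``."""
    raw_elements = text.strip().split("-")
    if not raw_elements or raw_elements == [""]:
        raise PatternSyntaxError("empty pattern")
    elements = []
    for pos, raw in enumerate(raw_elements):
        alts = [a for a in raw.split("/")]
        if not alts or any(not a for a in alts):
            raise PatternSyntaxError(f"empty alternative at element {pos}")
        elements.append(tuple(_parse_token(a, pos) for a in alts))
    return MotifPattern(elements=tuple(elements), text=text)


def _window_bases(assignments: Sequence[AssignmentResult], start: int, nsteps: int) -> str:
    # n consecutive steps span n+1 bases; consecutive steps share a base
    bases = [assignments[start].sequence[0]]
    for k in range(nsteps):
        bases.append(assignments[start + k].sequence[1])
    return "".join(bases)


def find_motifs(
    annotation: Sequence[AssignmentResult],
    pattern: MotifPattern,
    constraint: Optional[SequenceConstraint] = None,
    chain_id: str = "",
) -> List[MotifMatch]:
    """All (possibly overlapping) windows matching the pattern.

    The annotation must be ordered and contiguous along one chain; the
    caller is responsible for not concatenating across chain breaks.
    """
    n = len(pattern)
    matches: List[MotifMatch] = []
    for start in range(len(annotation) - n + 1):
        window = annotation[start:start + n]
        if not all(pattern.element_matches(i, a.ntc) for i, a in enumerate(window)):
            continue
        bases = _window_bases(annotation, start, n)
        if constraint is not None and not constraint.matches(bases):
            continue
        matches.append(
            MotifMatch(
                chain_id=chain_id,
                start_index=start,
                matched_classes=tuple(a.ntc for a in window),
                matched_sequence=bases,
            )
        )
    return matches


def _is_double_helical(classes: Sequence[str]) -> bool:
    return all(c[:2] in HELICAL_FAMILIES for c in classes)


def tetraloop_scan(
    annotation: Sequence[AssignmentResult],
    loop_kind: str = "GNRA",
    chain_id: str = "",
) -> List[Tuple[MotifMatch, str]]:
    """Scan for N-GNRA-N / N-UNCG-N hexanucleotide windows.

    Every window of six consecutive bases (five consecutive steps) whose
    sequence matches the flanked tetraloop pattern is returned with its
    five NtC names and a flag: ``"double-helical"`` when all five classes
    belong to the helix-forming families (AA, AB, BA, BB), otherwise
    ``"non-trivial"`` — the windows of structural interest.
    """
    if loop_kind not in ("GNRA", "UNCG"):
        raise ValueError("loop_kind must be GNRA or UNCG")
    constraint = SequenceConstraint("N" + loop_kind + "N")
    results: List[Tuple[MotifMatch, str]] = []
    nsteps = 5
    for start in range(len(annotation) - nsteps + 1):
        bases = _window_bases(annotation, start, nsteps)
        if not constraint.matches(bases):
            continue
        classes = tuple(a.ntc for a in annotation[start:start + nsteps])
        flag = "double-helical" if _is_double_helical(classes) else "non-trivial"
        results.append(
            (
                MotifMatch(
                    chain_id=chain_id,
                    start_index=start,
                    matched_classes=classes,
                    matched_sequence=bases,
                ),
                flag,
            )
        )
    return results
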