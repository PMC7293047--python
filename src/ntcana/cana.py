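"""The CANA structural alphabet.

CANA (Conformational Alphabet of Nucleic Acids) groups the geometry-
defined NtC conformer classes into 14 structurally defined three-letter
codes — AAA, AAw, AAu, A-B, B-A, BBB, BBw, B12, BB2, miB, ICL, OPN, SYN,
ZZZ — plus NAN for unclassified steps (the single NtC NANT).  The codes
give a compact symbolic annotation of a chain: A-form and B-form double
helix, their torsion-switched and bridging variants, BII substates,
intercalation-capable steps (ICL), open unstacked steps (OPN), syn-base
steps (SYN) and Z-form steps (ZZZ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .classify import AssignmentResult, ClassTable

__all__ = [
    "CANA_CODES",
    "CanaMapping",
    "PartitionReport",
    "load_mapping",
    "mapping_from_table",
    "cana_of",
    "annotate_chain",
    "validate_partition",
]

#: The 15 CANA codes: 14 structurally defined plus NAN.
CANA_CODES = (
    "AAA", "AAw", "AAu", "A-B", "B-A", "BBB", "BBw", "B12", "BB2",
    "miB", "ICL", "OPN", "SYN", "ZZZ", "NAN",
)


class CanaLookupError(KeyError):
    """Raised when a class name has no CANA code in a mapping."""


@dataclass
class CanaMapping:
    """NtC-class-name -> CANA-code mapping; NANT always maps to NAN."""

    assignment: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignment.setdefault("NANT", "NAN")
        bad = {
            (ntc, code) for ntc, code in self.assignment.items()
            if code not in CANA_CODES
        }
        if bad:
            raise ValueError(f"unknown CANA codes in mapping: {sorted(bad)}")
        if self.assignment["NANT"] != "NAN":
            raise ValueError("NANT must map to NAN")
        wrong_nan = [
            ntc for ntc, code in self.assignment.items()
            if code == "NAN" and ntc != "NANT"
        ]
        if wrong_nan:
            raise ValueError(f"only NANT may map to NAN, got: {sorted(wrong_nan)}")

    def __len__(self) -> int:
        return len(self.assignment)

    def __contains__(self, ntc: str) -> bool:
        return ntc in self.assignment


def load_mapping(path) -> CanaMapping:
    """Read a two-column (ntc, cana) delimited text file."""
    df = pd.read_csv(Path(path), sep=None, engine="python", comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: expected two columns (ntc, cana)")
    assignment = dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))
    return CanaMapping(assignment=assignment)


def mapping_from_table(table: ClassTable) -> CanaMapping:
    """Derive the mapping from the cana column of a class table."""
    return CanaMapping(assignment={c.name: c.cana for c in table.classes})


def cana_of(ntc: str, mapping: CanaMapping) -> str:
    """The CANA code of a class name (NANT -> NAN)."""
    try:
        return mapping.assignment[ntc]
    except KeyError:
        raise CanaLookupError(f"class {ntc!r} has no CANA code") from None


def annotate_chain(assignments: Sequence[AssignmentResult], mapping: CanaMapping | None = None) -> str:
    """Hyphen-joined CANA string for an ordered list of assignments.

    Without an explicit mapping the codes recorded on the assignments
    themselves are used.
    """
    if mapping is None:
        return "-".join(a.cana for a in assignments)
    return "-".join(cana_of(a.ntc, mapping) for a in assignments)


@dataclass
class PartitionReport:
    """Result of checking that a mapping partitions a class table."""

    per_code: Dict[str, int]
    orphans: List[str]
    total_defined: int

    @property
    def ok(self) -> bool:
        return not self.orphans


def validate_partition(table: ClassTable, mapping: CanaMapping) -> PartitionReport:
    """Check that every defined class has exactly one non-NAN CANA code.

    Returns per-code class counts, the list of orphan classes (present in
    the table but absent from the mapping) and the total number of
    defined classes.  The report passes only with zero orphans.
    """
    per_code: Dict[str, int] = {code: 0 for code in CANA_CODES if code != "NAN"}
    orphans: List[str] = []
    for cls in table.classes:
        code = mapping.assignment.get(cls.name)
        if code is None or code == "NAN":
            orphans.append(cls.name)
            continue
        per_code[code] += 1
    return PartitionReport(
        per_code=per_code,
        orphans=sorted(orphans),
        total_defined=len(table),
    )
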