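"""Contingency statistics for conformer count tables.

Conformer usage is compared across conditions (the 16 dinucleotide
sequences, inside/outside ligand binding sites, X-ray vs cryo-EM) with
adjusted standardized Pearson residuals,

    SPR_ij = (O_ij - E_ij) / sqrt(E_ij (1 - n_i./N) (1 - n_.j/N)),

where E_ij = n_i. n_.j / N is the independence expectation.  Under the
null each residual is approximately standard normal; |SPR| > 3 flags a
significant departure, |SPR| > 5 a stringent one.  Because a row's
residuals depend only on that row's counts and the table margins,
collapsing the remaining rows into a single "rest" row leaves them
unchanged — which is how compact published tables reproduce full-table
values.  Row-wise chi-square tests use columns-1 degrees of freedom with
critical values from the chi-square quantile function.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import AssignmentResult

__all__ = [
    "ContingencyTable",
    "ResidualTable",
    "expected_counts",
    "standardized_pearson_residuals",
    "row_chi_square",
    "build_ntc_sequence_table",
    "load_counts_csv",
    "SIGNIFICANT_SPR",
    "STRINGENT_SPR",
]

SIGNIFICANT_SPR = 3.0
STRINGENT_SPR = 5.0


class TableError(ValueError):
    """Raised for invalid contingency tables."""


@dataclass
class ContingencyTable:
    """Observed counts with row and column labels."""

    row_labels: List[str]
    col_labels: List[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise TableError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise TableError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise TableError("counts must be integral")
        self.counts = np.round(self.counts).astype(np.int64)
        if np.any(self.counts.sum(axis=1) == 0) or np.any(self.counts.sum(axis=0) == 0):
            raise TableError("table has an all-zero margin")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, label: str) -> np.ndarray:
        return self.counts[self.row_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    def collapse_rows(self, keep: Sequence[str], rest_label: str = "Rest") -> "ContingencyTable":
        """Collapse all rows not in *keep* into a single rest row."""
        keep = list(keep)
        kept_idx = [self.row_labels.index(k) for k in keep]
        rest_idx = [i for i in range(len(self.row_labels)) if i not in kept_idx]
        rows = [self.counts[i] for i in kept_idx]
        labels = list(keep)
        if rest_idx:
            rows.append(self.counts[rest_idx].sum(axis=0))
            labels.append(rest_label)
        return ContingencyTable(labels, list(self.col_labels), np.vstack(rows))


@dataclass
class ResidualTable:
    """Expectations, adjusted residuals, row chi-squares and flags."""

    table: ContingencyTable
    expected: np.ndarray
    residuals: np.ndarray
    row_chisq: np.ndarray
    df: int
    flags: np.ndarray  # 'over' / 'under' / 'ns'

    def residual(self, row: str, col: str) -> float:
        return float(
            self.residuals[self.table.row_labels.index(row),
                           self.table.col_labels.index(col)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.residuals, index=self.table.row_labels, columns=self.table.col_labels
        )


def expected_counts(t: ContingencyTable) -> np.ndarray:
    """Independence expectations E_ij = (row total)(column total)/N."""
    rows = t.counts.sum(axis=1, keepdims=True).astype(float)
    cols = t.counts.sum(axis=0, keepdims=True).astype(float)
    return rows * cols / t.total


def standardized_pearson_residuals(
    t: ContingencyTable, threshold: float = SIGNIFICANT_SPR
) -> ResidualTable:
    """Adjusted standardized Pearson residuals and significance flags."""
    e = expected_counts(t)
    n = float(t.total)
    row_share = t.counts.sum(axis=1, keepdims=True) / n
    col_share = t.counts.sum(axis=0, keepdims=True) / n
    denom = np.sqrt(e * (1.0 - row_share) * (1.0 - col_share))
    resid = (t.counts - e) / denom
    chisq = np.sum((t.counts - e) ** 2 / e, axis=1)
    flags = np.where(resid > threshold, "over", np.where(resid < -threshold, "under", "ns"))
    return ResidualTable(
        table=t,
        expected=e,
        residuals=resid,
        row_chisq=chisq,
        df=len(t.col_labels) - 1,
        flags=flags,
    )


def row_chi_square(
    t: ContingencyTable, row: str, alpha: float = 0.01
) -> Tuple[float, int, bool]:
    """Row-wise goodness-of-fit chi-square against the independence row.

    Returns (chi2, df, significant) where df = columns - 1 and the
    critical value is the upper-*alpha* chi-square quantile.
    """
    e = expected_counts(t)
    i = t.row_labels.index(row)
    if np.any(e[i] <= 0):
        raise TableError(f"row {row!r} has a zero expected cell")
    chisq = float(np.sum((t.counts[i] - e[i]) ** 2 / e[i]))
    df = len(t.col_labels) - 1
    critical = float(sps.chi2.ppf(1.0 - alpha, df))
    return chisq, df, chisq > critical


_RNA = set("ACGU")
_DNA = set("ACGT")


def build_ntc_sequence_table(
    assignments: Sequence[AssignmentResult],
) -> Tuple[ContingencyTable, int]:
    """Cross-tabulate NtC classes against the 16 dinucleotide sequences.

    Rows are the classes present (NANT included), columns the 16 ordered
    dinucleotides of the alphabet in use.  Steps whose sequence contains
    an undetermined base (N) are excluded and returned as a discard
    tally.  Mixing U- and T-containing sequences in one table is an
    error.
    """
    if not assignments:
        raise TableError("no assignments to tabulate")
    has_u = any("U" in a.sequence for a in assignments)
    has_t = any("T" in a.sequence for a in assignments)
    if has_u and has_t:
        raise TableError("mixed RNA (U) and DNA (T) sequences in one table")
    alphabet = sorted(_DNA) if has_t else sorted(_RNA)
    col_labels = [x + y for x in alphabet for y in alphabet]
    counts: Dict[str, Dict[str, int]] = {}
    discarded = 0
    for a in assignments:
        if any(b not in alphabet for b in a.sequence):
            discarded += 1
            continue
        counts.setdefault(a.ntc, {})
        counts[a.ntc][a.sequence] = counts[a.ntc].get(a.sequence, 0) + 1
    if not counts:
        raise TableError("all assignments discarded (undetermined bases)")
    row_labels = sorted(counts)
    matrix = np.array(
        [[counts[r].get(c, 0) for c in col_labels] for r in row_labels],
        dtype=np.int64,
    )
    keep_cols = matrix.sum(axis=0) > 0
    matrix = matrix[:, keep_cols]
    col_labels = [c for c, k in zip(col_labels, keep_cols) if k]
    return ContingencyTable(row_labels, col_labels, matrix), discarded


def load_counts_csv(path) -> ContingencyTable:
    """Read a count table: header of column labels, row label first."""
    df = pd.read_csv(Path(path), index_col=0, comment="#")
    return ContingencyTable(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(),
    )
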