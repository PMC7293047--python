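"""End-to-end convenience: structure file -> per-step assignment table."""

from __future__ import annotations

from typing import List, Optional, Tuple

import pandas as pd

from .classify import AssignmentResult, ClassTable, GoldenSet, assign_step
from .geometry import ANGLE_FIELDS, DISTANCE_FIELDS, StepParameters, measure_step
from .structure_io import enumerate_steps, read_structure

__all__ = ["assign_structure", "step_table_frame", "write_step_table"]


def assign_structure(
    path,
    table: ClassTable,
    golden: Optional[GoldenSet] = None,
    format: str = "auto",
    max_link: float = 2.5,
) -> List[Tuple[StepParameters, AssignmentResult]]:
    """Read a structure and assign every enumerable step.

    Returns (parameters, assignment) pairs in chain/file order.
    """
    out: List[Tuple[StepParameters, AssignmentResult]] = []
    for chain in read_structure(path, format=format):
        for raw in enumerate_steps(chain, max_link=max_link):
            params = measure_step(raw)
            out.append((params, assign_step(params, table, golden)))
    return out


def step_table_frame(
    results: List[Tuple[StepParameters, AssignmentResult]]
) -> pd.DataFrame:
    """Per-step report: id, sequence, the 12 parameters, NtC, CANA, confal."""
    rows = []
    for params, res in results:
        row = {"step_id": params.step_id, "sequence": params.sequence}
        for f in ANGLE_FIELDS:
            row[f] = round(getattr(params, f), 1)
        for f in DISTANCE_FIELDS:
            row[f] = round(getattr(params, f), 2)
        row.update(ntc=res.ntc, cana=res.cana, confal=round(res.confal, 1))
        rows.append(row)
    return pd.DataFrame(rows)


def write_step_table(
    results: List[Tuple[StepParameters, AssignmentResult]], path, sep: str = "\t"
) -> None:
    """Write the per-step report as TSV (default) or CSV."""
    step_table_frame(results).to_csv(path, sep=sep, index=False)
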