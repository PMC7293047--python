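"""Assignment of dinucleotide steps to NtC conformer classes.

Each conformer class (NtC) is defined by circular means and spreads of the
twelve step parameters.  Assignment proceeds in two stages:

1. *Voting*: every parameter whose deviation from the class mean falls
   inside a tolerance window (a multiple of the class spread, with a
   floor) casts a vote; classes reaching the vote quorum are candidates.
2. *Nearest-reference selection* among the candidates, either against the
   labelled golden-set members (preferred) or against class centroids,
   using a circularity-aware Euclidean metric in which the NN and C'C'
   distances are brought to the scale of the torsions by a multiplicative
   factor (default 32 degrees per angstrom).

Steps with no candidate class are reported as NANT (not-a-NtC).  The
geometric quality of the match is summarized by the *confal* score: one
0-100 value per parameter from a Gaussian kernel in deviation/spread,
combined by the harmonic mean, whose sensitivity to a single poor
parameter is the point — one gross outlier crushes the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import (
    ANGLE_FIELDS,
    DISTANCE_FIELDS,
    PARAMETER_FIELDS,
    StepParameters,
    circular_difference,
    normalize_angle,
)

__all__ = [
    "NtCClassDefinition",
    "ClassTable",
    "GoldenSet",
    "AssignmentResult",
    "ClassTableError",
    "load_class_table",
    "write_class_table",
    "step_distance",
    "deviations",
    "parameter_votes",
    "assign_step",
    "confal_parameter_score",
    "confal_step_score",
    "torsion_rmsd",
    "cartesian_rmsd",
    "DEFAULT_SCALING",
    "ANGLE_FLOOR",
    "DISTANCE_FLOOR",
]

#: Degrees per angstrom used to place NN and C'C' on the torsion scale.
DEFAULT_SCALING = 32.0
#: Vote-window floors: a parameter always tolerates at least this much.
ANGLE_FLOOR = 15.0      # degrees
DISTANCE_FLOOR = 0.5    # angstroms
#: Per-parameter confal scores are clamped below at this value so the
#: harmonic mean stays defined while a gross outlier still dominates it.
CONFAL_CLAMP = 1e-4

_N_ANGLES = len(ANGLE_FIELDS)


class ClassTableError(ValueError):
    """Raised for malformed or inconsistent class-definition tables."""


@dataclass(frozen=True)
class NtCClassDefinition:
    """One conformer class: name, CANA code, 12 means and 12 spreads."""

    name: str
    cana: str
    means: StepParameters
    spreads: Tuple[float, ...]
    member_count: int = 0

    def __post_init__(self) -> None:
        if len(self.spreads) != 12:
            raise ClassTableError(f"{self.name}: expected 12 spreads")
        if any(s <= 0 for s in self.spreads):
            raise ClassTableError(f"{self.name}: spreads must be strictly positive")
        if self.member_count < 0:
            raise ClassTableError(f"{self.name}: negative member count")


@dataclass
class ClassTable:
    """A set of conformer classes plus the assignment-protocol knobs."""

    classes: List[NtCClassDefinition]
    scaling: float = DEFAULT_SCALING
    vote_quorum: int = 11
    tolerance_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.scaling <= 0:
            raise ClassTableError("scaling must be positive")
        if not 0 <= self.vote_quorum <= 12:
            raise ClassTableError("vote_quorum must be in [0, 12]")
        if self.tolerance_multiplier <= 0:
            raise ClassTableError("tolerance_multiplier must be positive")
        names = [c.name for c in self.classes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ClassTableError(f"duplicate class names: {sorted(dupes)}")
        self._by_name = {c.name: c for c in self.classes}

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, name: str) -> NtCClassDefinition:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> List[str]:
        return [c.name for c in self.classes]


@dataclass
class GoldenSet:
    """Class-labelled reference steps anchoring nearest-member assignment."""

    members: List[Tuple[StepParameters, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def validate_against(self, table: ClassTable) -> None:
        unknown = {name for _, name in self.members if name not in table}
        if unknown:
            raise ClassTableError(f"golden-set classes not in table: {sorted(unknown)}")

    def by_class(self) -> Dict[str, List[StepParameters]]:
        out: Dict[str, List[StepParameters]] = {}
        for params, name in self.members:
            out.setdefault(name, []).append(params)
        return out


@dataclass
class AssignmentResult:
    """Outcome of assigning one step: class, CANA code, diagnostics."""

    step_id: str
    ntc: str
    cana: str
    distance: float
    nearest_class: str
    votes: int
    confal_components: Tuple[float, ...]
    confal: float
    torsion_rmsd: float
    cartesian_rmsd: Optional[float] = None
    sequence: str = "NN"

    @property
    def is_assigned(self) -> bool:
        return self.ntc != "NANT"


# ---------------------------------------------------------------------------
# class-table I/O

_TABLE_COLUMNS = (
    ["name", "cana"]
    + ["d1", "e1", "z1", "a2", "b2", "g2", "d2", "ch1", "ch2", "mu", "nn", "cc"]
    + ["sd_d1", "sd_e1", "sd_z1", "sd_a2", "sd_b2", "sd_g2", "sd_d2",
       "sd_ch1", "sd_ch2", "sd_mu", "sd_nn", "sd_cc"]
)


def load_class_table(
    path,
    scaling: float = DEFAULT_SCALING,
    vote_quorum: int = 11,
    tolerance_multiplier: float = 3.0,
) -> ClassTable:
    """Load a class-definition table from delimited text.

    Expected header: ``name,cana,d1,...,cc,sd_d1,...,sd_cc`` with angles
    in degrees on [0, 360) and distances in angstroms.  Comma, tab and
    semicolon delimiters are accepted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ClassTableError(f"cannot read class table {path}: {exc}") from exc
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ClassTableError(f"{path}: missing columns {missing}")
    classes: List[NtCClassDefinition] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            values = [float(getattr(row, c)) for c in _TABLE_COLUMNS[2:14]]
            spreads = tuple(float(getattr(row, c)) for c in _TABLE_COLUMNS[14:])
            values[:_N_ANGLES] = [float(normalize_angle(v)) for v in values[:_N_ANGLES]]
            means = StepParameters.from_vector(values, step_id=str(row.name))
            classes.append(
                NtCClassDefinition(
                    name=str(row.name), cana=str(row.cana),
                    means=means, spreads=spreads,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ClassTableError(f"{path}: malformed row {row_no}: {exc}") from exc
    return ClassTable(
        classes=classes,
        scaling=scaling,
        vote_quorum=vote_quorum,
        tolerance_multiplier=tolerance_multiplier,
    )


def write_class_table(table: ClassTable, path) -> None:
    """Write a class table in the format read by :func:`load_class_table`."""
    rows = []
    for c in table.classes:
        rows.append([c.name, c.cana] + list(c.means.vector()) + list(c.spreads))
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# the metric and the votes


def deviations(s: StepParameters, means: StepParameters) -> np.ndarray:
    """Per-parameter deviations: circular for angles, absolute for distances."""
    ang = circular_difference(s.angles(), means.angles())
    dist = np.abs(s.distances() - means.distances())
    return np.concatenate([np.atleast_1d(ang), dist])


def step_distance(a: StepParameters, b: StepParameters, scaling: float = DEFAULT_SCALING) -> float:
    """Circularity-aware Euclidean distance in the 12-parameter space.

    Angular components contribute their circular difference in degrees;
    NN and C'C' contribute their absolute difference multiplied by
    *scaling* (degrees per angstrom), so the result is in scaled degrees.
    """
    if scaling <= 0:
        raise ValueError("scaling must be positive")
    d = deviations(a, b)
    d[_N_ANGLES:] *= scaling
    return float(np.linalg.norm(d))


def _vote_windows(c: NtCClassDefinition, tolerance_multiplier: float) -> np.ndarray:
    spreads = np.asarray(c.spreads, dtype=float)
    floors = np.array([ANGLE_FLOOR] * _N_ANGLES + [DISTANCE_FLOOR] * 2)
    return np.maximum(tolerance_multiplier * spreads, floors)


def parameter_votes(
    s: StepParameters, c: NtCClassDefinition, tolerance_multiplier: float = 3.0
) -> int:
    """Number of the 12 parameters falling inside the class windows."""
    dev = deviations(s, c.means)
    return int(np.sum(dev <= _vote_windows(c, tolerance_multiplier)))


# ---------------------------------------------------------------------------
# confal


def confal_parameter_score(deviation: float, spread: float) -> float:
    """Per-parameter 0-100 match score, Gaussian in deviation/spread."""
    if spread <= 0:
        raise ValueError("spread must be positive")
    if deviation < 0:
        raise ValueError("deviation must be non-negative")
    return max(100.0 * math.exp(-(deviation ** 2) / (2.0 * spread ** 2)), CONFAL_CLAMP)


def confal_step_score(components: Sequence[float]) -> float:
    """Harmonic mean of the per-parameter confal scores."""
    comps = np.asarray(components, dtype=float)
    if np.any(comps <= 0):
        raise ValueError("confal components must be positive")
    hm = float(len(comps) / np.sum(1.0 / comps))
    return min(max(hm, CONFAL_CLAMP), 100.0)


def _confal(s: StepParameters, c: NtCClassDefinition) -> Tuple[Tuple[float, ...], float]:
    dev = deviations(s, c.means)
    comps = tuple(confal_parameter_score(d, sp) for d, sp in zip(dev, c.spreads))
    return comps, confal_step_score(comps)


# ---------------------------------------------------------------------------
# rmsd diagnostics


def torsion_rmsd(a: StepParameters, b: StepParameters) -> float:
    """RMS of circular differences over the ten angular parameters."""
    d = np.atleast_1d(circular_difference(a.angles(), b.angles()))
    return float(np.sqrt(np.mean(d ** 2)))


def cartesian_rmsd(a, b) -> float:
    """RMSD of the 18 defining atoms after least-squares superposition.

    Uses the Kabsch algorithm (SVD with determinant correction, proper
    rotations only) on the name-paired atom lists of two RawSteps.
    """
    names_a, names_b = a.atom_names(), b.atom_names()
    if len(names_a) != len(names_b):
        raise ValueError("steps have different atom counts")
    pa = np.array([at.position for at in a.atoms18], dtype=float)
    pb = np.array([at.position for at in b.atoms18], dtype=float)
    return _kabsch_rmsd(pa, pb)


def _kabsch_rmsd(pa: np.ndarray, pb: np.ndarray) -> float:
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    h = pa.T @ pb
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    diff = pa @ rot.T - pb
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def _idealized_cartesian_rmsd(a: StepParameters, b: StepParameters) -> float:
    """Cartesian rmsd between idealized rebuilds of two parameter sets.

    The 18 defining atoms of each step are reconstructed from the nine
    settable torsions with ideal bond lengths/angles, then superposed.
    Used as a diagnostic when the original coordinates of the reference
    are not available (class centroids, golden-set members stored as
    parameters only).
    """
    from .synthetic import build_step_coordinates  # deferred: avoids cycle

    ra = build_step_coordinates(_settable_torsions(a))
    rb = build_step_coordinates(_settable_torsions(b))
    pa = np.array([at.position for at in ra.atoms18], dtype=float)
    pb = np.array([at.position for at in rb.atoms18], dtype=float)
    return _kabsch_rmsd(pa, pb)


_SETTABLE = ("delta1", "epsilon1", "zeta1", "alpha2", "beta2", "gamma2",
             "delta2", "chi1", "chi2")


def _settable_torsions(s: StepParameters) -> Dict[str, float]:
    return {k: getattr(s, k) for k in _SETTABLE}


# ---------------------------------------------------------------------------
# assignment


def assign_step(
    s: StepParameters,
    table: ClassTable,
    golden: Optional[GoldenSet] = None,
    compute_cartesian_rmsd: bool = False,
) -> AssignmentResult:
    """Assign one step to an NtC class, or to NANT.

    Candidate classes are those reaching the vote quorum.  With a golden
    set, the winner is the class of the nearest labelled member among the
    candidates; otherwise the nearest candidate centroid wins.  Steps
    with no candidates are NANT with CANA code NAN; their diagnostics
    (nearest class, distance, confal, rmsd) are still populated against
    the geometrically nearest class.

    ``distance`` is reported in scaled-degree units: to the chosen golden
    member in golden mode, to the class centroid otherwise.
    """
    if len(table) == 0:
        raise ClassTableError("cannot assign against an empty class table")
    if golden is not None and len(golden) > 0:
        golden.validate_against(table)
    centroid_dist = {
        c.name: step_distance(s, c.means, table.scaling) for c in table.classes
    }
    votes_by_class = {
        c.name: parameter_votes(s, c, table.tolerance_multiplier)
        for c in table.classes
    }
    candidates = [n for n in table.names if votes_by_class[n] >= table.vote_quorum]
    nearest_class = min(centroid_dist, key=centroid_dist.get)

    if not candidates:
        ntc, ref_class = "NANT", nearest_class
        distance = centroid_dist[nearest_class]
        votes = votes_by_class[nearest_class]
    else:
        if golden is not None and len(golden) > 0:
            pool = [
                (step_distance(s, params, table.scaling), name)
                for params, name in golden.members
                if name in candidates
            ]
        else:
            pool = []
        if pool:
            distance, ntc = min(pool, key=lambda t: t[0])
        else:
            ntc = min(candidates, key=centroid_dist.get)
            distance = centroid_dist[ntc]
        ref_class = ntc
        votes = votes_by_class[ntc]

    ref = table[ref_class]
    comps, confal = _confal(s, ref)

    # rmsd diagnostics against the closest concrete reference geometry
    if golden is not None and len(golden) > 0:
        refs = golden.by_class().get(ref_class) or [ref.means]
        best = min(refs, key=lambda p: step_distance(s, p, table.scaling))
    else:
        best = ref.means
    t_rmsd = torsion_rmsd(s, best)
    c_rmsd = _idealized_cartesian_rmsd(s, best) if compute_cartesian_rmsd else None

    return AssignmentResult(
        step_id=s.step_id,
        ntc=ntc,
        cana="NAN" if ntc == "NANT" else table[ntc].cana,
        distance=float(distance),
        nearest_class=nearest_class,
        votes=votes,
        confal_components=comps,
        confal=confal,
        torsion_rmsd=t_rmsd,
        cartesian_rmsd=c_rmsd,
        sequence=s.sequence,
    )
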