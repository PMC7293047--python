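"""Dinucleotide step geometry.

A *step* is the near-dinucleotide fragment running from C5' of the first
nucleotide to O3' of the second.  Its conformation is summarized by twelve
geometric parameters: seven backbone torsions (delta1, epsilon1, zeta1,
alpha2, beta2, gamma2, delta2), the two glycosidic torsions (chi1, chi2),
the base-to-base pseudo-torsion mu through N1/N9(1)-C1'(1)-C1'(2)-N1/N9(2),
and the two distances NN (between the glycosidic nitrogens) and C'C'
(between the two C1' atoms).

All torsions are reported in degrees on [0, 360), which is the convention
used throughout the dinucleotide-conformer literature; helpers to convert
to the signed (-180, 180] range are provided.  Distances are in angstroms.

This module also houses the circular-arithmetic primitives (differences,
means, standard deviations) that the classifier and the class-discovery
clustering build on.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StepParameters",
    "GeometryError",
    "ANGLE_FIELDS",
    "DISTANCE_FIELDS",
    "PARAMETER_FIELDS",
    "dihedral",
    "circular_difference",
    "circular_mean",
    "circular_std",
    "normalize_angle",
    "to_signed",
    "measure_step",
    "sugar_pucker_label",
]

#: The ten angular parameters, in canonical order.
ANGLE_FIELDS = (
    "delta1", "epsilon1", "zeta1", "alpha2", "beta2",
    "gamma2", "delta2", "chi1", "chi2", "mu",
)
#: The two distance parameters, in canonical order.
DISTANCE_FIELDS = ("nn", "cc")
#: All twelve parameters, angles first.
PARAMETER_FIELDS = ANGLE_FIELDS + DISTANCE_FIELDS


class GeometryError(ValueError):
    """Raised for degenerate geometry (coincident or colinear atoms)."""


@dataclass(frozen=True)
class StepParameters:
    """The twelve geometric descriptors of one dinucleotide step."""

    delta1: float
    epsilon1: float
    zeta1: float
    alpha2: float
    beta2: float
    gamma2: float
    delta2: float
    chi1: float
    chi2: float
    mu: float
    nn: float
    cc: float
    step_id: str = ""
    sequence: str = "NN"

    def __post_init__(self) -> None:
        for name in ANGLE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} is not finite: {v!r}")
        for name in DISTANCE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative: {v!r}")

    def angles(self) -> np.ndarray:
        """The ten angular parameters as an array, canonical order."""
        return np.array([getattr(self, f) for f in ANGLE_FIELDS], dtype=float)

    def distances(self) -> np.ndarray:
        """The (NN, C'C') distance pair as an array."""
        return np.array([self.nn, self.cc], dtype=float)

    def vector(self) -> np.ndarray:
        """All twelve parameters, angles first then distances."""
        return np.concatenate([self.angles(), self.distances()])

    @classmethod
    def from_vector(
        cls, values: Sequence[float], step_id: str = "", sequence: str = "NN"
    ) -> "StepParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (12,):
            raise ValueError("expected 12 parameter values")
        kwargs = dict(zip(PARAMETER_FIELDS, values.tolist()))
        return cls(step_id=step_id, sequence=sequence, **kwargs)


def normalize_angle(angle):
    """Map an angle in degrees into [0, 360)."""
    a = np.mod(angle, 360.0)
    # np.mod(-1e-17, 360) rounds to exactly 360.0; keep the range half-open
    return np.where(a >= 360.0, 0.0, a)[()]


def to_signed(angle):
    """Map an angle in degrees into (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    return np.where(a > 180.0, a - 360.0, a)[()]


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle defined by four points, in degrees on [0, 360).

    Uses the IUPAC sign convention: looking down the p2->p3 bond, a
    clockwise rotation of p4 relative to p1 is positive.

    Raises
    ------
    GeometryError
        If consecutive points coincide or a bonded triple is colinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-12:
            raise GeometryError("coincident consecutive points in torsion")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("colinear atom triple in torsion")
    x = float(np.dot(n1, n2))
    y = float(np.dot(b2 / np.linalg.norm(b2), np.cross(n1, n2)))
    return float(normalize_angle(np.degrees(np.arctan2(y, x))))


def circular_difference(a, b):
    """Smallest absolute angular separation of *a* and *b*, in [0, 180]."""
    d = np.abs(normalize_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
    return np.minimum(d, 360.0 - d)[()]


def circular_mean(angles: Iterable[float]) -> float:
    """Circular mean via vector averaging, in degrees on [0, 360)."""
    a = np.radians(np.asarray(list(angles), dtype=float))
    if a.size == 0:
        raise ValueError("circular mean of empty sequence")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if np.hypot(s, c) < 1e-12:
        raise ValueError("circular mean undefined: zero resultant vector")
    return float(normalize_angle(np.degrees(np.arctan2(s, c))))


def circular_std(angles: Iterable[float]) -> float:
    """Circular standard deviation sqrt(-2 ln R), in degrees.

    For tightly concentrated data this approaches the ordinary standard
    deviation of the unwrapped angles.
    """
    a = np.radians(np.asarray(list(angles), dtype=float))
    if a.size == 0:
        raise ValueError("circular std of empty sequence")
    r = float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))
    r = min(r, 1.0)
    if r < 1e-12:
        return 180.0
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


# Atom quadruples for the backbone and glycosidic torsions.  Indices refer
# to the canonical 18-atom step layout (see structure_io.RawStep): atoms
# 0-7 belong to nucleotide 1, atoms 8-17 to nucleotide 2.
_A18 = {
    # residue 1
    "C5'1": 0, "C4'1": 1, "C3'1": 2, "O3'1": 3, "O4'1": 4, "C1'1": 5,
    "N1": 6, "C1": 7,
    # residue 2
    "P2": 8, "O5'2": 9, "C5'2": 10, "C4'2": 11, "C3'2": 12, "O3'2": 13,
    "O4'2": 14, "C1'2": 15, "N2": 16, "C2": 17,
}

_TORSION_QUADRUPLES = {
    "delta1": ("C5'1", "C4'1", "C3'1", "O3'1"),
    "epsilon1": ("C4'1", "C3'1", "O3'1", "P2"),
    "zeta1": ("C3'1", "O3'1", "P2", "O5'2"),
    "alpha2": ("O3'1", "P2", "O5'2", "C5'2"),
    "beta2": ("P2", "O5'2", "C5'2", "C4'2"),
    "gamma2": ("O5'2", "C5'2", "C4'2", "C3'2"),
    "delta2": ("C5'2", "C4'2", "C3'2", "O3'2"),
    "chi1": ("O4'1", "C1'1", "N1", "C1"),
    "chi2": ("O4'2", "C1'2", "N2", "C2"),
    "mu": ("N1", "C1'1", "C1'2", "N2"),
}


def measure_step(step) -> StepParameters:
    """Measure the twelve step parameters from a :class:`RawStep`.

    The torsions are taken over the atom quadruples of the standard
    fragment definition; NN is the N1/N9(1)-N1/N9(2) distance and C'C'
    the C1'(1)-C1'(2) distance.
    """
    coords = np.array([a.position for a in step.atoms18], dtype=float)
    if coords.shape != (18, 3):
        raise ValueError("step does not carry the 18 defining atoms")
    values = {}
    for name, quad in _TORSION_QUADRUPLES.items():
        pts = [coords[_A18[q]] for q in quad]
        values[name] = dihedral(*pts)
    nn = float(np.linalg.norm(coords[_A18["N1"]] - coords[_A18["N2"]]))
    cc = float(np.linalg.norm(coords[_A18["C1'1"]] - coords[_A18["C1'2"]]))
    return StepParameters(
        step_id=step.step_id,
        sequence=step.sequence,
        nn=nn,
        cc=cc,
        **values,
    )


def sugar_pucker_label(
    delta: float,
    c3_endo: tuple = (55.0, 110.0),
    c2_endo: tuple = (120.0, 175.0),
) -> str:
    """Coarse sugar-pucker label from the delta torsion.

    C3'-endo (A-form-like) and C2'-endo (B-form-like) windows are a
    descriptive convenience only; the conformer classifier never consults
    the pucker, it works directly on the twelve parameters.
    """
    d = float(normalize_angle(delta))
    if c3_endo[0] <= d <= c3_endo[1]:
        return "C3p_endo"
    if c2_endo[0] <= d <= c2_endo[1]:
        return "C2p_endo"
    return "other"
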