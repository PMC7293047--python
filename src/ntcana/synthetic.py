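"""Synthetic dinucleotide fixtures: coordinates, samples, demo tables.

Everything here exists so the whole pipeline — file parsing, step
enumeration, geometry measurement, classification, clustering and the
statistics — can be exercised end to end without any external data.

Coordinates are produced by sequential internal-coordinate construction
(the NeRF scheme: each new atom is placed from a bond length, a bond
angle and a torsion).  Only the 18 step-defining atoms plus the O4'
needed by the chi torsion are built, with ideal bond lengths and angles
from standard nucleic-acid geometry; the ribose ring is not closed,
because ring closure is irrelevant to the twelve step parameters.  The
nine settable torsions (delta1, epsilon1, zeta1, alpha2, beta2, gamma2,
delta2, chi1, chi2) are reproduced exactly by construction; mu, NN and
C'C' emerge from the geometry and are measured, not prescribed.

The demo class table is synthetic: its torsion centroids sit at
literature-typical values for A-form, B-form, bridging, open,
intercalation-like and Z-like steps, and its mu/NN/C'C' centroids are
whatever the idealized builder produces for those torsions, so that a
noise-free build at a centroid measures exactly to the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
from scipy.stats import truncnorm

from .classify import ClassTable, GoldenSet, NtCClassDefinition
from .geometry import (
    ANGLE_FIELDS,
    StepParameters,
    measure_step,
    normalize_angle,
)
from .structure_io import AtomRecord, NucleotideResidue, PolymerChain, RawStep

__all__ = [
    "IdealGeometry",
    "build_step_coordinates",
    "build_chain",
    "sample_class_instances",
    "make_demo_class_table",
    "write_synthetic_structure",
    "DEMO_TORSIONS",
    "SETTABLE_TORSIONS",
]

#: The nine torsions a caller may prescribe, in canonical order.
SETTABLE_TORSIONS = (
    "delta1", "epsilon1", "zeta1", "alpha2", "beta2", "gamma2",
    "delta2", "chi1", "chi2",
)


@dataclass(frozen=True)
class IdealGeometry:
    """Ideal bond lengths (A) and bond angles (deg) of the reduced step.

    Values follow standard nucleic-acid stereochemistry; small deviations
    from any particular dictionary are immaterial because every consumer
    of these coordinates works in torsion space.
    """

    bonds: Dict[str, float] = field(default_factory=lambda: {
        "C5'-C4'": 1.51, "C4'-C3'": 1.52, "C3'-O3'": 1.42,
        "O3'-P": 1.60, "P-O5'": 1.59, "O5'-C5'": 1.44,
        "C4'-O4'": 1.45, "O4'-C1'": 1.41, "C1'-N": 1.47, "N-C": 1.37,
    })
    angles: Dict[str, float] = field(default_factory=lambda: {
        "C5'-C4'-C3'": 115.5, "C4'-C3'-O3'": 110.0, "C3'-O3'-P": 120.0,
        "O3'-P-O5'": 104.0, "P-O5'-C5'": 121.0, "O5'-C5'-C4'": 111.0,
        "C5'-C4'-O4'": 109.5, "C4'-O4'-C1'": 109.7, "O4'-C1'-N": 108.2,
        "C1'-N-C": 122.0,
    })
    # fixed reference torsions for the two non-settable branch placements,
    # chosen to mimic a C3'-endo-like sugar so the emergent base-to-base
    # parameters land in realistic ranges
    o4_torsion: float = 240.0   # C3'-C5'-C4'-O4'
    c1_torsion: float = 100.0   # C5'-C4'-O4'-C1'
    n_torsion: float = 240.0    # C4'-O4'-C1'-N

    def __post_init__(self) -> None:
        for name, b in self.bonds.items():
            if not 1.2 <= b <= 1.8:
                raise ValueError(f"bond {name} out of range: {b}")
        for name, a in self.angles.items():
            if not 80.0 < a < 140.0:
                raise ValueError(f"angle {name} out of range: {a}")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c, with angle b-c-d and torsion a-b-c-d."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("colinear reference atoms in internal-coordinate build")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_PURINES = set("AG")


def _residue_base_atoms(letter: str) -> Tuple[str, str]:
    return ("N9", "C4") if letter.upper() in _PURINES else ("N1", "C2")


def _check_torsions(torsions: Dict[str, float]) -> Dict[str, float]:
    out = {}
    for name in SETTABLE_TORSIONS:
        if name not in torsions:
            raise ValueError(f"missing torsion {name}")
        v = float(torsions[name])
        if not np.isfinite(v) or not 0.0 <= v < 360.0:
            raise ValueError(f"torsion {name} must lie in [0, 360): {v!r}")
        out[name] = v
    return out


def _build_residue_branch(
    c5: np.ndarray, c4: np.ndarray, c3: np.ndarray,
    chi: float, geometry: IdealGeometry,
) -> Dict[str, np.ndarray]:
    g = geometry
    o4 = _place(c3, c5, c4, g.bonds["C4'-O4'"], g.angles["C5'-C4'-O4'"], g.o4_torsion)
    c1 = _place(c5, c4, o4, g.bonds["O4'-C1'"], g.angles["C4'-O4'-C1'"], g.c1_torsion)
    n = _place(c4, o4, c1, g.bonds["C1'-N"], g.angles["O4'-C1'-N"], g.n_torsion)
    cbase = _place(o4, c1, n, g.bonds["N-C"], g.angles["C1'-N-C"], chi)
    return {"O4'": o4, "C1'": c1, "N": n, "C": cbase}


def build_chain(
    step_torsions: Sequence[Dict[str, float]],
    bases: str = "",
    geometry: Optional[IdealGeometry] = None,
) -> PolymerChain:
    """Build an n+1-residue chain realizing n steps' torsions.

    Consecutive steps share their bridging torsions: delta1 and chi1 of
    step i (i > 0) are identified with delta2 and chi2 of step i-1, and
    any values supplied for them are ignored.  *bases* gives one letter
    per residue (default all G).
    """
    if not step_torsions:
        raise ValueError("need at least one step")
    n_res = len(step_torsions) + 1
    bases = (bases or "G" * n_res).upper()
    if len(bases) != n_res:
        raise ValueError(f"need {n_res} base letters, got {len(bases)}")
    g = geometry or IdealGeometry()
    tors = [_check_torsions(t) for t in step_torsions]

    # residue 1 backbone seed: C5' at origin, C4' on x, C3' in xy-plane
    b, ang = g.bonds, g.angles
    c5 = np.zeros(3)
    c4 = np.array([b["C5'-C4'"], 0.0, 0.0])
    theta = np.radians(180.0 - ang["C5'-C4'-C3'"])
    c3 = c4 + b["C4'-C3'"] * np.array([np.cos(theta), np.sin(theta), 0.0])

    residues: List[Dict[str, np.ndarray]] = []
    first = {"C5'": c5, "C4'": c4, "C3'": c3}
    first["O3'"] = _place(c5, c4, c3, b["C3'-O3'"], ang["C4'-C3'-O3'"], tors[0]["delta1"])
    first.update(_build_residue_branch(c5, c4, c3, tors[0]["chi1"], g))
    residues.append(first)

    for i, t in enumerate(tors):
        prev = residues[-1]
        p = _place(prev["C4'"], prev["C3'"], prev["O3'"], b["O3'-P"],
                   ang["C3'-O3'-P"], t["epsilon1"])
        o5 = _place(prev["C3'"], prev["O3'"], p, b["P-O5'"],
                    ang["O3'-P-O5'"], t["zeta1"])
        c5n = _place(prev["O3'"], p, o5, b["O5'-C5'"],
                     ang["P-O5'-C5'"], t["alpha2"])
        c4n = _place(p, o5, c5n, b["C5'-C4'"], ang["O5'-C5'-C4'"], t["beta2"])
        c3n = _place(o5, c5n, c4n, b["C4'-C3'"], ang["C5'-C4'-C3'"], t["gamma2"])
        o3n = _place(c5n, c4n, c3n, b["C3'-O3'"], ang["C4'-C3'-O3'"], t["delta2"])
        res = {"P": p, "O5'": o5, "C5'": c5n, "C4'": c4n, "C3'": c3n, "O3'": o3n}
        res.update(_build_residue_branch(c5n, c4n, c3n, t["chi2"], g))
        residues.append(res)

    out: List[NucleotideResidue] = []
    for i, (coords, letter) in enumerate(zip(residues, bases), start=1):
        n_name, c_name = _residue_base_atoms(letter)
        atoms: Dict[str, AtomRecord] = {}
        for key, pos in coords.items():
            name = {"N": n_name, "C": c_name}.get(key, key)
            element = name[0] if name[0] in "CONP" else "C"
            atoms[name] = AtomRecord(
                name=name, element=element, position=tuple(float(x) for x in pos)
            )
        out.append(
            NucleotideResidue(
                chain_id="A", residue_number=i, insertion_code="",
                residue_name=letter, base_letter=letter, atoms=atoms,
            )
        )
    return PolymerChain(chain_id="A", residues=out)


def build_step_coordinates(
    torsions: Dict[str, float],
    geometry: Optional[IdealGeometry] = None,
    bases: str = "GG",
    step_id: str = "synthetic",
) -> RawStep:
    """Build one step's 18 atoms realizing the nine settable torsions.

    The returned step measures back to the prescribed torsions within
    numerical round-off; mu, NN and C'C' are emergent.
    """
    from .structure_io import enumerate_steps  # local to keep import light

    chain = build_chain([torsions], bases=bases, geometry=geometry)
    steps = enumerate_steps(chain)
    if len(steps) != 1:  # pragma: no cover - construction guarantees linkage
        raise RuntimeError("internal-coordinate build did not produce one step")
    step = steps[0]
    step.step_id = step_id
    return step


def sample_class_instances(
    c: NtCClassDefinition,
    n: int,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> List[StepParameters]:
    """Draw step parameters around a class centroid.

    Angles come from a wrapped normal around each circular mean with
    standard deviation ``noise_scale * spread``; NN and C'C' from a
    normal truncated at zero.  Reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    rng = np.random.default_rng(seed)
    means = c.means.vector()
    spreads = np.asarray(c.spreads, dtype=float)
    n_ang = len(ANGLE_FIELDS)
    out: List[StepParameters] = []
    ang_sd = noise_scale * spreads[:n_ang]
    dist_sd = noise_scale * spreads[n_ang:]
    for k in range(n):
        angles = normalize_angle(means[:n_ang] + rng.normal(0.0, 1.0, n_ang) * ang_sd)
        if noise_scale == 0:
            dists = means[n_ang:]
        else:
            dists = np.array([
                truncnorm.rvs(
                    -m / sd, np.inf, loc=m, scale=sd, random_state=rng
                ) if sd > 0 else m
                for m, sd in zip(means[n_ang:], dist_sd)
            ])
        vec = np.concatenate([np.atleast_1d(angles), dists])
        out.append(StepParameters.from_vector(vec, step_id=f"{c.name}:{k}"))
    return out


#: Torsion centroids of the demo classes (degrees).  A-form, B-form,
#: A/B bridging, open, intercalation-like and Z-like regions, in the
#: order delta1, epsilon1, zeta1, alpha2, beta2, gamma2, delta2,
#: chi1, chi2.
DEMO_TORSIONS: Dict[str, Tuple[str, Tuple[float, ...]]] = {
    "AA00": ("AAA", (83.0, 212.0, 287.0, 295.0, 173.0, 53.0, 83.0, 199.0, 199.0)),
    "BB00": ("BBB", (139.0, 187.0, 258.0, 300.0, 177.0, 44.0, 139.0, 252.0, 252.0)),
    "AB01": ("A-B", (84.0, 200.0, 290.0, 292.0, 168.0, 56.0, 145.0, 205.0, 250.0)),
    "BA01": ("B-A", (140.0, 185.0, 265.0, 288.0, 175.0, 50.0, 84.0, 250.0, 200.0)),
    "OP03": ("OPN", (84.0, 235.0, 160.0, 165.0, 140.0, 190.0, 85.0, 200.0, 65.0)),
    "IC01": ("ICL", (85.0, 225.0, 295.0, 150.0, 190.0, 175.0, 88.0, 205.0, 300.0)),
    "ZZ01": ("ZZZ", (147.0, 264.0, 75.0, 65.0, 185.0, 180.0, 95.0, 205.0, 60.0)),
}

_DEMO_ANGLE_SPREAD = 8.0   # degrees
_DEMO_DIST_SPREAD = 0.25   # angstroms


def make_demo_class_table(
    seed: int = 0,
    golden_per_class: int = 12,
    scaling: float = 32.0,
) -> Tuple[ClassTable, GoldenSet]:
    """A small synthetic class table plus a sampled golden set.

    Seven well-separated classes spanning A-like, B-like, bridging,
    open, intercalation-like and Z-like torsion regions.  The mu/NN/C'C'
    centroids are measured from noise-free idealized builds of the
    torsion centroids, so a built centroid scores confal 100 exactly.
    Golden-set members are sampled at a quarter of the class spreads.
    """
    classes: List[NtCClassDefinition] = []
    spreads = tuple([_DEMO_ANGLE_SPREAD] * 10 + [_DEMO_DIST_SPREAD] * 2)
    for name, (cana, torsions) in DEMO_TORSIONS.items():
        tdict = dict(zip(SETTABLE_TORSIONS, torsions))
        step = build_step_coordinates(tdict, step_id=name)
        means = measure_step(step)
        classes.append(
            NtCClassDefinition(name=name, cana=cana, means=means, spreads=spreads)
        )
    table = ClassTable(classes=classes, scaling=scaling)
    members: List[Tuple[StepParameters, str]] = []
    for i, c in enumerate(table.classes):
        for params in sample_class_instances(
            c, golden_per_class, noise_scale=0.25, seed=seed * 1009 + i
        ):
            members.append((params, c.name))
    return table, GoldenSet(members)


def write_synthetic_structure(
    step_torsions: Sequence[Dict[str, float]],
    path,
    format: str = "mmcif",
    bases: str = "",
    chain_id: str = "A",
    geometry: Optional[IdealGeometry] = None,
) -> Path:
    """Write a single-chain structure realizing the given step torsions.

    The file round-trips through the reader, step enumeration and
    measurement to the prescribed torsions within file precision
    (coordinates are written at 0.001 A).
    """
    if format not in ("mmcif", "pdb"):
        raise ValueError("format must be mmcif or pdb")
    chain = build_chain(step_torsions, bases=bases, geometry=geometry)
    st = gemmi.Structure()
    st.name = "synthetic dinucleotide chain"
    model = gemmi.Model(1)
    gchain = gemmi.Chain(chain_id)
    for res in chain.residues:
        gres = gemmi.Residue()
        gres.name = res.residue_name
        gres.seqid = gemmi.SeqId(res.residue_number, ' ')
        gres.het_flag = 'A'
        for atom in res.atoms.values():
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = 1.0
            ga.b_iso = 10.0
            gres.add_atom(ga)
        gchain.add_residue(gres)
    model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    try:
        if format == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except OSError as exc:
        raise OSError(f"cannot write structure to {path}: {exc}") from exc
    return path
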