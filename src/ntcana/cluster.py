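"""Discovery of conformer classes by circularity-aware clustering.

Candidate classes are found by agglomerative hierarchical clustering of
step parameters using the same circular 12-dimensional metric as the
classifier (distances scaled to the torsion scale), computed into a full
distance matrix beforehand.  The dendrogram is cut at a user-chosen
height; clusters reaching a minimum population (default 8 members) are
harvested into candidate classes with circular centroids and spreads.
An iterative growth step then absorbs unassigned steps whose geometry
fits an existing class well, producing a self-consistent golden set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .classify import (
    ClassTable,
    GoldenSet,
    NtCClassDefinition,
    assign_step,
    step_distance,
    DEFAULT_SCALING,
)
from .geometry import (
    ANGLE_FIELDS,
    PARAMETER_FIELDS,
    StepParameters,
    circular_mean,
    circular_std,
)

__all__ = [
    "CandidateClass",
    "circular_distance_matrix",
    "agglomerate",
    "harvest_classes",
    "candidate_to_definition",
    "iterate_golden_set",
    "MIN_CLASS_SIZE",
]

#: Minimum population for a cluster to seed a candidate class.
MIN_CLASS_SIZE = 8
#: Spreads of degenerate (zero-variance) clusters are floored here.
_SPREAD_EPS_ANGLE = 0.5   # degrees
_SPREAD_EPS_DIST = 0.02   # angstroms

_N_ANGLES = len(ANGLE_FIELDS)


@dataclass
class CandidateClass:
    """A harvested cluster: members, circular centroid, spreads."""

    members: List[StepParameters]
    centroid: StepParameters
    spreads: Tuple[float, ...]

    def __len__(self) -> int:
        return len(self.members)


def circular_distance_matrix(
    steps: Sequence[StepParameters], scaling: float = DEFAULT_SCALING
) -> np.ndarray:
    """Symmetric pairwise step-distance matrix with zero diagonal."""
    if len(steps) < 2:
        raise ValueError("need at least two steps for a distance matrix")
    vecs = np.array([s.vector() for s in steps], dtype=float)
    ang = vecs[:, :_N_ANGLES]
    dist = vecs[:, _N_ANGLES:] * scaling
    # circular differences for all pairs, vectorized
    d_ang = np.abs(ang[:, None, :] - ang[None, :, :]) % 360.0
    d_ang = np.minimum(d_ang, 360.0 - d_ang)
    d_dist = dist[:, None, :] - dist[None, :, :]
    sq = (d_ang ** 2).sum(axis=2) + (d_dist ** 2).sum(axis=2)
    out = np.sqrt(sq)
    np.fill_diagonal(out, 0.0)
    return out


def agglomerate(
    matrix: np.ndarray,
    linkage_method: str = "average",
    cut_height: float = 0.0,
) -> List[List[int]]:
    """Cut an agglomerative dendrogram at a height; return index sets.

    The dendrogram is built from the precomputed distance matrix with
    the requested linkage (average, complete or single) and cut at
    *cut_height*; the returned clusters are disjoint and cover all
    indices, ordered by first member.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if linkage_method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    condensed = squareform(matrix, checks=False)
    tree = linkage(condensed, method=linkage_method)
    labels = fcluster(tree, t=cut_height, criterion="distance")
    clusters: Dict[int, List[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx)
    return sorted(clusters.values(), key=lambda c: c[0])


def _circular_centroid(members: Sequence[StepParameters]) -> Tuple[StepParameters, Tuple[float, ...]]:
    vecs = np.array([m.vector() for m in members], dtype=float)
    means: List[float] = []
    spreads: List[float] = []
    for j, name in enumerate(PARAMETER_FIELDS):
        col = vecs[:, j]
        if j < _N_ANGLES:
            means.append(circular_mean(col))
            spreads.append(max(circular_std(col), _SPREAD_EPS_ANGLE))
        else:
            means.append(float(col.mean()))
            spreads.append(max(float(col.std(ddof=0)), _SPREAD_EPS_DIST))
    return StepParameters.from_vector(means), tuple(spreads)


def harvest_classes(
    clusters: Sequence[Sequence[int]],
    steps: Sequence[StepParameters],
    min_size: int = MIN_CLASS_SIZE,
) -> List[CandidateClass]:
    """Candidate classes from clusters of at least *min_size* members."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    out: List[CandidateClass] = []
    for cluster in clusters:
        if len(cluster) < min_size:
            continue
        members = [steps[i] for i in cluster]
        centroid, spreads = _circular_centroid(members)
        out.append(CandidateClass(members=members, centroid=centroid, spreads=spreads))
    return out


def candidate_to_definition(
    candidate: CandidateClass, name: str, cana: str = "OPN"
) -> NtCClassDefinition:
    """Promote a harvested candidate to a class-table definition."""
    return NtCClassDefinition(
        name=name,
        cana=cana,
        means=candidate.centroid,
        spreads=candidate.spreads,
        member_count=len(candidate),
    )


def _inclusion_threshold(
    members: Sequence[StepParameters], scaling: float, factor: float
) -> float:
    """Median intra-class nearest-neighbour distance times *factor*."""
    if len(members) < 2:
        return factor * scaling  # degenerate class: permissive fallback
    nn = []
    for i, m in enumerate(members):
        best = min(
            step_distance(m, other, scaling)
            for j, other in enumerate(members) if j != i
        )
        nn.append(best)
    return factor * float(np.median(nn))


def iterate_golden_set(
    seed: GoldenSet,
    unassigned: Sequence[StepParameters],
    table: ClassTable,
    rounds: int = 5,
    inclusion_factor: float = 1.5,
) -> GoldenSet:
    """Grow a golden set by absorbing well-fitting unassigned steps.

    Per round, each remaining step is tentatively assigned; steps whose
    distance to the nearest member of their assigned class falls below
    the class's inclusion threshold (median intra-class nearest-
    neighbour distance times *inclusion_factor*) join the set.  Stops
    when a round adds nothing or *rounds* is exhausted.  The member set
    never shrinks.
    """
    seed.validate_against(table)
    members = list(seed.members)
    remaining = list(unassigned)
    for _ in range(rounds):
        by_class = GoldenSet(members).by_class()
        thresholds = {
            name: _inclusion_threshold(mlist, table.scaling, inclusion_factor)
            for name, mlist in by_class.items()
        }
        current = GoldenSet(members)
        added: List[int] = []
        for idx, s in enumerate(remaining):
            result = assign_step(s, table, current)
            if result.ntc == "NANT" or result.ntc not in by_class:
                continue
            best = min(
                step_distance(s, m, table.scaling) for m in by_class[result.ntc]
            )
            if best <= thresholds[result.ntc]:
                members.append((s, result.ntc))
                added.append(idx)
        if not added:
            break
        remaining = [s for i, s in enumerate(remaining) if i not in set(added)]
    return GoldenSet(members)
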