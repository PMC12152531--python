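"""Bound/unbound classification, unique fibril assignment, and binding scores.

A particle is bound iff its minimum distance over all fibrils of the same
micrograph is at most the threshold; when several fibrils fall within the
threshold the closest one receives the particle, so each bound particle is
assigned to exactly one fibril. The per-fibril binding score is the number
of assigned particles divided by the fibril length (particles per nm) — the
unit of all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .annotations import AnnotationSet, Fibril
from .errors import ValidationError
from .geometry import (
    BindingParameters,
    point_segment_distance_matrix,
    segment_segment_distance,
)

__all__ = [
    "BindingAssignment",
    "FibrilScore",
    "assign_particles",
    "score_fibrils",
    "crowding_filter",
]


@dataclass(frozen=True)
class BindingAssignment:
    """Classification of one particle.

    ``distance`` is the distance to the assigned fibril when bound, else the
    minimum distance over all fibrils (infinite if there are none).
    """

    particle_id: str
    status: Literal["bound", "unbound"]
    fibril_id: str | None
    distance: float


@dataclass(frozen=True)
class FibrilScore:
    """Per-fibril labelling density: bound particles per nm of fibril."""

    sample_label: str
    micrograph_id: str
    fibril_id: str
    length: float
    bound_count: int
    score: float


def assign_particles(
    annotations: AnnotationSet, params: BindingParameters
) -> list[BindingAssignment]:
    """Classify every particle and assign bound particles to their closest fibril.

    The threshold comparison is inclusive (distance == threshold counts as
    bound) and exact equidistance between fibrils is broken in favour of the
    first fibril in file order.
    """
    particles = annotations.particles
    fibrils = annotations.fibrils
    if not particles:
        return []
    if not fibrils:
        return [
            BindingAssignment(p.particle_id, "unbound", None, float("inf"))
            for p in particles
        ]

    dist = point_segment_distance_matrix(
        np.array([p.x for p in particles]),
        np.array([p.y for p in particles]),
        np.array([f.x1 for f in fibrils]),
        np.array([f.y1 for f in fibrils]),
        np.array([f.x2 for f in fibrils]),
        np.array([f.y2 for f in fibrils]),
    )
    closest = dist.argmin(axis=1)  # first minimum on ties = file order
    min_dist = dist[np.arange(len(particles)), closest]
    threshold = params.threshold

    out = []
    for p, j, dmin in zip(particles, closest, min_dist):
        if dmin <= threshold:
            out.append(BindingAssignment(p.particle_id, "bound", fibrils[j].fibril_id, float(dmin)))
        else:
            out.append(BindingAssignment(p.particle_id, "unbound", None, float(dmin)))
    return out


def score_fibrils(
    assignments: Sequence[BindingAssignment], annotations: AnnotationSet
) -> list[FibrilScore]:
    """One score per fibril (fibrils with no bound particle score 0)."""
    known = {f.fibril_id for f in annotations.fibrils}
    counts: dict[str, int] = {fid: 0 for fid in known}
    for a in assignments:
        if a.status == "bound":
            if a.fibril_id not in known:
                raise ValidationError(
                    f"assignment references unknown fibril {a.fibril_id!r}"
                )
            counts[a.fibril_id] += 1
    return [
        FibrilScore(
            sample_label=annotations.sample_label,
            micrograph_id=annotations.meta.micrograph_id,
            fibril_id=f.fibril_id,
            length=f.length,
            bound_count=counts[f.fibril_id],
            score=counts[f.fibril_id] / f.length,
        )
        for f in annotations.fibrils
    ]


def crowding_filter(
    fibrils: Sequence[Fibril], min_separation: float
) -> list[Fibril]:
    """Drop fibrils packed closer than ``min_separation`` to a retained one.

    Emulates the annotation-time selection of sterically accessible fibrils:
    greedily keeps fibrils in file order, dropping any fibril whose minimum
    segment-to-segment distance to an already retained fibril is below
    ``min_separation``. With ``min_separation == 0`` the input is returned
    unchanged.
    """
    if min_separation < 0:
        raise ValidationError("min_separation must be >= 0")
    if min_separation == 0:
        return list(fibrils)
    kept: list[Fibril] = []
    for f in fibrils:
        if all(segment_segment_distance(f, k) >= min_separation for k in kept):
            kept.append(f)
    return kept
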