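"""Geometric primitives for particle-fibril co-localization.

Fibrils are straight line segments in the micrograph plane; gold particles
are represented by their centre coordinates. A particle counts as bound to a
fibril when the shortest distance from its centre to the fibril axis is at
most the binding threshold

    threshold = r + a + d/2

where ``r`` is the gold-particle radius, ``a`` the span of the
primary + secondary antibody complex, and ``d`` the fibril width, all in nm.
With the defaults (r = 5 nm, a = 30 nm, d = 17 nm) the threshold is 43.5 nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from shapely.geometry import LineString

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .annotations import Fibril

__all__ = [
    "BindingParameters",
    "binding_threshold",
    "point_segment_distance",
    "point_segment_distance_matrix",
    "segment_segment_distance",
]


@dataclass(frozen=True)
class BindingParameters:
    """Physical sizes (nm) that define the binding threshold.

    Parameters
    ----------
    r : float
        Gold-particle radius in nm (measured on the micrographs).
    a : float
        Length of the primary + secondary antibody complex in nm.
    d : float
        Fibril width in nm; the threshold uses the half-width ``d/2``
        because distances are measured to the fibril axis.
    """

    r: float = 5.0
    a: float = 30.0
    d: float = 17.0

    def __post_init__(self) -> None:
        for name in ("r", "a", "d"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"binding parameter {name!r} must be finite and >= 0, got {value!r}"
                )

    @property
    def threshold(self) -> float:
        """Maximum centre-to-axis distance (nm) at which a particle is bound."""
        return self.r + self.a + self.d / 2.0


def binding_threshold(params: BindingParameters) -> float:
    """Return the binding distance threshold ``r + a + d/2`` in nm."""
    return params.threshold


def point_segment_distance_matrix(
    px: np.ndarray,
    py: np.ndarray,
    x1: np.ndarray,
    y1: np.ndarray,
    x2: np.ndarray,
    y2: np.ndarray,
) -> np.ndarray:
    """All pairwise point-to-segment distances.

    Returns the ``(n_points, n_segments)`` matrix of shortest Euclidean
    distances between each point and each segment: the perpendicular
    distance where the orthogonal projection falls inside the segment,
    otherwise the distance to the nearer endpoint (which covers the
    "particle at the fibril end" case with no separate branch).
    """
    px = np.asarray(px, dtype=float)[:, None]
    py = np.asarray(py, dtype=float)[:, None]
    x1 = np.asarray(x1, dtype=float)[None, :]
    y1 = np.asarray(y1, dtype=float)[None, :]
    x2 = np.asarray(x2, dtype=float)[None, :]
    y2 = np.asarray(y2, dtype=float)[None, :]

    dx = x2 - x1
    dy = y2 - y1
    seg_len2 = dx * dx + dy * dy
    if np.any(seg_len2 == 0.0):
        raise ValidationError("zero-length segment in distance computation")

    # projection parameter clipped to the segment
    t = ((px - x1) * dx + (py - y1) * dy) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    cx = x1 + t * dx
    cy = y1 + t * dy
    return np.hypot(px - cx, py - cy)


def point_segment_distance(px: float, py: float, fibril: "Fibril") -> float:
    """Shortest distance (nm) from a particle centre to one fibril segment."""
    dist = point_segment_distance_matrix(
        np.array([px]),
        np.array([py]),
        np.array([fibril.x1]),
        np.array([fibril.y1]),
        np.array([fibril.x2]),
        np.array([fibril.y2]),
    )
    return float(dist[0, 0])


def segment_segment_distance(f1: "Fibril", f2: "Fibril") -> float:
    """Minimum distance (nm) between two fibril segments (0 if they cross)."""
    a = LineString([(f1.x1, f1.y1), (f1.x2, f1.y2)])
    b = LineString([(f2.x1, f2.y1), (f2.x2, f2.y2)])
    return float(a.distance(b))
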