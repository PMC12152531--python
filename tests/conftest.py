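import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import LineString, Point

from fibrilgold import AnnotationSet, BindingParameters, Fibril, MicrographMeta, Particle

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params() -> BindingParameters:
    return BindingParameters()  # r=5, a=30, d=17 -> threshold 43.5 nm


@pytest.fixture
def make_annotations():
    """Build an AnnotationSet from raw coordinate tuples."""

    def _make(particle_xy, fibril_xyxy, sample_label="s", micrograph_id="m0",
              field=10_000.0):
        particles = tuple(
            Particle(f"p{i}", float(x), float(y)) for i, (x, y) in enumerate(particle_xy)
        )
        fibrils = tuple(
            Fibril(f"f{i}", *map(float, coords)) for i, coords in enumerate(fibril_xyxy)
        )
        meta = MicrographMeta(micrograph_id, 1.0, field, field)
        return AnnotationSet(meta, particles, fibrils, sample_label)

    return _make


def shapely_point_segment_distance(px, py, fibril) -> float:
    """Independent oracle for the point-to-segment distance."""
    return float(
        Point(px, py).distance(LineString([(fibril.x1, fibril.y1), (fibril.x2, fibril.y2)]))
    )


def brute_force_assign(annotations: AnnotationSet, params: BindingParameters):
    """All-pairs assignment oracle built on shapely distances.

    Returns {particle_id: (status, fibril_id, distance)} by scanning every
    particle-fibril pair, independent of the vectorized implementation.
    """
    out = {}
    for p in annotations.particles:
        best_fid, best_d = None, float("inf")
        for f in annotations.fibrils:
            d = shapely_point_segment_distance(p.x, p.y, f)
            if d < best_d:
                best_fid, best_d = f.fibril_id, d
        if best_d <= params.threshold:
            out[p.particle_id] = ("bound", best_fid, best_d)
        else:
            out[p.particle_id] = ("unbound", None, best_d)
    return out


def random_instance(rng: np.random.Generator, n_particles=50, n_fibrils=8, extent=1000.0):
    """A random micrograph-like instance for oracle-equivalence checks."""
    n_p = int(rng.integers(1, n_particles + 1))
    n_f = int(rng.integers(1, n_fibrils + 1))
    particle_xy = rng.uniform(0, extent, size=(n_p, 2))
    fibril_xyxy = []
    while len(fibril_xyxy) < n_f:
        coords = rng.uniform(0, extent, size=4)
        if (coords[0], coords[1]) != (coords[2], coords[3]):
            fibril_xyxy.append(tuple(coords))
    return particle_xy, fibril_xyxy
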