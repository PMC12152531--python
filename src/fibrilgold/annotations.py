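"""Reading and writing micrograph annotation tables.

Annotations are the coordinates a human (or a synthetic generator) placed on
an electron micrograph: gold-particle centres and fibril start/end points.
All internal computation is in nm; tables exported in pixel units are
converted at load using the micrograph's pixel size.

CSV dialects
------------
Particles: columns ``micrograph_id`` (optional), ``particle_id`` (optional),
``x``, ``y``. Fibrils: ``micrograph_id`` (optional), ``fibril_id``
(optional), ``x1``, ``y1``, ``x2``, ``y2``. Comma-separated, header row,
UTF-8, ``.`` decimal. Annotation tools that export points as (row, col)
pairs are accommodated by ``swap_axes=True``, which swaps the two coordinate
columns at load. Ids are auto-generated (``p0, p1, ...`` / ``f0, f1, ...``)
when the id column is absent. If a ``micrograph_id`` column is present, rows
are filtered to the requested micrograph.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import yaml

from .errors import AnnotationFormatError, AnnotationParseError, ValidationError

__all__ = [
    "MicrographMeta",
    "Particle",
    "Fibril",
    "AnnotationSet",
    "read_annotations",
    "write_annotations",
    "write_scores",
    "read_scores",
    "read_config",
]

SCORE_COLUMNS = [
    "sample_label",
    "micrograph_id",
    "fibril_id",
    "length_nm",
    "bound_count",
    "score",
]


@dataclass(frozen=True)
class MicrographMeta:
    """Identity and physical calibration of one micrograph."""

    micrograph_id: str
    pixel_size: float = 1.0  # nm per pixel
    field_width: float = 10_000.0  # nm
    field_height: float = 10_000.0  # nm

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size!r}")
        if not (self.field_width > 0 and self.field_height > 0):
            raise ValidationError("field dimensions must be > 0")


@dataclass(frozen=True)
class Particle:
    """A gold particle, represented by its centre coordinates in nm."""

    particle_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"particle {self.particle_id!r} has non-finite coordinates"
            )


@dataclass(frozen=True)
class Fibril:
    """A fibril annotated as a straight segment from (x1,y1) to (x2,y2), in nm."""

    fibril_id: str
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for name in ("x1", "y1", "x2", "y2"):
            object.__setattr__(self, name, float(getattr(self, name)))
        coords = (self.x1, self.y1, self.x2, self.y2)
        if not all(math.isfinite(c) for c in coords):
            raise ValidationError(f"fibril {self.fibril_id!r} has non-finite coordinates")
        if self.length == 0.0:
            raise ValidationError(
                f"fibril {self.fibril_id!r} has coincident endpoints (zero length)"
            )

    @property
    def length(self) -> float:
        """Euclidean length of the segment, nm."""
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)


@dataclass(frozen=True)
class AnnotationSet:
    """All annotations for one micrograph, in nm."""

    meta: MicrographMeta
    particles: tuple[Particle, ...]
    fibrils: tuple[Fibril, ...]
    sample_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "particles", tuple(self.particles))
        object.__setattr__(self, "fibrils", tuple(self.fibrils))
        pids = [p.particle_id for p in self.particles]
        if len(set(pids)) != len(pids):
            dupes = sorted({i for i in pids if pids.count(i) > 1})
            raise ValidationError(f"duplicate particle ids: {dupes}")
        fids = [f.fibril_id for f in self.fibrils]
        if len(set(fids)) != len(fids):
            dupes = sorted({i for i in fids if fids.count(i) > 1})
            raise ValidationError(f"duplicate fibril ids: {dupes}")


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise AnnotationFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _numeric(df: pd.DataFrame, columns: Sequence[str], path: Path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        values = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[values.isna() & out[col].notna()]
        empty = out.index[out[col].isna()]
        problems = list(bad) + list(empty)
        if problems:
            # +2: header line plus 1-based numbering
            rows = [int(i) + 2 for i in sorted(problems)]
            raise AnnotationParseError(
                f"{path}: non-numeric value in column {col!r} at file row(s) {rows}"
            )
        # Python float() is exactly round-trip on repr output; pd.to_numeric is not
        out[col] = [float(v) for v in out[col]]
    return out


def _filter_micrograph(df: pd.DataFrame, micrograph_id: str) -> pd.DataFrame:
    if "micrograph_id" in df.columns:
        mask = df["micrograph_id"].astype(str) == micrograph_id
        if mask.any():
            return df.loc[mask]
    return df


def read_annotations(
    particles_file: str | Path,
    fibrils_file: str | Path,
    meta: MicrographMeta,
    units: Literal["pixel", "nm"] = "nm",
    sample_label: str = "",
    swap_axes: bool = False,
) -> AnnotationSet:
    """Load particle and fibril tables for one micrograph.

    Parameters
    ----------
    units
        ``"nm"`` if the tables are already in physical units, ``"pixel"``
        to multiply every coordinate by ``meta.pixel_size`` at load.
    swap_axes
        Swap the coordinate columns at load, for tools that export points
        in (row, col) order instead of (x, y).
    """
    if units not in ("pixel", "nm"):
        raise ValidationError(f"units must be 'pixel' or 'nm', got {units!r}")
    scale = meta.pixel_size if units == "pixel" else 1.0

    pdf = _read_table(particles_file, ["x", "y"])
    pdf = _filter_micrograph(pdf, meta.micrograph_id).reset_index(drop=False)
    pdf = _numeric(pdf.set_index("index"), ["x", "y"], Path(particles_file))
    pdf = pdf.reset_index(drop=True)
    if swap_axes:
        pdf[["x", "y"]] = pdf[["y", "x"]].to_numpy()
    particles = []
    for i, row in pdf.iterrows():
        pid = str(row["particle_id"]) if "particle_id" in pdf.columns and pd.notna(row.get("particle_id")) else f"p{i}"
        particles.append(Particle(pid, float(row["x"]) * scale, float(row["y"]) * scale))

    fdf = _read_table(fibrils_file, ["x1", "y1", "x2", "y2"])
    fdf = _filter_micrograph(fdf, meta.micrograph_id).reset_index(drop=False)
    fdf = _numeric(fdf.set_index("index"), ["x1", "y1", "x2", "y2"], Path(fibrils_file))
    fdf = fdf.reset_index(drop=True)
    if swap_axes:
        fdf[["x1", "y1"]] = fdf[["y1", "x1"]].to_numpy()
        fdf[["x2", "y2"]] = fdf[["y2", "x2"]].to_numpy()

    zero_rows = [
        int(i) + 2
        for i, row in fdf.iterrows()
        if row["x1"] == row["x2"] and row["y1"] == row["y2"]
    ]
    if zero_rows:
        raise ValidationError(
            f"{fibrils_file}: zero-length fibril(s) at file row(s) {zero_rows}"
        )

    fibrils = []
    for i, row in fdf.iterrows():
        fid = str(row["fibril_id"]) if "fibril_id" in fdf.columns and pd.notna(row.get("fibril_id")) else f"f{i}"
        fibrils.append(
            Fibril(
                fid,
                float(row["x1"]) * scale,
                float(row["y1"]) * scale,
                float(row["x2"]) * scale,
                float(row["y2"]) * scale,
            )
        )

    return AnnotationSet(meta=meta, particles=tuple(particles), fibrils=tuple(fibrils), sample_label=sample_label)


def write_annotations(
    annotations: AnnotationSet,
    particles_file: str | Path,
    fibrils_file: str | Path,
) -> None:
    """Write an annotation set back to the particle/fibril CSV dialect (nm)."""
    mid = annotations.meta.micrograph_id
    pd.DataFrame(
        {
            "micrograph_id": [mid] * len(annotations.particles),
            "particle_id": [p.particle_id for p in annotations.particles],
            "x": [repr(p.x) for p in annotations.particles],
            "y": [repr(p.y) for p in annotations.particles],
        }
    ).to_csv(particles_file, index=False)
    pd.DataFrame(
        {
            "micrograph_id": [mid] * len(annotations.fibrils),
            "fibril_id": [f.fibril_id for f in annotations.fibrils],
            "x1": [repr(f.x1) for f in annotations.fibrils],
            "y1": [repr(f.y1) for f in annotations.fibrils],
            "x2": [repr(f.x2) for f in annotations.fibrils],
            "y2": [repr(f.y2) for f in annotations.fibrils],
        }
    ).to_csv(fibrils_file, index=False)


def write_scores(scores: Iterable, out: str | Path) -> None:
    """Write per-fibril binding scores to CSV (one row per fibril).

    Floats are serialised with ``repr`` so a round-trip read reproduces the
    values bit-exactly. An empty score list produces a header-only file.
    """
    rows = [
        {
            "sample_label": s.sample_label,
            "micrograph_id": s.micrograph_id,
            "fibril_id": s.fibril_id,
            "length_nm": repr(float(s.length)),
            "bound_count": int(s.bound_count),
            "score": repr(float(s.score)),
        }
        for s in scores
    ]
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    try:
        df.to_csv(out, index=False)
    except OSError as exc:
        raise OSError(f"cannot write scores to {out}: {exc}") from exc


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a scores CSV back into a typed DataFrame."""
    df = _read_table(path, SCORE_COLUMNS)
    df = _numeric(df, ["length_nm", "score"], Path(path)) if len(df) else df
    if len(df):
        df["bound_count"] = pd.to_numeric(df["bound_count"]).astype(int)
    else:
        df = df.astype({"length_nm": float, "bound_count": int, "score": float}, errors="ignore")
    return df


def read_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration.

    Recognised keys include ``r_nm``, ``a_nm``, ``d_nm``, ``pixel_size_nm``,
    ``units``, ``reference_sample``, ``alpha``; unknown keys pass through.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise AnnotationFormatError(f"{path}: config must be a mapping")
    return cfg
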