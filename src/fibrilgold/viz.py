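"""Figure outputs: score violin plots and annotated-micrograph overlays.

The violin plot mirrors the standard presentation of labelling-density
comparisons: one kernel-density violin per sample, individual fibril scores
as scattered dots, a bold mean line, thin quartile lines, and significance
asterisks against the reference group. Points beyond 1.5 x IQR from the
quartiles can be excluded from the display for clarity; that rule is
display-only — every statistic is computed elsewhere on complete data and
this module never modifies a ComparisonResult.

The overlay draws each fibril as a band of width d and each particle as a
circle of radius r + a: a circle overlaps a band exactly when the
centre-to-axis distance is at most r + a + d/2, so the picture is a visual
identity of the binding rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Circle, Polygon as MplPolygon
from scipy.stats import gaussian_kde
from shapely.geometry import LineString

from .annotations import AnnotationSet
from .binding import BindingAssignment
from .errors import ValidationError
from .geometry import BindingParameters
from .stats import ComparisonResult, SampleScores

__all__ = ["PlotSpec", "display_outlier_mask", "violin_plot", "overlay_plot"]


@dataclass(frozen=True)
class PlotSpec:
    """Display options for the violin plot."""

    exclude_outliers: bool = True  # hide points beyond 1.5*IQR from quartiles
    order: tuple[str, ...] | None = None  # sample display order
    annotate: bool = True  # draw significance labels vs the reference


def display_outlier_mask(values: np.ndarray) -> np.ndarray:
    """Boolean mask of values flagged as display outliers.

    A value is an outlier when it lies below Q1 - 1.5*IQR or above
    Q3 + 1.5*IQR. Display-only: callers must never feed the mask back into
    any statistic.
    """
    values = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def _ordered(samples: Sequence[SampleScores], spec: PlotSpec) -> list[SampleScores]:
    if spec.order is None:
        return list(samples)
    by_label = {s.sample_label: s for s in samples}
    if sorted(spec.order) != sorted(by_label):
        raise ValidationError(
            f"order {list(spec.order)} is not a permutation of {sorted(by_label)}"
        )
    return [by_label[lb] for lb in spec.order]


def violin_plot(
    samples: Sequence[SampleScores],
    comparison: ComparisonResult | None = None,
    spec: PlotSpec = PlotSpec(),
    out: str | Path = "violins.png",
) -> dict:
    """Render the per-sample score distributions; return the figure metadata.

    Violins are kernel density estimates of the displayed values, clipped at
    zero (scores cannot be negative). A JSON sidecar (``<out>.json``)
    records the KDE bandwidth factor and the number of display-excluded
    points per sample so the figure is reproducible.
    """
    if not samples:
        raise ValidationError("violin_plot needs at least one sample")
    samples = _ordered(samples, spec)
    rng = np.random.default_rng(0)  # jitter only; cosmetic

    fig, ax = plt.subplots(figsize=(1.6 * len(samples) + 2, 4.5))
    meta: dict = {
        "spec": {
            "exclude_outliers": spec.exclude_outliers,
            "order": [s.sample_label for s in samples],
            "annotate": spec.annotate,
        },
        "samples": {},
    }
    half_width = 0.38
    top = 0.0
    for i, s in enumerate(samples):
        values = np.asarray(s.scores, dtype=float)
        if spec.exclude_outliers and len(values) >= 4:
            outliers = display_outlier_mask(values)
        else:
            outliers = np.zeros(len(values), dtype=bool)
        shown = values[~outliers]
        n_excluded = int(outliers.sum())
        bw = None
        if len(shown) >= 2 and np.ptp(shown) > 0:
            kde = gaussian_kde(shown)
            bw = float(kde.factor)
            lo = max(0.0, shown.min() - 2 * shown.std())
            hi = shown.max() + 2 * shown.std()
            grid = np.linspace(lo, hi, 200)
            dens = kde(grid)
            dens = dens / dens.max() * half_width
            ax.fill_betweenx(grid, i - dens, i + dens, color="#9ecae1", alpha=0.8, lw=0)
        if len(shown):
            jitter = rng.uniform(-0.08, 0.08, size=len(shown))
            ax.plot(i + jitter, shown, ".", color="#2b2b2b", ms=3, alpha=0.6, zorder=3)
            q1, q2, q3 = np.percentile(shown, [25, 50, 75])
            mean = shown.mean()
            ax.hlines(mean, i - 0.3, i + 0.3, color="#08306b", lw=2.5, zorder=4)
            ax.hlines([q1, q3], i - 0.2, i + 0.2, color="#08306b", lw=1.0, zorder=4)
            top = max(top, shown.max())
        meta["samples"][s.sample_label] = {
            "n": int(len(values)),
            "n_display_excluded": n_excluded,
            "kde_bandwidth_factor": bw,
        }

    if comparison is not None and spec.annotate and comparison.pairwise:
        idx = {s.sample_label: i for i, s in enumerate(samples)}
        y = top * 1.05 if top > 0 else 1.0
        step = 0.07 * (top if top > 0 else 1.0)
        for j, c in enumerate(comparison.pairwise):
            ia, ib = idx[c.label_a], idx[c.label_b]
            yy = y + j * step
            ax.plot([ia, ib], [yy, yy], color="0.3", lw=0.8)
            ax.text((ia + ib) / 2, yy, c.label, ha="center", va="bottom", fontsize=8)

    ax.set_xticks(range(len(samples)))
    ax.set_xticklabels([s.sample_label for s in samples], rotation=30, ha="right")
    ax.set_ylabel("binding score (gold particles per nm fibril)")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    out = Path(out)
    try:
        fig.savefig(out, dpi=200)
    except OSError as exc:
        plt.close(fig)
        raise OSError(f"cannot write figure to {out}: {exc}") from exc
    plt.close(fig)
    sidecar = out.with_suffix(out.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    return meta


def overlay_plot(
    annotations: AnnotationSet,
    assignments: Sequence[BindingAssignment],
    params: BindingParameters,
    out: str | Path,
) -> None:
    """Draw the annotation overlay encoding the binding rule geometrically.

    Fibrils appear as green bands of width d; each particle as a circle of
    radius r + a, red when bound and grey when unbound. A circle touches its
    fibril's band exactly when the particle is within the binding threshold.
    """
    fig, ax = plt.subplots(figsize=(7, 7))
    for f in annotations.fibrils:
        band = LineString([(f.x1, f.y1), (f.x2, f.y2)]).buffer(params.d / 2.0)
        ax.add_patch(
            MplPolygon(
                np.asarray(band.exterior.coords),
                closed=True,
                facecolor="#41ab5d",
                edgecolor="#238b45",
                alpha=0.7,
                zorder=1,
            )
        )
    status = {a.particle_id: a.status for a in assignments}
    for p in annotations.particles:
        bound = status.get(p.particle_id) == "bound"
        ax.add_patch(
            Circle(
                (p.x, p.y),
                radius=params.r + params.a,
                fill=False,
                edgecolor="#cb181d" if bound else "0.55",
                lw=1.0 if bound else 0.6,
                zorder=2,
            )
        )
        ax.plot(p.x, p.y, ".", color="#cb181d" if bound else "0.4", ms=2, zorder=3)
    ax.set_xlim(0, annotations.meta.field_width)
    ax.set_ylim(0, annotations.meta.field_height)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: origin top-left
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.set_title(
        f"{annotations.meta.micrograph_id}: circles r+a = {params.r + params.a:g} nm, "
        f"band width d = {params.d:g} nm"
    )
    fig.tight_layout()
    fig.savefig(Path(out), dpi=200)
    plt.close(fig)
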