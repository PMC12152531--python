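"""Gated statistical comparison of per-fibril score distributions.

The comparison is a two-step procedure. A Shapiro-Wilk gate first decides
the route: if every group looks normal (p >= alpha in each group) the
parametric route is taken (one-way ANOVA, then Tukey's HSD), otherwise the
nonparametric route (Kruskal-Wallis H, then Mann-Whitney U with Bonferroni
correction). Post hoc pairwise tests run only when the omnibus test is
significant. In reference mode only the k-1 pairs involving the reference
group are tested and the Bonferroni factor shrinks accordingly.

All statistics are computed on complete data; any outlier handling in plots
is display-only and never feeds back into these numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "SampleScores",
    "PairwiseComparison",
    "ComparisonResult",
    "normality_gate",
    "omnibus_test",
    "posthoc",
    "significance_label",
    "compare_samples",
    "write_report",
]

Route = Literal["parametric", "nonparametric"]


@dataclass(frozen=True)
class SampleScores:
    """One group's per-fibril binding scores (particles per nm)."""

    sample_label: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", tuple(float(v) for v in self.scores))
        if len(self.scores) < 1:
            raise ValidationError(f"sample {self.sample_label!r} is empty")

    @property
    def n(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class PairwiseComparison:
    label_a: str
    label_b: str
    raw_p: float
    adjusted_p: float
    label: str  # ns / * / ** / ***


@dataclass(frozen=True)
class ComparisonResult:
    route: Route
    normality_p: dict[str, float]
    omnibus_name: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: tuple[PairwiseComparison, ...]
    reference: str | None
    m_comparisons: int
    posthoc_forced: bool = False

    def to_dict(self) -> dict:
        return {
            "route": self.route,
            "normality_p": dict(self.normality_p),
            "omnibus": {
                "name": self.omnibus_name,
                "statistic": self.omnibus_stat,
                "p": self.omnibus_p,
            },
            "pairwise": [
                {
                    "label_a": c.label_a,
                    "label_b": c.label_b,
                    "raw_p": c.raw_p,
                    "adjusted_p": c.adjusted_p,
                    "stars": c.label,
                }
                for c in self.pairwise
            ],
            "reference": self.reference,
            "m_comparisons": self.m_comparisons,
            "posthoc_forced": self.posthoc_forced,
        }


def _check_samples(samples: Sequence[SampleScores]) -> None:
    labels = [s.sample_label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate sample labels: {labels}")


def normality_gate(
    samples: Sequence[SampleScores], alpha: float = 0.05
) -> tuple[Route, dict[str, float]]:
    """Decide the analysis route from per-group Shapiro-Wilk tests.

    Returns ``("parametric", pvalues)`` iff every group has n >= 3 and a
    Shapiro-Wilk p >= alpha; a group with n < 3 (the test's minimum) forces
    the nonparametric route and is recorded with p = nan.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    _check_samples(samples)
    pvalues: dict[str, float] = {}
    route: Route = "parametric"
    for s in samples:
        if s.n < 3:
            pvalues[s.sample_label] = float("nan")
            route = "nonparametric"
            continue
        if len(set(s.scores)) == 1:
            # Shapiro-Wilk is undefined on a constant sample; a constant
            # group is certainly not normal for gating purposes.
            pvalues[s.sample_label] = 0.0
            route = "nonparametric"
            continue
        p = float(sps.shapiro(np.asarray(s.scores)).pvalue)
        pvalues[s.sample_label] = p
        if p < alpha:
            route = "nonparametric"
    return route, pvalues


def omnibus_test(
    samples: Sequence[SampleScores], route: Route
) -> tuple[str, float, float]:
    """One-way ANOVA (parametric) or tie-corrected Kruskal-Wallis H."""
    if len(samples) < 2:
        raise ValidationError("omnibus test needs at least 2 samples")
    groups = [np.asarray(s.scores, dtype=float) for s in samples]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError(
            "all observations identical across all groups; statistic undefined"
        )
    if route == "parametric":
        res = sps.f_oneway(*groups)
        return "one-way ANOVA", float(res.statistic), float(res.pvalue)
    res = sps.kruskal(*groups)
    return "Kruskal-Wallis H", float(res.statistic), float(res.pvalue)


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    # exact for small untied samples, asymptotic with tie correction otherwise
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(a), len(b)) <= 20
    method = "exact" if (small and not ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def posthoc(
    samples: Sequence[SampleScores],
    route: Route,
    reference: str | None = None,
    alpha: float = 0.05,
) -> tuple[list[PairwiseComparison], int]:
    """Pairwise comparisons after a significant omnibus test.

    Without a reference: all k(k-1)/2 pairs, with Tukey's HSD family-wise
    adjustment on the parametric route or Bonferroni (m = k(k-1)/2) on
    Mann-Whitney U p-values on the nonparametric route. Tukey's HSD yields
    family-wise-adjusted p-values directly, so raw and adjusted coincide on
    that route. With a reference: only the k-1 pairs involving it, and the
    Bonferroni factor is m = k-1 (pairwise t-tests on the parametric route).
    Returns the comparisons and the number of comparisons m.
    """
    _check_samples(samples)
    labels = [s.sample_label for s in samples]
    if reference is not None and reference not in labels:
        raise ValidationError(f"reference {reference!r} not among samples {labels}")
    by_label = {s.sample_label: np.asarray(s.scores, dtype=float) for s in samples}
    k = len(samples)

    if reference is None:
        pairs = list(combinations(labels, 2))
        m = k * (k - 1) // 2
    else:
        pairs = [(reference, lb) for lb in labels if lb != reference]
        m = k - 1

    out: list[PairwiseComparison] = []
    if route == "parametric" and reference is None:
        endog = np.concatenate([by_label[lb] for lb in labels])
        grp = np.concatenate([[lb] * len(by_label[lb]) for lb in labels])
        tk = pairwise_tukeyhsd(endog, grp, alpha=alpha)
        tukey_pairs = list(combinations(list(tk.groupsunique), 2))
        pmap = {frozenset(pr): float(p) for pr, p in zip(tukey_pairs, tk.pvalues)}
        for a, b in pairs:
            p = pmap[frozenset((a, b))]
            out.append(PairwiseComparison(a, b, p, p, significance_label(p)))
        return out, m

    for a, b in pairs:
        if route == "parametric":
            raw = float(sps.ttest_ind(by_label[a], by_label[b]).pvalue)
        else:
            raw = _mannwhitney_p(by_label[a], by_label[b])
        adj = min(1.0, m * raw)
        out.append(PairwiseComparison(a, b, raw, adj, significance_label(adj)))
    return out, m


def significance_label(
    adjusted_p: float, thresholds: tuple[float, float, float] = (0.05, 0.01, 0.001)
) -> str:
    """Asterisk notation: *** p<0.001, ** p<0.01, * p<0.05, else ns (strict)."""
    if not (0.0 <= adjusted_p <= 1.0):
        raise ValidationError(f"p-value outside [0,1]: {adjusted_p}")
    one, two, three = thresholds
    if adjusted_p < three:
        return "***"
    if adjusted_p < two:
        return "**"
    if adjusted_p < one:
        return "*"
    return "ns"


def compare_samples(
    samples: Sequence[SampleScores],
    reference: str | None = None,
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
    force_posthoc: bool = False,
) -> ComparisonResult:
    """Run the full gated comparison on complete data.

    Composes the normality gate, the omnibus test, and — when the omnibus
    p-value is below ``alpha`` (or ``force_posthoc`` is set, which is
    recorded in the result) — the pairwise post hoc tests.
    """
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples to compare")
    route, norm_p = normality_gate(samples, alpha=gate_alpha)
    name, stat, p = omnibus_test(samples, route)
    pairwise: list[PairwiseComparison] = []
    m = 0
    forced = False
    if p < alpha:
        pairwise, m = posthoc(samples, route, reference=reference, alpha=alpha)
    elif force_posthoc:
        pairwise, m = posthoc(samples, route, reference=reference, alpha=alpha)
        forced = True
    return ComparisonResult(
        route=route,
        normality_p=norm_p,
        omnibus_name=name,
        omnibus_stat=stat,
        omnibus_p=p,
        pairwise=tuple(pairwise),
        reference=reference,
        m_comparisons=m,
        posthoc_forced=forced,
    )


def write_report(
    result: ComparisonResult, json_path: str | Path, tsv_path: str | Path | None = None
) -> None:
    """Write the full result as JSON plus a flat TSV of the pairwise rows."""
    Path(json_path).write_text(
        json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    if tsv_path is not None:
        lines = ["label_a\tlabel_b\traw_p\tadjusted_p\tstars"]
        for c in result.pairwise:
            lines.append(
                f"{c.label_a}\t{c.label_b}\t{c.raw_p!r}\t{c.adjusted_p!r}\t{c.label}"
            )
        Path(tsv_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
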