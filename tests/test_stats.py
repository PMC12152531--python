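"""Gated group comparison: normality gate, omnibus, post hoc, labelling."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from fibrilgold import (
    SampleScores,
    compare_samples,
    normality_gate,
    omnibus_test,
    posthoc,
    significance_label,
)
from fibrilgold.errors import DegenerateDataError, ValidationError
from fibrilgold.stats import write_report


def _samples(arrays, labels=None):
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    return [SampleScores(lb, tuple(a)) for lb, a in zip(labels, arrays)]


def test_gate_parametric_on_normal_data():
    rng = np.random.default_rng(3)
    samples = _samples([rng.normal(10, 2, 50) for _ in range(4)])
    route, pvals = normality_gate(samples)
    assert route == "parametric"
    assert all(p >= 0.05 for p in pvals.values())


def test_gate_nonparametric_on_heavy_skew():
    rng = np.random.default_rng(3)
    arrays = [rng.normal(10, 2, 50) for _ in range(3)]
    arrays.append(np.exp(rng.normal(0, 1, 50)) ** 2)  # heavily right-skewed
    route, pvals = normality_gate(_samples(arrays))
    assert route == "nonparametric"
    assert pvals["g3"] < 0.05


def test_gate_small_sample_forces_nonparametric():
    samples = _samples([[1.0, 2.0], np.random.default_rng(0).normal(0, 1, 30)])
    route, pvals = normality_gate(samples)
    assert route == "nonparametric"
    assert np.isnan(pvals["g0"])


def test_gate_nonparametric_rate_under_null_matches_alpha():
    """P(any of k normal groups fails the gate) ~ 1-(1-alpha)^k."""
    k, alpha, reps = 3, 0.05, 200
    rng = np.random.default_rng(12)
    nonparam = 0
    for _ in range(reps):
        route, _ = normality_gate(
            _samples([rng.normal(0, 1, 50) for _ in range(k)]), alpha=alpha
        )
        nonparam += route == "nonparametric"
    expected = 1 - (1 - alpha) ** k
    se = np.sqrt(expected * (1 - expected) / reps)
    assert abs(nonparam / reps - expected) < 3 * se + 1e-9


def test_gate_rejects_empty_and_bad_alpha():
    with pytest.raises(ValidationError):
        SampleScores("g", ())
    with pytest.raises(ValidationError):
        normality_gate(_samples([[1.0, 2.0, 3.0]]), alpha=1.5)


def test_omnibus_identical_groups_h_zero():
    samples = _samples([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    name, stat, p = omnibus_test(samples, "nonparametric")
    assert name == "Kruskal-Wallis H"
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_omnibus_degenerate_input():
    with pytest.raises(DegenerateDataError):
        omnibus_test(_samples([[5.0, 5.0, 5.0], [5.0, 5.0]]), "parametric")


def test_omnibus_strong_shift_detected():
    rng = np.random.default_rng(8)
    arrays = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(10, 1, 30)]
    for route in ("parametric", "nonparametric"):
        _, _, p = omnibus_test(_samples(arrays), route)
        assert p < 0.001


def _rank_sum_h(x, y):
    """Independent Kruskal-Wallis H for two untied groups, from first principles."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, nx = len(pooled), len(x)
    rx, ry = ranks[:nx].sum(), ranks[nx:].sum()
    return 12 / (n * (n + 1)) * (rx**2 / nx + ry**2 / (n - nx)) - 3 * (n + 1)


def test_omnibus_two_group_matches_exact_permutation_null():
    """KW on 6+6 toy data: H matches a from-scratch rank formula and the
    chi-square p is close to the exact permutation p."""
    x = np.array([1.2, 3.4, 2.2, 5.1, 0.7, 4.0])
    y = np.array([6.3, 7.1, 5.9, 8.2, 9.0, 6.8])
    name, h, p = omnibus_test(_samples([x, y]), "nonparametric")
    assert h == pytest.approx(_rank_sum_h(x, y), rel=1e-9)

    pooled = np.concatenate([x, y])
    h_null = [
        _rank_sum_h(pooled[list(idx)], np.delete(pooled, list(idx)))
        for idx in combinations(range(12), 6)
    ]
    p_exact = np.mean(np.asarray(h_null) >= h - 1e-12)
    assert p == pytest.approx(p_exact, abs=0.05)


def test_posthoc_reference_mode_m_equals_k_minus_1():
    rng = np.random.default_rng(1)
    samples = _samples([rng.normal(i, 1, 25) for i in range(6)])
    pairs, m = posthoc(samples, "nonparametric", reference="g0")
    assert m == 5 and len(pairs) == 5
    assert all("g0" in (c.label_a, c.label_b) for c in pairs)
    for c in pairs:
        assert c.adjusted_p == pytest.approx(min(1.0, 5 * c.raw_p))
        assert c.adjusted_p >= c.raw_p


def test_posthoc_all_pairs_bonferroni_count():
    rng = np.random.default_rng(1)
    samples = _samples([rng.normal(0, 1, 10) for _ in range(4)])
    pairs, m = posthoc(samples, "nonparametric")
    assert m == 6 and len(pairs) == 6


def test_posthoc_adjustment_capped_and_monotone():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 15)
    samples = _samples([x, x + rng.normal(0, 1e-6, 15), x + rng.normal(0, 1e-6, 15),
                        x + rng.normal(0, 1e-6, 15), x + rng.normal(0, 1e-6, 15),
                        x + rng.normal(0, 1e-6, 15)])
    pairs, m = posthoc(samples, "nonparametric", reference="g0")
    for c in pairs:
        assert c.raw_p > 0.2  # essentially identical groups
        assert c.adjusted_p == 1.0 if m * c.raw_p > 1 else True
        assert c.adjusted_p <= 1.0


def test_posthoc_tukey_route_family_adjusted():
    rng = np.random.default_rng(4)
    samples = _samples([rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
    pairs, m = posthoc(samples, "parametric")
    assert m == 3 and len(pairs) == 3
    strong = [c for c in pairs if "g2" in (c.label_a, c.label_b)]
    assert all(c.adjusted_p < 0.001 for c in strong)
    null_pair = [c for c in pairs if {c.label_a, c.label_b} == {"g0", "g1"}][0]
    assert null_pair.adjusted_p > 0.05


def test_posthoc_unknown_reference():
    samples = _samples([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
    with pytest.raises(ValidationError):
        posthoc(samples, "nonparametric", reference="nope")


@pytest.mark.parametrize(
    "p, label",
    [
        (0.0005, "***"),
        (0.001, "**"),  # strict boundary
        (0.009, "**"),
        (0.01, "*"),
        (0.02, "*"),
        (0.05, "ns"),
        (0.5, "ns"),
        (0.0, "***"),
        (1.0, "ns"),
    ],
)
def test_significance_labels(p, label):
    assert significance_label(p) == label


def test_significance_label_rejects_invalid():
    with pytest.raises(ValidationError):
        significance_label(1.5)


@given(st.floats(1e-6, 1.0))
def test_kruskal_invariant_under_monotone_transform(scale):
    rng = np.random.default_rng(9)
    arrays = [rng.normal(0, 1, 12), rng.normal(1, 1, 12)]
    _, h1, p1 = omnibus_test(_samples(arrays), "nonparametric")
    transformed = [np.exp(scale * a) for a in arrays]  # strictly increasing
    _, h2, p2 = omnibus_test(_samples(transformed), "nonparametric")
    assert h1 == pytest.approx(h2, rel=1e-9)
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_compare_samples_strong_effect_reference(tmp_path):
    """Five high-rate groups vs one low-rate reference: all pairs starred."""
    rng = np.random.default_rng(21)
    arrays = [np.maximum(rng.normal(0.02, 0.006, 100), 0) for _ in range(5)]
    arrays.append(np.maximum(rng.normal(0.002, 0.002, 100), 0))
    labels = [f"tg{i}" for i in range(5)] + ["ref"]
    result = compare_samples(_samples(arrays, labels), reference="ref")
    assert result.omnibus_p < 0.001
    assert len(result.pairwise) == 5
    assert result.m_comparisons == 5
    assert all(c.label == "***" for c in result.pairwise)
    # report round trip
    write_report(result, tmp_path / "r.json", tmp_path / "r.tsv")
    assert (tmp_path / "r.json").exists()
    tsv = (tmp_path / "r.tsv").read_text().splitlines()
    assert len(tsv) == 6 and tsv[0].startswith("label_a")


def test_compare_samples_null_skips_posthoc_unless_forced():
    rng = np.random.default_rng(101)  # a seed where the null omnibus is ns
    arrays = [rng.normal(0, 1, 20) for _ in range(3)]
    result = compare_samples(_samples(arrays))
    if result.omnibus_p >= 0.05:
        assert result.pairwise == ()
        forced = compare_samples(_samples(arrays), force_posthoc=True)
        assert forced.posthoc_forced and len(forced.pairwise) == 3


def test_compare_two_samples_consistent_with_pairwise():
    rng = np.random.default_rng(6)
    arrays = [rng.normal(0, 1, 25), rng.normal(2, 1, 25)]
    result = compare_samples(_samples(arrays))
    assert result.omnibus_p < 0.05
    assert len(result.pairwise) == 1
    assert result.pairwise[0].adjusted_p < 0.05


def test_compare_requires_two_samples():
    with pytest.raises(ValidationError):
        compare_samples(_samples([[1.0, 2.0, 3.0]]))
    with pytest.raises(ValidationError):
        compare_samples(_samples([[1.0, 2.0], [1.0, 2.0]], labels=["a", "a"]))
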