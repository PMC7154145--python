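"""Robust statistics: Cliff's delta, Spearman, Zou, chi-square, ICC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from touchlimits.stats import (
    chisq_2x2,
    cliffs_delta,
    group_comparison_table,
    icc_consistency,
    spearman_corr,
    zou_compare,
)

samples = st.lists(st.integers(min_value=-20, max_value=20), min_size=2, max_size=12)


def brute_delta(x, y):
    num = 0
    for xi in x:
        for yj in y:
            num += (xi > yj) - (xi < yj)
    return num / (len(x) * len(y))


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [4, 5, 6], -1.0),
        ([1, 3], [2, 4], -0.5),
        ([1, 2, 2, 5], [1, 2, 2, 5], 0.0),
    ],
)
def test_cliffs_delta_reference(x, y, expected):
    assert cliffs_delta(x, y).delta == pytest.approx(expected, abs=1e-15)


@settings(derandomize=True, max_examples=200)
@given(x=samples, y=samples)
def test_cliffs_delta_matches_brute_force_and_antisymmetry(x, y):
    r = cliffs_delta(x, y)
    assert r.delta == pytest.approx(brute_delta(x, y), abs=1e-12)
    assert r.delta == pytest.approx(-cliffs_delta(y, x).delta, abs=1e-15)
    assert -1.0 <= r.ci_low <= r.delta <= r.ci_high <= 1.0


@settings(derandomize=True, max_examples=100)
@given(x=samples, y=samples)
def test_cliffs_delta_equals_mann_whitney_u(x, y):
    """delta = 2U/(nm) - 1 with ties counted half in U."""
    u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    expected = 2 * u / (len(x) * len(y)) - 1
    assert cliffs_delta(x, y).delta == pytest.approx(expected, abs=1e-12)


def test_cliffs_delta_empty_rejected():
    with pytest.raises(ValueError):
        cliffs_delta([], [1.0])


def test_spearman_reference_and_oracle(rng):
    x = np.arange(10.0)
    assert spearman_corr(x, x**3)[0] == pytest.approx(1.0)
    assert spearman_corr(x, -x)[0] == pytest.approx(-1.0)
    a = rng.normal(size=6)
    b = rng.normal(size=6)
    rho, _ = spearman_corr(a, b)
    # Pearson on ranks is the defining identity
    oracle = np.corrcoef(sps.rankdata(a), sps.rankdata(b))[0, 1]
    assert rho == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(ValueError):
        spearman_corr([1, 1, 1], [1, 2, 3])


def test_zou_equal_correlations_symmetric():
    r = zou_compare(0.4, 50, 0.4, 50)
    assert r.delta_r == 0.0
    assert r.ci_low == pytest.approx(-r.ci_high, abs=1e-12)


def test_zou_agrees_with_fisher_z_decision():
    """CI excludes 0 iff the two-sample Fisher z-test rejects at alpha=.05."""
    for r1, n1, r2, n2 in [(0.6, 50, 0.2, 50), (0.5, 40, 0.4, 45), (0.7, 30, 0.1, 30)]:
        z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
        rejects = abs(z) > sps.norm.ppf(0.975)
        ci = zou_compare(r1, n1, r2, n2)
        assert (ci.ci_low > 0 or ci.ci_high < 0) == rejects


def test_zou_ci_shrinks_with_n():
    widths = [
        zou_compare(0.5, n, 0.2, n).ci_high - zou_compare(0.5, n, 0.2, n).ci_low
        for n in (10, 40, 160, 640)
    ]
    assert all(b < a for a, b in zip(widths, widths[1:]))
    with pytest.raises(ValueError):
        zou_compare(1.0, 30, 0.2, 30)


def test_chisq_reference_values():
    chi2, p = chisq_2x2([[10, 10], [10, 10]])
    assert chi2 == 0.0 and p == 1.0
    chi2, _ = chisq_2x2([[20, 10], [10, 20]])
    # closed form n(ad-bc)^2 / product of margins
    assert chi2 == pytest.approx(60 * 300**2 / 30**4, abs=1e-12)
    assert chisq_2x2([[40, 20], [20, 40]])[0] == pytest.approx(2 * chi2, abs=1e-12)
    with pytest.raises(ValueError):
        chisq_2x2([[0, 0], [5, 5]])


def test_chisq_equals_squared_two_proportion_z():
    a, b, c, d = 18, 12, 9, 21
    chi2, _ = chisq_2x2([[a, b], [c, d]])
    p1, p2 = a / (a + b), c / (c + d)
    pool = (a + c) / (a + b + c + d)
    z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / (a + b) + 1 / (c + d)))
    assert chi2 == pytest.approx(z**2, abs=1e-10)


def test_icc_identical_columns_is_one():
    base = np.arange(8.0)
    m = np.column_stack([base] * 4)
    assert icc_consistency(m).icc == pytest.approx(1.0)


def test_icc_pure_noise_near_zero(rng):
    m = rng.normal(size=(500, 4))
    r = icc_consistency(m)
    assert abs(r.icc) < 0.1
    assert r.ci_low <= r.icc <= r.ci_high


def test_icc_matches_hand_anova_and_pingouin():
    m = np.array(
        [[9.0, 2.0, 5.0, 8.0], [6.0, 1.0, 3.0, 2.0], [8.0, 4.0, 6.0, 8.0], [7.0, 1.0, 2.0, 6.0]]
    )
    n, k = m.shape
    grand = m.mean()
    bms = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    jms = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ems = (((m - grand) ** 2).sum() - (n - 1) * bms - (k - 1) * jms) / ((n - 1) * (k - 1))
    r = icc_consistency(m)
    assert r.icc == pytest.approx((bms - ems) / bms, abs=1e-12)

    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    tab = pingouin.intraclass_corr(long, targets="target", raters="rater", ratings="score")
    tab = tab.set_index("Type")
    # two-way mixed consistency, average measures: labelled ICC(C,k) / ICC3k
    key = "ICC(C,k)" if "ICC(C,k)" in tab.index else "ICC3k"
    ref = tab.loc[key]
    assert r.icc == pytest.approx(ref["ICC"], abs=1e-9)
    lo, hi = ref[[c for c in ("CI95", "CI95%") if c in tab.columns][0]]
    assert r.ci_low == pytest.approx(lo, abs=0.006)  # pingouin rounds to 2 dp
    assert r.ci_high == pytest.approx(hi, abs=0.006)


def test_icc_shape_validation():
    with pytest.raises(ValueError):
        icc_consistency(np.ones((1, 4)))
    with pytest.raises(ValueError):
        icc_consistency(np.ones((5, 1)))


def test_group_comparison_table_orientation():
    """ASD-elevated variables must come out with negative delta."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "diagnosis": ["ASD"] * 5 + ["NT"] * 5,
            "threshold_g": [0.3, 0.4, 0.5, 0.6, 0.7, 0.1, 0.12, 0.15, 0.2, 0.25],
        }
    )
    tab = group_comparison_table(df, ["threshold_g"])
    assert tab.loc[0, "delta"] == -1.0
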