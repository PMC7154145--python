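"""Cumulative probability model: likelihood, inference, model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from touchlimits.cpm import (
    CPMError,
    best_subset,
    design_matrix,
    fit_cpm,
    lr_test,
    mechanism_scenario,
    nagelkerke_r2,
    score_test,
    wald_summary,
)


@pytest.fixture(scope="module")
def shift_data():
    rng = np.random.default_rng(42)
    n = 80
    g = rng.integers(0, 2, n).astype(float)
    y = rng.normal(size=n) + 1.0 * g
    return y, pd.DataFrame({"g": g})


def test_null_model_closed_form(rng):
    y = rng.normal(size=40)
    fit = fit_cpm(y, None)
    # all-distinct outcome: empirical multinomial loglik is n log(1/n)
    assert fit.loglik == pytest.approx(40 * np.log(1 / 40), abs=1e-10)
    assert fit.loglik == fit.loglik_null
    assert fit.n_slopes == 0
    assert np.all(np.diff(fit.intercepts) < 0)


def test_constant_outcome_rejected():
    with pytest.raises(CPMError):
        fit_cpm(np.ones(10), None)


def test_matches_statsmodels_ordered_model(shift_data):
    """Dual route: own Newton fit vs statsmodels' ordinal MLE."""
    sm = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
    y, X = shift_data
    fit = fit_cpm(y, X)
    ref = sm.OrderedModel(y, X.to_numpy(), distr="logit").fit(
        method="bfgs", disp=False, maxiter=500
    )
    assert fit.converged
    assert fit.coefficients["g"] == pytest.approx(ref.params[0], abs=1e-4)
    # own Newton solve meets a tighter gradient tolerance than BFGS, so it
    # may sit marginally above the reference likelihood, never below
    assert fit.loglik >= ref.llf - 1e-6
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
    assert wald_summary(fit).table.loc["g", "se"] == pytest.approx(
        ref.bse[0], rel=1e-3
    )


def test_rank_invariance_under_monotone_transforms(shift_data):
    y, X = shift_data
    base = fit_cpm(y, X).coefficients["g"]
    for f in (np.exp, lambda v: v**3, lambda v: sps.rankdata(v)):
        assert fit_cpm(f(y), X).coefficients["g"] == pytest.approx(base, abs=1e-6)


def test_slope_sign_matches_dominance(shift_data):
    y, X = shift_data
    fit = fit_cpm(y, X)
    assert fit.coefficients["g"] > 0  # group 1 stochastically larger
    assert wald_summary(fit).table.loc["g", "aOR"] > 1


def test_proportional_odds_exceedance_curves(shift_data):
    """aOR > 1 for a binary predictor lifts P(Y >= t) at every cut point."""
    y, X = shift_data
    fit = fit_cpm(y, X)
    p0 = fit.exceedance_prob(np.array([0.0]))
    p1 = fit.exceedance_prob(np.array([1.0]))
    assert np.all(p1 > p0)


def test_score_test_is_wilcoxon(shift_data):
    """Binary-predictor score statistic = n/(n-1) x Wilcoxon chi-square."""
    y, X = shift_data
    n = len(y)
    chi2, df, _ = score_test(y, X)
    assert df == 1
    g = X["g"].to_numpy()
    pw = sps.mannwhitneyu(
        y[g == 1], y[g == 0], alternative="two-sided",
        method="asymptotic", use_continuity=False,
    ).pvalue
    z2 = sps.norm.isf(pw / 2) ** 2
    assert chi2 == pytest.approx(z2 * n / (n - 1), abs=1e-9)
    # ties must flow through the tie-corrected variance identically
    yt = np.round(y, 1)
    chi2t, _, _ = score_test(yt, X)
    pwt = sps.mannwhitneyu(
        yt[g == 1], yt[g == 0], alternative="two-sided",
        method="asymptotic", use_continuity=False,
    ).pvalue
    assert chi2t == pytest.approx(sps.norm.isf(pwt / 2) ** 2 * n / (n - 1), abs=1e-9)


def test_lr_test_self_and_nesting(shift_data):
    y, X = shift_data
    fit = fit_cpm(y, X)
    chi2, df, p = lr_test(fit, fit)
    assert chi2 == 0.0 and p == 1.0
    rng = np.random.default_rng(0)
    X2 = X.assign(noise=rng.normal(size=len(X)))
    fit2 = fit_cpm(y, X2)
    assert fit2.loglik >= fit.loglik - 1e-8  # nesting: extra column can't hurt
    chi2, df, _ = lr_test(fit2, fit)
    assert df == 1 and chi2 >= -1e-8
    with pytest.raises(CPMError):
        lr_test(fit, fit2)  # not nested this way around


def test_wald_ci_algebra(shift_data):
    y, X = shift_data
    tab = wald_summary(fit_cpm(y, X)).table
    b, se = tab.loc["g", "coef"], tab.loc["g", "se"]
    z = sps.norm.ppf(0.975)
    assert tab.loc["g", "ci_low"] == pytest.approx(np.exp(b - z * se), rel=1e-12)
    assert tab.loc["g", "wald_chi2"] == pytest.approx((b / se) ** 2, rel=1e-12)


def test_nagelkerke_bounds(shift_data):
    y, X = shift_data
    fit = fit_cpm(y, X)
    r2 = nagelkerke_r2(fit)
    assert 0.0 < r2 < 1.0
    null = fit_cpm(y, None)
    assert nagelkerke_r2(null) == pytest.approx(0.0, abs=1e-12)


def test_stronger_effect_larger_r2():
    rng = np.random.default_rng(7)
    n = 200
    g = rng.integers(0, 2, n).astype(float)
    noise = rng.normal(size=n)
    weak = fit_cpm(noise + 0.2 * g, pd.DataFrame({"g": g}))
    strong = fit_cpm(noise + 2.0 * g, pd.DataFrame({"g": g}))
    assert nagelkerke_r2(strong) > nagelkerke_r2(weak)


def test_best_subset_zero_candidates(shift_data):
    y, X = shift_data
    res = best_subset(y, X, X.iloc[:, :0])
    assert res.subsets == [()]
    assert res.weights[0] == pytest.approx(1.0)
    assert res.bf10_vs_baseline == pytest.approx(1.0)


def test_best_subset_weights_and_selection():
    rng = np.random.default_rng(3)
    n = 150
    driver = rng.normal(size=n)
    noise = rng.normal(size=n)
    y = rng.logistic(size=n) + 2.0 * driver
    base = pd.DataFrame({"b": rng.normal(size=n)})
    cands = pd.DataFrame({"driver": driver, "noise": noise})
    res = best_subset(y, base, cands)
    assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert "driver" in res.best_subset
    assert res.bics[res.subsets.index(res.best_subset)] == res.bics.min()
    assert res.bf10_vs_baseline > 1.0
    with pytest.raises(CPMError):
        best_subset(y, base, pd.concat([cands] * 8, axis=1))


def test_design_matrix_coding():
    df = pd.DataFrame(
        {
            "diagnosis": ["ASD", "NT"],
            "sex": ["M", "F"],
            "age_years": [10.0, 12.0],
            "counterbalance": ["descending-first", "ascending-first"],
        }
    )
    X = design_matrix(df)
    assert X.loc[0].tolist() == [1.0, 1.0, 10.0, 1.0]
    assert X.loc[1].tolist() == [0.0, 0.0, 12.0, 0.0]


def test_mechanism_scenario_smoke(default_summary):
    _, _, summary = default_summary
    child = summary[(summary["age_band"] == "child") & (~summary["excluded"])]
    rep = mechanism_scenario(child)
    assert rep.n == len(child.dropna(subset=["threshold_g", "az", "c"]))
    assert set(rep.baseline.table.index) == {
        "diagnosis_asd", "sex_male", "age_years", "counterbalance_desc",
    }
    assert "c" in rep.augmented.table.index
    assert rep.search.weights.sum() == pytest.approx(1.0, abs=1e-9)
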