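"""Group-comparison and correlation statistics for skewed psychophysical data.

Cliff's delta is the primary between-group effect size: the probability that
a random draw from one group exceeds a random draw from the other, minus the
reverse, estimated by pairwise dominance counts with ties scoring zero.  Its
confidence interval uses Cliff's consistent variance estimator with a normal
approximation, truncated to [-1, 1].  Correlations are Spearman rank
correlations; two independent correlations are compared with Zou's
modified-asymptotic CI on their difference.  Categorical 2x2 comparisons use
the Pearson chi-square without continuity correction, and the stability of
repeated threshold estimates is summarised by the two-way mixed,
average-measures consistency ICC, ICC(3,k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CliffResult",
    "CorrComparison",
    "ICCResult",
    "cliffs_delta",
    "spearman_corr",
    "zou_compare",
    "chisq_2x2",
    "icc_consistency",
    "group_comparison_table",
]


@dataclass(frozen=True)
class CliffResult:
    delta: float
    ci_low: float
    ci_high: float
    p: float
    se: float


@dataclass(frozen=True)
class CorrComparison:
    delta_r: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    form: str = "ICC(3,k)"


def cliffs_delta(x, y, ci_level: float = 0.95) -> CliffResult:
    """Cliff's dominance delta of ``x`` over ``y`` with CI and p-value.

    ``delta > 0`` means values of ``x`` tend to exceed values of ``y``.  With
    the study's table convention (ASD column first, NT second), pass the NT
    sample as ``x`` so that a group in which ASD exceeds NT yields a negative
    delta.

    The variance is Cliff's consistent estimator built from the row/column
    dominance means; the CI is ``delta +/- z * SE`` truncated to [-1, 1], and
    the p-value is the two-sided normal test of delta = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    d = np.sign(x[:, None] - y[None, :])  # dominance kernel, ties -> 0
    delta = float(d.mean())
    if nx < 2 or ny < 2:
        return CliffResult(delta, -1.0, 1.0, 1.0, np.inf)
    di = d.mean(axis=1)
    dj = d.mean(axis=0)
    var = (
        ny**2 * np.sum((di - delta) ** 2)
        + nx**2 * np.sum((dj - delta) ** 2)
        - np.sum((d - delta) ** 2)
    ) / (nx * ny * (nx - 1) * (ny - 1))
    se = float(np.sqrt(max(var, 0.0)))
    z = sps.norm.ppf(0.5 + ci_level / 2)
    lo = max(-1.0, delta - z * se)
    hi = min(1.0, delta + z * se)
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2 * sps.norm.sf(abs(delta) / se))
    return CliffResult(delta, lo, hi, p, se)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _fisher_ci(r: float, n: int, level: float) -> tuple[float, float]:
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def zou_compare(r1: float, n1: int, r2: float, n2: int, ci_level: float = 0.95) -> CorrComparison:
    """Zou's modified-asymptotic CI for r1 - r2 from two independent samples.

    Each correlation first gets its own Fisher-z back-transformed CI
    (l_i, u_i); the interval for the difference is then

        L = r1 - r2 - sqrt((r1 - l1)^2 + (u2 - r2)^2)
        U = r1 - r2 + sqrt((u1 - r1)^2 + (r2 - l2)^2)
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly in (-1, 1)")
        if n < 4:
            raise ValueError("each sample needs n >= 4")
    l1, u1 = _fisher_ci(r1, n1, ci_level)
    l2, u2 = _fisher_ci(r2, n2, ci_level)
    diff = r1 - r2
    lo = diff - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2)
    hi = diff + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2)
    return CorrComparison(float(diff), float(lo), float(hi))


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def icc_consistency(data, ci_level: float = 0.95) -> ICCResult:
    """ICC(3,k): two-way mixed, average-measures, consistency.

    ``data`` is an n x k matrix (n targets rated by the same k raters /
    measurement occasions).  ICC(3,k) = (BMS - EMS) / BMS from the two-way
    ANOVA mean squares, with the F-based confidence interval.
    """
    m = np.asarray(data, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 and k >= 2")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((m - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms == 0:
        raise ValueError("no between-target variance: ICC undefined")
    icc = (bms - ems) / bms
    f = bms / ems if ems > 0 else np.inf
    df1, df2 = n - 1, (n - 1) * (k - 1)
    alpha = 1 - ci_level
    fl = f / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * sps.f.ppf(1 - alpha / 2, df2, df1)
    return ICCResult(
        icc=float(icc),
        ci_low=float(1 - 1 / fl),
        ci_high=float(1 - 1 / fu),
        k=k,
        n=n,
    )


def group_comparison_table(
    df: pd.DataFrame,
    variables: list[str],
    group_col: str = "diagnosis",
    reference: str = "NT",
    other: str = "ASD",
) -> pd.DataFrame:
    """Per-variable Cliff's delta comparison table (descriptives + delta CI + p).

    Delta is computed as dominance of the reference (second-listed, NT)
    group over the other (first-listed, ASD) group, so a variable elevated
    in the ASD group reports a negative delta.
    """
    rows = []
    for var in variables:
        sub = df[[group_col, var]].dropna()
        a = sub.loc[sub[group_col] == other, var].to_numpy()
        b = sub.loc[sub[group_col] == reference, var].to_numpy()
        res = cliffs_delta(b, a)
        rows.append(
            {
                "variable": var,
                f"n_{other}": a.size,
                f"n_{reference}": b.size,
                f"mean_{other}": a.mean() if a.size else np.nan,
                f"sd_{other}": a.std(ddof=1) if a.size > 1 else np.nan,
                f"mean_{reference}": b.mean() if b.size else np.nan,
                f"sd_{reference}": b.std(ddof=1) if b.size > 1 else np.nan,
                "delta": res.delta,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
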