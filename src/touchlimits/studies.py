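"""Simulation studies over the pipeline: recovery, calibration, mechanism.

Each function here runs a self-contained Monte-Carlo study built from the
package's own primitives and returns plain dataclass/dict results.  They are
what the analysis drivers, the acceptance checks and the docs' worked
examples execute, so every reported number is recomputed at call time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cpm import fit_cpm, lr_test, mechanism_scenario, score_test
from .observer import ObserverParams, default_cohort_spec, generate_cohort
from .protocol import (
    ProtocolConfig,
    block_threshold,
    run_session,
    session_sdt_counts,
    simulate_sessions,
)
from .sdt import metrics_from_counts
from .stats import cliffs_delta

__all__ = [
    "criterion_recovery_sweep",
    "criterion_recovery_regression",
    "mechanism_replicates",
    "lr_null_calibration",
    "bic_weight_growth",
    "cliff_ci_coverage",
    "cpm_wilcoxon_agreement",
]


# --------------------------------------------------------------------------
# criterion -> threshold mechanism at the single-observer level


@dataclass
class RecoverySweep:
    lam_grid: np.ndarray
    mean_c: np.ndarray
    mean_threshold: np.ndarray
    sessions_per_level: int


def criterion_recovery_sweep(
    lam_grid=None,
    sessions_per_level: int = 200,
    alpha: float = 0.05,
    beta: float = 2.0,
    lapse: float = 0.0,
    seed: int = 0,
) -> RecoverySweep:
    """Sweep the generative criterion with sensitivity fixed.

    For each criterion level, simulates full sessions and records the mean
    estimated c and the mean session threshold.  Thresholds are computed for
    every session directly from its blocks (the catch-trial exclusion filter
    is bypassed here: at very liberal criteria it would censor the liberal
    tail and distort the marginal mapping being measured).
    """
    if lam_grid is None:
        lam_grid = np.linspace(0.2, 1.2, 11)
    lam_grid = np.asarray(lam_grid, dtype=float)
    rng = np.random.default_rng(seed)
    cfg = ProtocolConfig()
    mean_c = np.empty(lam_grid.size)
    mean_thr = np.empty(lam_grid.size)
    for i, lam in enumerate(lam_grid):
        obs = ObserverParams(alpha=alpha, beta=beta, lam=float(lam), lapse=lapse)
        cs, ths = [], []
        for j in range(sessions_per_level):
            cb = "ascending-first" if j % 2 == 0 else "descending-first"
            s = run_session(obs, cb, cfg, rng)
            m = metrics_from_counts(session_sdt_counts(s.blocks))
            cs.append(m.c)
            ths.append(np.mean([block_threshold(b) for b in s.blocks]))
        mean_c[i] = np.mean(cs)
        mean_thr[i] = np.mean(ths)
    return RecoverySweep(lam_grid, mean_c, mean_thr, sessions_per_level)


def criterion_recovery_regression(
    n_participants: int = 500,
    lam_range: tuple[float, float] = (0.2, 1.5),
    alpha: float = 0.05,
    beta: float = 2.0,
    seed: int = 0,
):
    """Regress estimated c on the true criterion across simulated observers.

    Returns (slope, p-value, n) from an ordinary least-squares fit; under a
    faithful protocol the slope is positive and overwhelmingly significant.
    """
    rng = np.random.default_rng(seed)
    lams = rng.uniform(*lam_range, size=n_participants)
    cs = []
    for j, lam in enumerate(lams):
        obs = ObserverParams(alpha=alpha, beta=beta, lam=float(lam), lapse=0.0)
        cb = "ascending-first" if j % 2 == 0 else "descending-first"
        s = run_session(obs, cb, rng=rng)
        cs.append(metrics_from_counts(session_sdt_counts(s.blocks)).c)
    res = sps.linregress(lams, cs)
    return float(res.slope), float(res.pvalue), n_participants


# --------------------------------------------------------------------------
# cohort-level mechanism replication


@dataclass
class MechanismRates:
    n_replicates: int
    rate_diag_sig_baseline: float
    rate_criterion_selected: float
    rate_diag_nonsig_augmented: float
    rate_criterion_largest_wald: float
    rate_full_pattern: float
    mean_baseline_diag_aor: float
    mean_augmented_diag_aor: float
    mean_threshold_delta: float


def _child_spec(seed: int, null: bool):
    spec = default_cohort_spec(seed=seed)
    children = [g for g in spec.groups if g.age_band == "child"]
    if null:
        nt_lam = next(g.lam for g in children if g.diagnosis == "NT")
        children = [dataclasses.replace(g, lam=nt_lam) for g in children]
    return dataclasses.replace(spec, groups=tuple(children), seed=seed)


def mechanism_replicates(
    n_replicates: int = 200, seed: int = 0, null: bool = False
) -> MechanismRates:
    """Replicate the child-cohort criterion-mechanism analysis.

    Each replicate simulates a fresh child cohort (55 ASD / 35 NT), scores
    sessions, fits the baseline CPM (diagnosis, sex, age, counterbalance),
    runs best-subset selection over {az, c}, and refits with c added.  With
    ``null=True`` the ASD group inherits the NT criterion distribution, so
    the baseline diagnosis test measures the type-I error rate.
    """
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    hits = dict(i=0, ii=0, iii=0, iv=0, full=0)
    base_aor, aug_aor, deltas = [], [], []
    for child_ss in ss:
        s1, s2 = child_ss.generate_state(2) % (2**31)
        spec = _child_spec(int(s1), null)
        records = generate_cohort(spec)
        _, summary = simulate_sessions(records, seed=int(s2))
        data = summary[~summary["excluded"]]
        rep = mechanism_scenario(data)
        hits["i"] += rep.diagnosis_sig_baseline
        hits["ii"] += rep.criterion_selected
        hits["iii"] += not rep.diagnosis_sig_augmented
        hits["iv"] += rep.criterion_largest_wald
        hits["full"] += (
            rep.diagnosis_sig_baseline
            and rep.criterion_selected
            and not rep.diagnosis_sig_augmented
            and rep.criterion_largest_wald
        )
        base_aor.append(rep.baseline.table.loc["diagnosis_asd", "aOR"])
        aug_aor.append(rep.augmented.table.loc["diagnosis_asd", "aOR"])
        deltas.append(
            cliffs_delta(
                data.loc[data["diagnosis"] == "NT", "threshold_g"],
                data.loc[data["diagnosis"] == "ASD", "threshold_g"],
            ).delta
        )
    r = n_replicates
    return MechanismRates(
        n_replicates=r,
        rate_diag_sig_baseline=hits["i"] / r,
        rate_criterion_selected=hits["ii"] / r,
        rate_diag_nonsig_augmented=hits["iii"] / r,
        rate_criterion_largest_wald=hits["iv"] / r,
        rate_full_pattern=hits["full"] / r,
        mean_baseline_diag_aor=float(np.mean(base_aor)),
        mean_augmented_diag_aor=float(np.mean(aug_aor)),
        mean_threshold_delta=float(np.mean(deltas)),
    )


# --------------------------------------------------------------------------
# inference calibration


def lr_null_calibration(n_reps: int = 1000, n: int = 100, seed: int = 0) -> np.ndarray:
    """LR statistics of a pure-noise predictor; should be chi-square(1)."""
    rng = np.random.default_rng(seed)
    stats = np.empty(n_reps)
    for i in range(n_reps):
        y = rng.normal(size=n)
        x = pd.DataFrame({"noise": rng.normal(size=n)})
        stats[i] = lr_test(fit_cpm(y, x))[0]
    return stats


def bic_weight_growth(
    ns=(100, 400, 1600), n_reps: int = 15, slope: float = 0.5, seed: int = 0
) -> dict[int, float]:
    """Mean BIC weight of the true single-predictor model as n grows."""
    from .cpm import best_subset

    out = {}
    rng = np.random.default_rng(seed)
    for n in ns:
        weights = []
        for _ in range(n_reps):
            driver = rng.normal(size=n)
            noise = rng.normal(size=n)
            y = rng.logistic(size=n) + slope * driver
            base = pd.DataFrame(index=pd.RangeIndex(n))
            cands = pd.DataFrame({"driver": driver, "noise": noise})
            res = best_subset(y, base, cands)
            weights.append(res.weight_of(("driver",)))
        out[int(n)] = float(np.mean(weights))
    return out


# --------------------------------------------------------------------------
# statistic-level calibrations


def cliff_ci_coverage(
    n_sims: int = 2000, n_per_group: int = 30, shift: float = 0.5, seed: int = 0
) -> float:
    """Empirical 95% CI coverage for Cliff's delta on shifted normal samples.

    The true dominance parameter for X ~ N(shift, 1) vs Y ~ N(0, 1) is
    2 Phi(shift / sqrt(2)) - 1.
    """
    rng = np.random.default_rng(seed)
    true_delta = 2 * sps.norm.cdf(shift / np.sqrt(2)) - 1
    covered = 0
    for _ in range(n_sims):
        x = rng.normal(shift, 1, n_per_group)
        y = rng.normal(0, 1, n_per_group)
        r = cliffs_delta(x, y)
        covered += r.ci_low <= true_delta <= r.ci_high
    return covered / n_sims


def cpm_wilcoxon_agreement(
    n_datasets: int = 100, n: int = 40, shift: float = 0.5, seed: int = 0
) -> np.ndarray:
    """|p_CPM - p_Wilcoxon| for single-binary-predictor models, per dataset.

    The CPM side is the Rao score test; the reference is the tie-corrected
    normal-approximation Wilcoxon-Mann-Whitney test (no continuity
    correction), the variant the score test generalises.
    """
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_datasets)
    for i in range(n_datasets):
        g = np.repeat([0.0, 1.0], n // 2)
        y = rng.normal(size=n) + shift * g
        p_cpm = score_test(y, pd.DataFrame({"g": g}))[2]
        p_w = sps.mannwhitneyu(
            y[g == 1], y[g == 0], alternative="two-sided",
            method="asymptotic", use_continuity=False,
        ).pvalue
        diffs[i] = abs(p_cpm - p_w)
    return diffs
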