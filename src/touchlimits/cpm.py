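"""Cumulative probability model (CPM) for continuous outcomes.

The CPM is a proportional-odds (cumulative logit) regression that treats
every distinct outcome value as its own ordered category:

    P(Y >= y_(k) | x) = expit(theta_k + x' beta),   k = 2..K,

with the intercepts ``theta`` a decreasing sequence (one per distinct value
minus one) and ``beta`` the log-odds slopes.  Because the likelihood depends
on the outcome only through its ranks, the model is invariant to monotone
transforms of Y and acts as a multi-predictor generalisation of the
Wilcoxon-Mann-Whitney test; ``exp(beta_j)`` is the adjusted odds ratio (aOR)
of exceeding any outcome cut point per unit of predictor j.

Fitting maximises the exact multinomial likelihood by Newton's method with
step-halving in the natural (theta, beta) parametrisation, where the
log-likelihood is concave.  The theta block of the Hessian is tridiagonal,
so each step costs O(K) via a banded solve plus a p x p Schur complement;
the same Schur complement provides the slope covariance for Wald inference.
A quasi-Newton fallback on a monotonicity-preserving reparametrisation
handles pathological cases.

Model comparison uses BIC = -2 loglik + p * log(n) with ``p`` counting slope
parameters only — all candidate models share the same outcome, so the
(identical) intercept count cancels from every BIC difference.  Best-subset
search reports BIC weights exp(-dBIC/2), normalised over candidates, and the
approximate Bayes factor exp((BIC_baseline - BIC_best)/2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.linalg import solveh_banded
from scipy.special import expit, log_expit

__all__ = [
    "CPMFit",
    "InferenceSummary",
    "ModelSearchResult",
    "MechanismReport",
    "fit_cpm",
    "lr_test",
    "wald_summary",
    "nagelkerke_r2",
    "best_subset",
    "design_matrix",
    "mechanism_scenario",
]

GRAD_TOL = 1e-8
MAX_NEWTON_ITER = 100


@dataclass
class CPMFit:
    """A fitted cumulative probability model."""

    coefficients: pd.Series            # slopes on the logit scale
    intercepts: np.ndarray             # theta_2..theta_K, non-increasing
    vcov: pd.DataFrame | None          # slope covariance (None for null model)
    loglik: float
    loglik_null: float                 # intercept-only log-likelihood, same data
    n: int
    converged: bool
    y_values: np.ndarray               # distinct outcome values, ascending

    @property
    def n_slopes(self) -> int:
        return len(self.coefficients)

    @property
    def bic(self) -> float:
        # slope parameters only; intercepts are shared nuisance across
        # models on the same outcome
        return -2.0 * self.loglik + self.n_slopes * np.log(self.n)

    def exceedance_prob(self, x_row: np.ndarray) -> np.ndarray:
        """P(Y >= y_(k)) for k = 2..K at one predictor row."""
        eta = self.intercepts + float(np.dot(x_row, self.coefficients.to_numpy()))
        return expit(eta)


class CPMError(ValueError):
    pass


def _prepare(y, X):
    y = np.asarray(y, dtype=float)
    if X is None:
        Xm = np.empty((y.size, 0))
        names: list[str] = []
    elif isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.atleast_2d(np.asarray(X, dtype=float))
        if Xm.shape[0] != y.size:
            Xm = Xm.T
        names = [f"x{j}" for j in range(Xm.shape[1])]
    if Xm.shape[0] != y.size:
        raise CPMError("X and y have incompatible shapes")
    if np.isnan(y).any() or np.isnan(Xm).any():
        raise CPMError("missing values are not supported; drop them first")
    return y, Xm, names


def _null_loglik(counts: np.ndarray, n: int) -> float:
    return float(np.sum(counts * np.log(counts / n)))


def _loglik_grad_schur(theta, beta, Xm, kidx, counts, want_hess=True):
    """Log-likelihood, gradient, and the Newton/vcov building blocks.

    Returns (ll, g_theta, g_beta, solve) where ``solve(r_theta, r_beta)``
    solves (-H) d = r via the banded theta block + Schur complement, and
    also exposes the Schur matrix S (whose inverse is the slope vcov).
    Returns ll = -inf (rest None) when theta is infeasible.
    """
    K1 = theta.size            # K - 1 intercepts
    n, p = Xm.shape
    xb = Xm @ beta if p else np.zeros(n)
    # eta_a: upper cumulative logit (exists for category k >= 1)
    has_a = kidx >= 1
    has_b = kidx <= K1 - 1
    eta_a = np.where(has_a, theta[np.clip(kidx - 1, 0, K1 - 1)] + xb, np.inf)
    eta_b = np.where(has_b, theta[np.clip(kidx, 0, K1 - 1)] + xb, -np.inf)
    A = expit(eta_a)
    B = expit(eta_b)
    P = A - B
    if np.any(P <= 0) or not np.all(np.isfinite(P[np.isfinite(eta_a) | np.isfinite(eta_b)])):
        return -np.inf, None, None, None
    ll = float(np.sum(np.log(P)))
    f_a = np.where(has_a, A * (1 - A), 0.0)
    f_b = np.where(has_b, B * (1 - B), 0.0)
    u_a = f_a / P
    u_b = -f_b / P
    g_theta = np.zeros(K1)
    np.add.at(g_theta, np.clip(kidx - 1, 0, K1 - 1), np.where(has_a, u_a, 0.0))
    np.add.at(g_theta, np.clip(kidx, 0, K1 - 1), np.where(has_b, u_b, 0.0))
    g_beta = Xm.T @ (u_a + u_b) if p else np.zeros(0)
    if not want_hess:
        return ll, g_theta, g_beta, None

    w_aa = np.where(has_a, f_a * (1 - 2 * A) / P - u_a**2, 0.0)
    w_bb = np.where(has_b, -f_b * (1 - 2 * B) / P - u_b**2, 0.0)
    w_ab = f_a * f_b / P**2  # zero automatically when either side missing

    diag = np.zeros(K1)
    np.add.at(diag, np.clip(kidx - 1, 0, K1 - 1), np.where(has_a, w_aa, 0.0))
    np.add.at(diag, np.clip(kidx, 0, K1 - 1), np.where(has_b, w_bb, 0.0))
    off = np.zeros(K1)  # off[j] couples theta_j, theta_{j+1}; obs in category j
    both = has_a & has_b
    np.add.at(off, np.clip(kidx - 1, 0, K1 - 1), np.where(both, w_ab, 0.0))
    off = off[: K1 - 1] if K1 > 1 else np.zeros(0)

    if p:
        Bmat = np.zeros((K1, p))
        ca = np.where(has_a, w_aa + w_ab, 0.0)
        cb = np.where(has_b, w_bb + w_ab, 0.0)
        np.add.at(Bmat, np.clip(kidx - 1, 0, K1 - 1), ca[:, None] * Xm)
        np.add.at(Bmat, np.clip(kidx, 0, K1 - 1), cb[:, None] * Xm)
        wq = w_aa + 2 * w_ab + w_bb
        Cmat = Xm.T @ (wq[:, None] * Xm)
    else:
        Bmat = np.zeros((K1, 0))
        Cmat = np.zeros((0, 0))

    # negate: (-H) is positive definite; banded form for solveh_banded
    ab = np.zeros((2, K1))
    ab[0] = -diag
    if K1 > 1:
        ab[1, : K1 - 1] = -off

    def solve(r_theta, r_beta):
        v = solveh_banded(ab, r_theta, lower=True)
        if p:
            W = solveh_banded(ab, -Bmat, lower=True)
            S = -Cmat - (-Bmat).T @ W
            d_beta = np.linalg.solve(S, r_beta - (-Bmat).T @ v)
            d_theta = v - W @ d_beta
            return d_theta, d_beta, S
        return v, np.zeros(0), np.zeros((0, 0))

    return ll, g_theta, g_beta, solve


def _start_theta(counts: np.ndarray, n: int) -> np.ndarray:
    exceed = 1.0 - np.cumsum(counts)[:-1] / n  # P(Y >= next category)
    return np.log(exceed / (1 - exceed))


def _fallback_lbfgs(theta0, beta0, Xm, kidx, counts):
    """Quasi-Newton fallback on a monotonicity-preserving reparametrisation."""
    K1, p = theta0.size, Xm.shape[1]

    def unpack(phi):
        t1 = phi[0]
        if K1 > 1:
            theta = t1 - np.concatenate([[0.0], np.cumsum(np.exp(phi[1:K1]))])
        else:
            theta = np.array([t1])
        return theta, phi[K1:]

    def negll_grad(phi):
        theta, beta = unpack(phi)
        ll, g_t, g_b, _ = _loglik_grad_schur(theta, beta, Xm, kidx, counts, want_hess=False)
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(phi)
        g = np.empty_like(phi)
        g[0] = g_t.sum()
        if K1 > 1:
            rev = np.cumsum(g_t[::-1])[::-1]
            g[1:K1] = -np.exp(phi[1:K1]) * rev[1:]
        g[K1:] = g_b
        return -ll, -g

    phi0 = np.empty(K1 + p)
    phi0[0] = theta0[0]
    if K1 > 1:
        incr = np.maximum(theta0[:-1] - theta0[1:], 1e-8)
        phi0[1:K1] = np.log(incr)
    phi0[K1:] = beta0
    res = optimize.minimize(
        negll_grad, phi0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    theta, beta = unpack(res.x)
    return theta, beta, bool(res.success)


def fit_cpm(y, X=None) -> CPMFit:
    """Fit the CPM of ``y`` on predictor matrix ``X`` (DataFrame or array).

    ``X=None`` (or zero columns) fits the intercept-only model, whose MLE is
    the empirical outcome distribution in closed form.  Raises on constant
    ``y``; a fit that stops without meeting the gradient tolerance is
    returned with ``converged=False``.
    """
    y, Xm, names = _prepare(y, X)
    n, p = Xm.shape
    if n < p + 2:
        raise CPMError(f"need n >= p + 2 (n={n}, p={p})")
    y_values, kidx = np.unique(y, return_inverse=True)
    K = y_values.size
    if K < 2:
        raise CPMError("outcome is constant; CPM undefined")
    counts = np.bincount(kidx, minlength=K).astype(float)
    ll0 = _null_loglik(counts, n)
    theta = _start_theta(counts, n)

    if p == 0:
        return CPMFit(
            coefficients=pd.Series(dtype=float),
            intercepts=theta,
            vcov=None,
            loglik=ll0,
            loglik_null=ll0,
            n=n,
            converged=True,
            y_values=y_values,
        )

    beta = np.zeros(p)
    converged = False
    S_final = None
    ll, g_t, g_b, solve = _loglik_grad_schur(theta, beta, Xm, kidx, counts)
    for _ in range(MAX_NEWTON_ITER):
        gnorm = max(np.abs(g_t).max(), np.abs(g_b).max() if p else 0.0)
        if gnorm < GRAD_TOL:
            converged = True
            break
        try:
            d_t, d_b, S_final = solve(g_t, g_b)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        improved = False
        for _ in range(40):
            ll_new, g_t_new, g_b_new, solve_new = _loglik_grad_schur(
                theta + step * d_t, beta + step * d_b, Xm, kidx, counts
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-13:
                theta = theta + step * d_t
                beta = beta + step * d_b
                ll, g_t, g_b, solve = ll_new, g_t_new, g_b_new, solve_new
                improved = True
                break
            step /= 2.0
        if not improved:
            break
    if not converged:
        theta, beta, ok = _fallback_lbfgs(theta, beta, Xm, kidx, counts)
        ll, g_t, g_b, solve = _loglik_grad_schur(theta, beta, Xm, kidx, counts)
        gnorm = max(np.abs(g_t).max(), np.abs(g_b).max())
        converged = bool(ok and gnorm < 1e-4)
    # slope covariance from the Schur complement at the optimum
    try:
        _, _, S = solve(g_t, g_b)
        vcov = pd.DataFrame(np.linalg.inv(S), index=names, columns=names)
    except Exception:
        vcov = None
        converged = False
    return CPMFit(
        coefficients=pd.Series(beta, index=names),
        intercepts=theta,
        vcov=vcov,
        loglik=float(ll),
        loglik_null=ll0,
        n=n,
        converged=converged,
        y_values=y_values,
    )


def score_test(y, X) -> tuple[float, int, float]:
    """Rao score test (expected information) of all slopes = 0 in the CPM.

    Evaluated at the intercept-only MLE, so no iterative fit is needed.
    With the expected (Fisher) information, the statistic for a single
    binary predictor is exactly n/(n-1) times the Wilcoxon-Mann-Whitney
    chi-square (tie-corrected normal approximation, no continuity
    correction) — the precise sense in which the CPM generalises that test.
    """
    y, Xm, _ = _prepare(y, X)
    n, p = Xm.shape
    if p == 0:
        raise CPMError("score test needs at least one predictor")
    y_values, kidx = np.unique(y, return_inverse=True)
    K = y_values.size
    if K < 2:
        raise CPMError("outcome is constant; CPM undefined")
    pk = np.bincount(kidx, minlength=K) / n
    exceed = 1.0 - np.cumsum(pk)[:-1]              # P(Y >= y_(k+1)) under H0
    F = np.concatenate([[1.0], exceed, [0.0]])     # cumulative logits' CDF values
    f = F * (1 - F)
    fp = f * (1 - 2 * F)
    ks = np.arange(K)
    # per-category score and curvature pieces at (theta0, beta=0)
    u = (f[ks] - f[ks + 1]) / pk
    w_aa = np.where(ks >= 1, fp[ks] / pk - (f[ks] / pk) ** 2, 0.0)
    w_bb = np.where(ks <= K - 2, -fp[ks + 1] / pk - (f[ks + 1] / pk) ** 2, 0.0)
    w_ab = np.where((ks >= 1) & (ks <= K - 2), f[ks] * f[ks + 1] / pk**2, 0.0)
    # expected per-observation information blocks (identical across i)
    diag = pk[1:] * w_aa[1:] + pk[: K - 1] * w_bb[: K - 1]
    off = pk[1 : K - 1] * w_ab[1 : K - 1]
    b1 = pk[1:] * (w_aa + w_ab)[1:] + pk[: K - 1] * (w_bb + w_ab)[: K - 1]
    c1 = float(np.sum(pk * (w_aa + 2 * w_ab + w_bb)))
    # Schur complement of -E[H]: theta block is n * tridiag(diag, off)
    ab = np.zeros((2, K - 1))
    ab[0] = -n * diag
    if K > 2:
        ab[1, : K - 2] = -n * off
    Bn = -np.outer(b1, Xm.sum(axis=0))
    W = solveh_banded(ab, Bn, lower=True)
    S = -c1 * (Xm.T @ Xm) - Bn.T @ W
    U = Xm.T @ u[kidx]
    chi2 = float(U @ np.linalg.solve(S, U))
    return chi2, p, float(sps.chi2.sf(chi2, p))


def lr_test(fit: CPMFit, null_fit: CPMFit | None = None) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square of ``fit`` against a nested null.

    Default null is the intercept-only model on the same data.
    """
    if null_fit is None:
        ll0, df = fit.loglik_null, fit.n_slopes
    else:
        if null_fit.n != fit.n or not set(null_fit.coefficients.index) <= set(
            fit.coefficients.index
        ):
            raise CPMError("models are not nested on the same data")
        ll0, df = null_fit.loglik, fit.n_slopes - null_fit.n_slopes
    chi2 = max(0.0, 2.0 * (fit.loglik - ll0))
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def nagelkerke_r2(fit: CPMFit) -> float:
    """Nagelkerke's rescaled likelihood-ratio R-squared."""
    n = fit.n
    cox_snell = 1.0 - np.exp(-(2.0 / n) * (fit.loglik - fit.loglik_null))
    maxv = 1.0 - np.exp((2.0 / n) * fit.loglik_null)
    return float(cox_snell / maxv) if maxv > 0 else 0.0


@dataclass
class InferenceSummary:
    """Per-predictor Wald inference plus whole-model fit statistics."""

    table: pd.DataFrame          # coef, se, aOR, ci_low, ci_high, wald_chi2, p
    lr_chi2: float
    lr_df: int
    lr_p: float
    nagelkerke_r2: float


def wald_summary(fit: CPMFit, ci_level: float = 0.95) -> InferenceSummary:
    """Adjusted odds ratios, Wald chi-squares and model-level fit for a CPM."""
    if fit.vcov is None:
        raise CPMError("fit has no slope covariance (null model or failed fit)")
    se = np.sqrt(np.diag(fit.vcov.to_numpy()))
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise CPMError("singular covariance; Wald inference unavailable")
    b = fit.coefficients.to_numpy()
    zq = sps.norm.ppf(0.5 + ci_level / 2)
    wald = (b / se) ** 2
    table = pd.DataFrame(
        {
            "coef": b,
            "se": se,
            "aOR": np.exp(b),
            "ci_low": np.exp(b - zq * se),
            "ci_high": np.exp(b + zq * se),
            "wald_chi2": wald,
            "p": sps.chi2.sf(wald, 1),
        },
        index=fit.coefficients.index,
    )
    chi2, df, p = lr_test(fit)
    return InferenceSummary(
        table=table, lr_chi2=chi2, lr_df=df, lr_p=p, nagelkerke_r2=nagelkerke_r2(fit)
    )


@dataclass
class ModelSearchResult:
    """Exhaustive best-subset search keyed by candidate subsets."""

    subsets: list[tuple[str, ...]]
    bics: np.ndarray
    weights: np.ndarray              # BIC weights, sum to 1
    best_subset: tuple[str, ...]
    best_fit: CPMFit
    baseline_bic: float
    bf10_vs_baseline: float

    def weight_of(self, subset) -> float:
        return float(self.weights[self.subsets.index(tuple(subset))])


def best_subset(
    y,
    X_base: pd.DataFrame,
    X_candidates: pd.DataFrame,
    force_base: bool = True,
    max_candidates: int = 15,
) -> ModelSearchResult:
    """All-subsets search over candidate predictors, baseline forced in.

    Fits baseline + S for every subset S of the candidate columns, ranks by
    BIC, and reports BIC weights and the approximate Bayes factor of the
    best model over the bare baseline.  With ``force_base=False`` the
    baseline columns join the candidate pool instead.
    """
    cand_cols = [str(c) for c in X_candidates.columns]
    if len(cand_cols) > max_candidates:
        raise CPMError(
            f"{len(cand_cols)} candidates exceed the exhaustive-search guard "
            f"({max_candidates})"
        )
    if not force_base:
        X_candidates = pd.concat([X_base, X_candidates], axis=1)
        X_base = X_base.iloc[:, :0]
        cand_cols = [str(c) for c in X_candidates.columns]
    subsets: list[tuple[str, ...]] = []
    fits: list[CPMFit] = []
    for r in range(len(cand_cols) + 1):
        for combo in itertools.combinations(cand_cols, r):
            X = pd.concat([X_base, X_candidates[list(combo)]], axis=1)
            subsets.append(combo)
            fits.append(fit_cpm(y, X if X.shape[1] else None))
    bics = np.array([f.bic for f in fits])
    delta = bics - bics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    best_i = int(np.argmin(bics))
    baseline_bic = bics[subsets.index(())]
    return ModelSearchResult(
        subsets=subsets,
        bics=bics,
        weights=w,
        best_subset=subsets[best_i],
        best_fit=fits[best_i],
        baseline_bic=float(baseline_bic),
        bf10_vs_baseline=float(np.exp((baseline_bic - bics[best_i]) / 2.0)),
    )


# --------------------------------------------------------------------------
# the study's two-step analysis on a participant table


BASELINE_PREDICTORS = ("diagnosis_asd", "sex_male", "age_years", "counterbalance_desc")


def design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns from a participant-level analysis table.

    Codes diagnosis ASD = 1, male sex = 1, descending-first counterbalance
    = 1; passes numeric columns through unchanged.
    """
    out = pd.DataFrame(index=df.index)
    out["diagnosis_asd"] = (df["diagnosis"].astype(str) == "ASD").astype(float)
    out["sex_male"] = (df["sex"].astype(str) == "M").astype(float)
    out["age_years"] = df["age_years"].astype(float)
    out["counterbalance_desc"] = (
        df["counterbalance"].astype(str) == "descending-first"
    ).astype(float)
    return out


@dataclass
class MechanismReport:
    """Baseline vs criterion-augmented CPM comparison on one dataset."""

    baseline: InferenceSummary
    augmented: InferenceSummary
    search: ModelSearchResult
    diagnosis_sig_baseline: bool
    criterion_selected: bool
    diagnosis_sig_augmented: bool
    criterion_largest_wald: bool
    n: int


def mechanism_scenario(
    df: pd.DataFrame,
    outcome: str = "threshold_g",
    criterion_col: str = "c",
    candidate_cols: tuple[str, ...] = ("az", "c"),
    alpha_level: float = 0.05,
) -> MechanismReport:
    """Does the response criterion supplant the diagnosis effect on thresholds?

    Fits the baseline CPM (diagnosis, sex, age, counterbalance order), runs
    the best-subset step over the candidate predictors, and refits with the
    criterion added, reporting (i) whether diagnosis is significant at
    baseline, (ii) whether the criterion enters the best subset, (iii)
    whether diagnosis stays significant once the criterion is included, and
    (iv) whether the criterion carries the largest Wald chi-square.
    """
    cols = [outcome, "diagnosis", "sex", "age_years", "counterbalance", *candidate_cols]
    data = df.dropna(subset=[c for c in cols if c in df.columns]).reset_index(drop=True)
    y = data[outcome].to_numpy(dtype=float)
    X_base = design_matrix(data)
    X_cand = data[list(candidate_cols)].astype(float)

    base_fit = fit_cpm(y, X_base)
    base_sum = wald_summary(base_fit)
    search = best_subset(y, X_base, X_cand)
    aug_fit = fit_cpm(y, pd.concat([X_base, data[[criterion_col]].astype(float)], axis=1))
    aug_sum = wald_summary(aug_fit)

    wald = aug_sum.table["wald_chi2"]
    return MechanismReport(
        baseline=base_sum,
        augmented=aug_sum,
        search=search,
        diagnosis_sig_baseline=bool(base_sum.table.loc["diagnosis_asd", "p"] < alpha_level),
        criterion_selected=criterion_col in search.best_subset,
        diagnosis_sig_augmented=bool(aug_sum.table.loc["diagnosis_asd", "p"] < alpha_level),
        criterion_largest_wald=bool(wald.idxmax() == criterion_col),
        n=len(data),
    )
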