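"""Equal-variance signal detection metrics for yes/no detection tasks.

A single session yields a hit count over stimulus trials and a false-alarm
count over catch (no-stimulus) trials.  Sensitivity is summarised by ``A_z``,
the area under the equal-variance ROC through the observed (F, H) point,

    A_z = Phi((Phi^-1(H) - Phi^-1(F)) / 2),

and response bias by the criterion

    c = -(Phi^-1(H) + Phi^-1(F)) / 2,

positive ``c`` meaning a conservative observer (biased toward "no" when
unsure).  Perfect hit rates and zero false-alarm rates are replaced by the
log-linear correction (k + 0.5)/(n + 1) so that both quantiles stay finite;
the mirrored corrections for H == 0 and F == 1 use the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "SDTCounts",
    "SDTMetrics",
    "corrected_hit_rate",
    "corrected_fa_rate",
    "az",
    "criterion_c",
    "metrics_from_counts",
]


class InvalidCountsError(ValueError):
    """Raised when trial counts are impossible (negative, or hits > trials)."""


def _check_counts(k: int, n: int, what: str) -> None:
    if n < 1:
        raise InvalidCountsError(f"need at least one {what} trial, got n={n}")
    if not 0 <= k <= n:
        raise InvalidCountsError(f"{what} 'yes' count {k} outside [0, {n}]")


def corrected_hit_rate(n_hits: int, n_stim: int) -> float:
    """Hit proportion with the log-linear correction at the boundaries.

    Returns ``n_hits / n_stim`` except at the extremes: a perfect score is
    replaced by ``(n_hits + 0.5) / (n_stim + 1)`` and a zero score by the
    mirrored ``0.5 / (n_stim + 1)``, keeping the result strictly inside (0, 1).
    """
    _check_counts(n_hits, n_stim, "stimulus")
    if n_hits == n_stim:
        return (n_hits + 0.5) / (n_stim + 1)
    if n_hits == 0:
        return 0.5 / (n_stim + 1)
    return n_hits / n_stim


def corrected_fa_rate(n_fa: int, n_catch: int) -> float:
    """False-alarm proportion with the log-linear correction at the boundaries.

    Returns ``n_fa / n_catch`` except at the extremes: zero false alarms are
    replaced by ``0.5 / (n_catch + 1)`` and an all-yes record by the mirrored
    ``(n_fa + 0.5) / (n_catch + 1)``.
    """
    _check_counts(n_fa, n_catch, "catch")
    if n_fa == 0:
        return 0.5 / (n_catch + 1)
    if n_fa == n_catch:
        return (n_fa + 0.5) / (n_catch + 1)
    return n_fa / n_catch


@dataclass(frozen=True)
class SDTCounts:
    """Raw yes/no counts for one session plus the corrected rates H and F."""

    n_stim: int
    n_hits: int
    n_catch: int
    n_fa: int

    def __post_init__(self) -> None:
        _check_counts(self.n_hits, self.n_stim, "stimulus")
        _check_counts(self.n_fa, self.n_catch, "catch")

    @property
    def H(self) -> float:
        return corrected_hit_rate(self.n_hits, self.n_stim)

    @property
    def F(self) -> float:
        return corrected_fa_rate(self.n_fa, self.n_catch)

    @property
    def h_corrected(self) -> bool:
        return self.n_hits in (0, self.n_stim)

    @property
    def f_corrected(self) -> bool:
        return self.n_fa in (0, self.n_catch)


@dataclass(frozen=True)
class SDTMetrics:
    """Sensitivity ``az`` in (0, 1) and criterion ``c`` (SD units, unbounded)."""

    az: float
    c: float


def _check_rate(p: float, name: str) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"{name} must lie strictly in (0, 1); got {p!r}. "
            "Apply the boundary corrections before computing metrics."
        )


def az(H: float, F: float) -> float:
    """Equal-variance ROC area through one (hit, false-alarm) pair.

    0.5 is chance (H == F); 1.0 would be perfect discrimination.
    """
    _check_rate(H, "H")
    _check_rate(F, "F")
    return float(norm.cdf((norm.ppf(H) - norm.ppf(F)) / 2.0))


def criterion_c(H: float, F: float) -> float:
    """Criterion location relative to the zero-bias point, in SD units.

    Positive values mean a conservative observer (both H and F pulled toward
    "no"); negative values a liberal one.
    """
    _check_rate(H, "H")
    _check_rate(F, "F")
    return float(-(norm.ppf(H) + norm.ppf(F)) / 2.0)


def metrics_from_counts(counts: SDTCounts) -> SDTMetrics:
    """Corrected rates -> (A_z, c) for one session's counts."""
    H, F = counts.H, counts.F
    return SDTMetrics(az=az(H, F), c=criterion_c(H, F))
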