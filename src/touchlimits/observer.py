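"""Simulated detection-task observers and cohort generation.

The task analyses assume an equal-variance Gaussian evidence model; the
simulator makes that model explicit so that the estimated statistics (A_z, c)
can be validated by parameter recovery.  Each observer is described by

* ``alpha`` — force (grams) at which the internal signal reaches 1 SD above
  the noise distribution,
* ``beta``  — growth of signal strength per log10-gram of force,
* ``lam``   — decision criterion on the evidence axis (SD units): respond
  "yes" iff the evidence sample exceeds ``lam``,
* ``lapse`` — probability of responding at random on any trial.

Signal strength is ``d(f) = max(0, beta * (log10 f - log10 alpha) + 1)``, so
``d(alpha) = 1`` and catch trials have ``d = 0``.  On a trial the observer
draws evidence ``X ~ Normal(d, 1)`` and answers yes iff ``X > lam``; hence
with no lapses the theoretical false-alarm rate is ``Phi(-lam)`` and the hit
rate at force f is ``Phi(d(f) - lam)``.

``lam`` is a *generative* criterion; the estimated statistic ``c`` depends on
the realised stimulus mix and coincides with ``lam`` only in expectation up to
a session-dependent monotone mapping — the recovery tests check monotonicity,
not identity.

Cohort generation draws per-participant parameters and covariates (age, sex,
IQ, SRS-2 T-score) from truncated normals per group, with group means chosen
to emulate a two-diagnosis (ASD / NT), two-age-band study in which the child
ASD group has the most conservative criterion while the groups share the same
sensitivity parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ObserverParams",
    "Dist",
    "GroupSpec",
    "CohortSpec",
    "ParticipantRecord",
    "signal_strength",
    "respond",
    "generate_cohort",
    "default_cohort_spec",
    "cohort_to_frame",
]

FORCE_MIN_G = 0.008
FORCE_MAX_G = 2.0


class ConfigError(ValueError):
    """Raised for impossible simulation configurations (e.g. hopeless truncation)."""


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated observer."""

    alpha: float
    beta: float
    lam: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not FORCE_MIN_G <= self.alpha <= FORCE_MAX_G:
            raise ConfigError(f"alpha must lie in [{FORCE_MIN_G}, {FORCE_MAX_G}] g")
        if self.beta <= 0:
            raise ConfigError("beta must be positive")
        if not 0.0 <= self.lapse <= 0.05:
            raise ConfigError("lapse must lie in [0, 0.05]")

    def respond(self, force: float | None, rng: np.random.Generator) -> bool:
        return respond(self, force, rng)


def signal_strength(obs: ObserverParams, force: float) -> float:
    """Mean evidence (SD units above noise) evoked by ``force`` grams.

    Clipped at zero: forces far below ``alpha`` are indistinguishable from no
    stimulus at all.
    """
    if force <= 0:
        raise ValueError("force must be positive (use force=None for catch trials)")
    return max(0.0, obs.beta * (math.log10(force) - math.log10(obs.alpha)) + 1.0)


def respond(obs: ObserverParams, force: float | None, rng: np.random.Generator) -> bool:
    """One yes/no decision; ``force=None`` encodes a catch trial."""
    if obs.lapse > 0.0 and rng.random() < obs.lapse:
        return bool(rng.random() < 0.5)
    d = 0.0 if force is None else signal_strength(obs, force)
    return bool(d + rng.standard_normal() > obs.lam)


# --------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class Dist:
    """Truncated-normal spec: mean, sd, and truncation bounds."""

    mean: float
    sd: float
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("sd must be non-negative")
        if self.low >= self.high:
            raise ConfigError("empty truncation interval")


_MAX_REJECTION_DRAWS = 1000


def _draw_trunc(dist: Dist, rng: np.random.Generator) -> tuple[float, float]:
    """One truncated-normal draw by rejection; returns (value, z-score used)."""
    if dist.sd == 0:
        if not dist.low <= dist.mean <= dist.high:
            raise ConfigError("degenerate distribution outside truncation bounds")
        return dist.mean, 0.0
    for _ in range(_MAX_REJECTION_DRAWS):
        z = rng.standard_normal()
        x = dist.mean + dist.sd * z
        if dist.low <= x <= dist.high:
            return x, z
    raise ConfigError(
        f"rejection sampling failed after {_MAX_REJECTION_DRAWS} draws for {dist}"
    )


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distributions for one diagnosis x age-band cell."""

    n: int
    diagnosis: str          # "ASD" | "NT"
    age_band: str           # "child" | "adult"
    alpha: Dist
    beta: Dist
    lam: Dist
    lapse: Dist
    age_years: Dist
    fsiq: Dist
    viq: Dist
    piq: Dist
    srs_t: Dist
    female_prop: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("each group needs n >= 1")
        if not 0.0 <= self.female_prop <= 1.0:
            raise ConfigError("female_prop must lie in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.diagnosis}-{self.age_band}"


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort: one GroupSpec per cell plus cross-variable structure.

    ``srs_lam_corr`` injects a Gaussian-copula correlation between the SRS-2
    T-score and the observer's criterion ``lam`` within each group, so that
    criterion-symptom correlation analyses have signal to find.
    """

    groups: tuple[GroupSpec, ...]
    seed: int = 0
    srs_lam_corr: float = 0.3

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigError("cohort needs at least one group")
        if not -1.0 < self.srs_lam_corr < 1.0:
            raise ConfigError("srs_lam_corr must lie in (-1, 1)")


@dataclass(frozen=True)
class ParticipantRecord:
    """One simulated participant: identity, covariates, true observer."""

    participant_id: str
    group: str
    diagnosis: str
    age_band: str
    age_years: float
    sex: str                # "M" | "F"
    fsiq: float
    viq: float
    piq: float
    srs_t: float
    observer: ObserverParams
    counterbalance: str = "ascending-first"


def _default_group(diagnosis: str, age_band: str, **overrides) -> GroupSpec:
    base = dict(
        alpha=Dist(0.05, 0.015, FORCE_MIN_G, FORCE_MAX_G),
        beta=Dist(2.0, 0.3, 0.5, 5.0),
        lapse=Dist(0.02, 0.01, 0.0, 0.05),
    )
    base.update(overrides)
    return GroupSpec(diagnosis=diagnosis, age_band=age_band, **base)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Study-like default cohort: 55/35 children and 33/24 adults (ASD/NT).

    Covariate means and SDs follow the emulated study's descriptive tables.
    The generative criterion means were calibrated once by forward
    simulation so that the *estimated* statistics reproduce the study's
    qualitative pattern: mean estimated c of roughly 0.55 for NT children
    versus 0.77 for ASD children (the child groups share identical
    sensitivity parameters, so their threshold gap is criterion-driven by
    construction), similar c for the two adult groups, and an adult-only
    sensitivity gap (NT adults get the lowest alpha).  Note the evidence-axis
    criterion ``lam`` must sit well above the estimated ``c`` it produces,
    because the session hit rate pools sub-threshold stimulus trials.
    """
    iq = dict(low=70.0, high=160.0)
    srs_asd = Dist(73.0, 10.0, 30.0, 110.0)
    srs_nt = Dist(44.0, 6.0, 30.0, 110.0)
    groups = (
        _default_group(
            "ASD", "child", n=55,
            lam=Dist(1.70, 0.42, 0.0, 3.5),
            age_years=Dist(10.91, 3.35, 7.0, 17.99),
            fsiq=Dist(103.5, 16.3, **iq), viq=Dist(100.5, 17.9, **iq),
            piq=Dist(105.1, 15.3, **iq), srs_t=srs_asd,
            female_prop=9 / 55,
        ),
        _default_group(
            "NT", "child", n=35,
            lam=Dist(1.25, 0.28, 0.0, 3.5),
            age_years=Dist(9.49, 2.61, 7.0, 17.99),
            fsiq=Dist(114.3, 15.5, **iq), viq=Dist(111.3, 12.8, **iq),
            piq=Dist(112.9, 18.2, **iq), srs_t=srs_nt,
            female_prop=9 / 35,
        ),
        _default_group(
            "ASD", "adult", n=33,
            lam=Dist(1.65, 0.50, 0.0, 3.5),
            alpha=Dist(0.065, 0.02, FORCE_MIN_G, FORCE_MAX_G),
            age_years=Dist(28.21, 8.92, 18.0, 54.99),
            fsiq=Dist(106.4, 15.4, **iq), viq=Dist(103.1, 13.5, **iq),
            piq=Dist(105.7, 20.6, **iq), srs_t=srs_asd,
            female_prop=12 / 33,
        ),
        _default_group(
            "NT", "adult", n=24,
            lam=Dist(1.70, 0.45, 0.0, 3.5),
            alpha=Dist(0.035, 0.012, FORCE_MIN_G, FORCE_MAX_G),
            beta=Dist(2.4, 0.3, 0.5, 5.0),
            age_years=Dist(28.46, 4.77, 18.0, 54.99),
            fsiq=Dist(107.7, 15.9, **iq), viq=Dist(107.5, 16.1, **iq),
            piq=Dist(107.5, 15.9, **iq), srs_t=srs_nt,
            female_prop=10 / 24,
        ),
    )
    return CohortSpec(groups=groups, seed=seed)


def generate_cohort(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> list[ParticipantRecord]:
    """Draw a cohort; deterministic for a given spec (seed) / generator.

    Counterbalance (which block direction opens the session) is alternated
    over a randomly permuted participant order, so the two orders differ in
    count by at most one overall.
    """
    from .protocol import counterbalance_assign  # local import avoids a cycle

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    records: list[ParticipantRecord] = []
    for g in spec.groups:
        for i in range(g.n):
            lam, z_lam = _draw_trunc(g.lam, rng)
            obs = ObserverParams(
                alpha=_draw_trunc(g.alpha, rng)[0],
                beta=_draw_trunc(g.beta, rng)[0],
                lam=lam,
                lapse=_draw_trunc(g.lapse, rng)[0],
            )
            rho = spec.srs_lam_corr
            # Gaussian copula: shared z for lam, fresh z for the SRS residual
            srs = None
            for _ in range(_MAX_REJECTION_DRAWS):
                z = rho * z_lam + math.sqrt(1 - rho * rho) * rng.standard_normal()
                x = g.srs_t.mean + g.srs_t.sd * z
                if g.srs_t.low <= x <= g.srs_t.high:
                    srs = x
                    break
            if srs is None:
                raise ConfigError("SRS truncation bounds unattainable")
            records.append(
                ParticipantRecord(
                    participant_id=f"{g.label}-{i + 1:03d}",
                    group=g.label,
                    diagnosis=g.diagnosis,
                    age_band=g.age_band,
                    age_years=_draw_trunc(g.age_years, rng)[0],
                    sex="F" if rng.random() < g.female_prop else "M",
                    fsiq=_draw_trunc(g.fsiq, rng)[0],
                    viq=_draw_trunc(g.viq, rng)[0],
                    piq=_draw_trunc(g.piq, rng)[0],
                    srs_t=srs,
                    observer=obs,
                )
            )
    order = counterbalance_assign([r.participant_id for r in records], rng=rng)
    return [replace(r, counterbalance=order[r.participant_id]) for r in records]


def cohort_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Tidy one-row-per-participant table, true observer parameters included."""
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "diagnosis": r.diagnosis,
                "age_band": r.age_band,
                "age_years": r.age_years,
                "sex": r.sex,
                "fsiq": r.fsiq,
                "viq": r.viq,
                "piq": r.piq,
                "srs_t": r.srs_t,
                "counterbalance": r.counterbalance,
                "true_alpha": r.observer.alpha,
                "true_beta": r.observer.beta,
                "true_lam": r.observer.lam,
                "true_lapse": r.observer.lapse,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# YAML round-trip for cohort specs


def _dist_from_obj(obj) -> Dist:
    if isinstance(obj, dict):
        return Dist(**obj)
    mean, sd, *bounds = obj
    return Dist(mean, sd, *bounds)


def cohort_spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from a YAML mapping (see docs for the schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = []
    for g in raw["groups"]:
        kwargs = {k: v for k, v in g.items()}
        for key in ("alpha", "beta", "lam", "lapse", "age_years",
                    "fsiq", "viq", "piq", "srs_t"):
            kwargs[key] = _dist_from_obj(kwargs[key])
        groups.append(GroupSpec(**kwargs))
    return CohortSpec(
        groups=tuple(groups),
        seed=int(raw.get("seed", 0)),
        srs_lam_corr=float(raw.get("srs_lam_corr", 0.3)),
    )
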