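"""Method-of-limits von Frey threshold protocol.

One session is four alternating blocks (two ascending, two descending;
which direction opens is counterbalanced across participants).  A descending
block starts at the heaviest filament and steps down one rung per stimulus
trial until the participant answers "no" on two consecutive stimulus trials;
an ascending block starts at the lightest rung and runs until two consecutive
"yes" responses.  Catch trials (no stimulus) are interleaved — 3 per
ascending and 7 per descending block, giving 20 per session — and a "yes" on
a catch trial triggers false-positive feedback.  The block threshold averages
the filament forces bracketing the terminating response pair; the session
threshold averages the four block thresholds.  Sessions with more than three
catch-trial "yes" responses inside any 10-trial window of a block are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sdt import SDTCounts, metrics_from_counts

__all__ = [
    "DEFAULT_FILAMENTS_G",
    "FilamentSet",
    "ProtocolConfig",
    "TrialRecord",
    "Block",
    "Session",
    "run_block",
    "run_session",
    "block_threshold",
    "session_threshold",
    "session_sdt_counts",
    "exclusion_check",
    "counterbalance_assign",
    "simulate_sessions",
]

# 10 log-spaced rungs spanning the study's stated 0.008-2.0 g range
DEFAULT_FILAMENTS_G = (0.008, 0.015, 0.028, 0.052, 0.097, 0.18, 0.33, 0.62, 1.15, 2.0)

ASCENDING = "ascending"
DESCENDING = "descending"


class ProtocolError(ValueError):
    """Invalid protocol configuration."""


@dataclass(frozen=True)
class FilamentSet:
    """Ordered ladder of filament forces in grams, lightest first."""

    forces: tuple[float, ...] = DEFAULT_FILAMENTS_G

    def __post_init__(self) -> None:
        f = self.forces
        if len(f) < 2:
            raise ProtocolError("ladder needs at least two rungs")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ProtocolError("ladder forces must be strictly increasing")
        if f[0] <= 0:
            raise ProtocolError("forces must be positive")

    def __len__(self) -> int:
        return len(self.forces)


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol options.

    ``threshold_rule``:
      * ``"adjacent"`` (default) — average the force last presented before
        the first terminating response with the force of that first
        terminating response;
      * ``"pair"`` — bracket the whole terminating pair (last pre-pair force
        averaged with the second terminating force).

    ``exclusion_rule``:
      * ``"window"`` (default) — exclude if any contiguous 10-trial window
        within a block holds more than ``exclusion_max_fa`` catch "yes";
      * ``"block"`` — apply the count to the whole block.
    """

    filaments: FilamentSet = FilamentSet()
    catch_quota_ascending: int = 3
    catch_quota_descending: int = 7
    threshold_rule: str = "adjacent"
    exclusion_rule: str = "window"
    exclusion_max_fa: int = 3
    exclusion_window: int = 10

    def __post_init__(self) -> None:
        if self.catch_quota_ascending < 0 or self.catch_quota_descending < 0:
            raise ProtocolError("catch quotas must be non-negative")
        if self.threshold_rule not in ("adjacent", "pair"):
            raise ProtocolError("threshold_rule must be 'adjacent' or 'pair'")
        if self.exclusion_rule not in ("window", "block"):
            raise ProtocolError("exclusion_rule must be 'window' or 'block'")

    def quota(self, direction: str) -> int:
        return (
            self.catch_quota_ascending
            if direction == ASCENDING
            else self.catch_quota_descending
        )


@dataclass(frozen=True)
class TrialRecord:
    """One trial: a filament presentation or a catch trial."""

    block_index: int            # 1..4
    position: int               # 1-based within block
    kind: str                   # "stimulus" | "catch"
    force_g: float | None       # None for catch trials
    response: bool              # True = "yes"
    feedback_given: bool = False  # false-positive feedback on (catch, yes)


@dataclass(frozen=True)
class Block:
    direction: str
    trials: tuple[TrialRecord, ...]
    terminal_pair_index: int | None  # position of first of the 2 terminating responses
    exhausted: bool                  # ladder ran out before termination


@dataclass(frozen=True)
class Session:
    participant_id: str
    counterbalance: str              # "ascending-first" | "descending-first"
    blocks: tuple[Block, ...]
    excluded: bool
    threshold_g: float | None        # None when excluded
    sdt: SDTCounts
    any_exhausted: bool


def _stub_rng() -> np.random.Generator:
    return np.random.default_rng(0)


def run_block(
    obs,
    direction: str,
    config: ProtocolConfig = ProtocolConfig(),
    rng: np.random.Generator | None = None,
    block_index: int = 1,
) -> Block:
    """Run one block against an observer exposing ``respond(force, rng)``.

    Stimulus trials walk the ladder one rung at a time from the direction's
    extreme; only stimulus responses feed the two-consecutive termination
    counter.  The catch quota is placed online: before each stimulus trial a
    catch trial is inserted with probability (catch remaining) / (expected
    trials remaining); quota left over at termination is inserted just before
    the final trial.
    """
    if direction not in (ASCENDING, DESCENDING):
        raise ProtocolError(f"unknown direction {direction!r}")
    if rng is None:
        rng = _stub_rng()
    ladder = list(config.filaments.forces)
    if direction == DESCENDING:
        ladder = ladder[::-1]
    target = direction == ASCENDING  # terminating response: yes asc / no desc
    quota = config.quota(direction)

    trials: list[TrialRecord] = []
    catch_left = quota
    consec = 0
    terminal_pos: int | None = None
    for i, force in enumerate(ladder):
        stim_left = len(ladder) - i
        while catch_left > 0 and rng.random() < catch_left / (stim_left + catch_left):
            resp = obs.respond(None, rng)
            trials.append(
                TrialRecord(block_index, len(trials) + 1, "catch", None, resp, resp)
            )
            catch_left -= 1
        resp = obs.respond(force, rng)
        trials.append(
            TrialRecord(block_index, len(trials) + 1, "stimulus", force, resp)
        )
        consec = consec + 1 if resp == target else 0
        if consec == 2:
            break
    exhausted = consec < 2
    # leftover catch trials go immediately before the final trial
    if catch_left > 0:
        extra = []
        for _ in range(catch_left):
            resp = obs.respond(None, rng)
            extra.append(TrialRecord(block_index, 0, "catch", None, resp, resp))
        trials = trials[:-1] + extra + trials[-1:]
        trials = [
            TrialRecord(t.block_index, pos, t.kind, t.force_g, t.response, t.feedback_given)
            for pos, t in enumerate(trials, start=1)
        ]
    if not exhausted:
        # position of the first of the two consecutive terminating responses:
        # the second-to-last stimulus trial
        stim_positions = [t.position for t in trials if t.kind == "stimulus"]
        terminal_pos = stim_positions[-2]
    return Block(direction, tuple(trials), terminal_pos, exhausted)


def block_threshold(block: Block, rule: str = "adjacent") -> float:
    """Threshold in grams for one block.

    ``"adjacent"``: mean of the force presented immediately before the first
    terminating response and the force of that first terminating response.
    ``"pair"``: mean of the force before the terminating pair and the force
    of the *second* terminating response.  A block whose ladder was exhausted
    without termination returns the extreme rung it ended on.
    """
    stim = [t for t in block.trials if t.kind == "stimulus"]
    if block.exhausted or block.terminal_pair_index is None:
        return float(stim[-1].force_g)
    first_term = next(t for t in stim if t.position == block.terminal_pair_index)
    idx = stim.index(first_term)
    if rule == "adjacent":
        after = first_term.force_g
    elif rule == "pair":
        after = stim[idx + 1].force_g
    else:
        raise ProtocolError(f"unknown threshold rule {rule!r}")
    before = stim[idx - 1].force_g if idx > 0 else first_term.force_g
    return float((before + after) / 2.0)


def session_threshold(blocks: Sequence[Block], rule: str = "adjacent") -> float:
    """Arithmetic mean of the four block thresholds, in grams."""
    return float(np.mean([block_threshold(b, rule) for b in blocks]))


def session_sdt_counts(blocks: Sequence[Block]) -> SDTCounts:
    """Pool hits/stimulus trials and false alarms/catch trials over all blocks."""
    n_stim = n_hits = n_catch = n_fa = 0
    for b in blocks:
        for t in b.trials:
            if t.kind == "stimulus":
                n_stim += 1
                n_hits += t.response
            else:
                n_catch += 1
                n_fa += t.response
    return SDTCounts(n_stim=n_stim, n_hits=n_hits, n_catch=n_catch, n_fa=n_fa)


def exclusion_check(blocks: Sequence[Block], config: ProtocolConfig = ProtocolConfig()) -> bool:
    """True iff the catch false-alarm exclusion rule fires in any block.

    Default reading: some contiguous window of 10 trials within a single
    block holds strictly more than 3 catch trials answered "yes".
    """
    limit = config.exclusion_max_fa
    for b in blocks:
        flags = [t.kind == "catch" and t.response for t in b.trials]
        if config.exclusion_rule == "block":
            if sum(flags) > limit:
                return True
            continue
        w = min(config.exclusion_window, len(flags))
        for start in range(len(flags) - w + 1):
            if sum(flags[start : start + w]) > limit:
                return True
    return False


def run_session(
    obs,
    counterbalance: str = "ascending-first",
    config: ProtocolConfig = ProtocolConfig(),
    rng: np.random.Generator | None = None,
    participant_id: str = "sim",
) -> Session:
    """Four alternating blocks -> threshold, SDT counts, exclusion flag."""
    if counterbalance not in ("ascending-first", "descending-first"):
        raise ProtocolError(f"unknown counterbalance {counterbalance!r}")
    if rng is None:
        rng = _stub_rng()
    first = ASCENDING if counterbalance == "ascending-first" else DESCENDING
    second = DESCENDING if first == ASCENDING else ASCENDING
    order = (first, second, first, second)
    blocks = tuple(
        run_block(obs, d, config, rng, block_index=i + 1) for i, d in enumerate(order)
    )
    excluded = exclusion_check(blocks, config)
    thr = None if excluded else session_threshold(blocks, config.threshold_rule)
    return Session(
        participant_id=participant_id,
        counterbalance=counterbalance,
        blocks=blocks,
        excluded=excluded,
        threshold_g=thr,
        sdt=session_sdt_counts(blocks),
        any_exhausted=any(b.exhausted for b in blocks),
    )


def counterbalance_assign(
    participant_ids: Sequence[str],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Alternate ascending-/descending-first over a shuffled participant order."""
    if not participant_ids:
        raise ProtocolError("need at least one participant")
    if rng is None:
        rng = np.random.default_rng(seed)
    order = list(participant_ids)
    rng.shuffle(order)
    labels = ("ascending-first", "descending-first")
    return {pid: labels[i % 2] for i, pid in enumerate(order)}


# --------------------------------------------------------------------------
# cohort-level convenience


def simulate_sessions(records, config=ProtocolConfig(), rng=None, seed=None):
    """Run the full protocol for a cohort; returns (sessions, summary frame).

    The summary holds one row per participant: threshold, SDT counts and
    metrics, exclusion flags — the analysis-ready table the statistics
    modules consume.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(seed)
    sessions, rows = [], []
    for r in records:
        s = run_session(
            r.observer, r.counterbalance, config, rng, participant_id=r.participant_id
        )
        sessions.append(s)
        m = None if s.excluded else metrics_from_counts(s.sdt)
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
                "threshold_g": s.threshold_g,
                "n_stim": s.sdt.n_stim,
                "n_hits": s.sdt.n_hits,
                "n_catch": s.sdt.n_catch,
                "n_fa": s.sdt.n_fa,
                "az": None if m is None else m.az,
                "c": None if m is None else m.c,
                "excluded": s.excluded,
                "any_exhausted": s.any_exhausted,
                "true_lam": r.observer.lam,
                "true_alpha": r.observer.alpha,
                "true_beta": r.observer.beta,
            }
        )
    return sessions, pd.DataFrame(rows)


def trials_to_frame(sessions: Sequence[Session]):
    """Tidy trial-level log (participant, block, position, kind, force, response)."""
    import pandas as pd

    rows = []
    for s in sessions:
        for b in s.blocks:
            for t in b.trials:
                rows.append(
                    {
                        "participant_id": s.participant_id,
                        "block_index": t.block_index,
                        "direction": b.direction,
                        "position": t.position,
                        "kind": t.kind,
                        "force_g": t.force_g,
                        "response": "yes" if t.response else "no",
                        "feedback": t.feedback_given,
                    }
                )
    return pd.DataFrame(rows)
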