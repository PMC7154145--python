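"""Method-of-limits engine: blocks, termination, thresholds, exclusion."""

import numpy as np
import pytest

from conftest import AlwaysObserver, StubObserver
from touchlimits.observer import ObserverParams
from touchlimits.protocol import (
    DEFAULT_FILAMENTS_G,
    FilamentSet,
    ProtocolConfig,
    ProtocolError,
    block_threshold,
    counterbalance_assign,
    exclusion_check,
    run_block,
    run_session,
    session_sdt_counts,
    session_threshold,
)


def test_default_ladder_shape():
    f = FilamentSet()
    assert len(f) == 10
    assert f.forces[0] == 0.008 and f.forces[-1] == 2.0
    assert all(b > a for a, b in zip(f.forces, f.forces[1:]))


def test_bad_ladders_rejected():
    with pytest.raises(ProtocolError):
        FilamentSet((0.5,))
    with pytest.raises(ProtocolError):
        FilamentSet((0.5, 0.4))
    with pytest.raises(ProtocolError):
        ProtocolConfig(threshold_rule="midpoint")


def test_descending_hand_trace(rng):
    """Cut at 0.4 g: yes down to 0.62, then no at 0.33 and 0.18 terminates."""
    block = run_block(StubObserver(0.4), "descending", rng=rng)
    stim = [t for t in block.trials if t.kind == "stimulus"]
    forces = [t.force_g for t in stim]
    assert forces == [2.0, 1.15, 0.62, 0.33, 0.18]
    assert [t.response for t in stim] == [True, True, True, False, False]
    assert not block.exhausted
    # first terminating response is the 'no' at 0.33
    first_term = next(t for t in stim if t.position == block.terminal_pair_index)
    assert first_term.force_g == 0.33
    assert block_threshold(block) == pytest.approx((0.62 + 0.33) / 2)


def test_ascending_hand_trace(rng):
    block = run_block(StubObserver(0.05), "ascending", rng=rng)
    stim = [t for t in block.trials if t.kind == "stimulus"]
    assert [t.force_g for t in stim] == [0.008, 0.015, 0.028, 0.052, 0.097]
    assert [t.response for t in stim] == [False, False, False, True, True]
    assert block_threshold(block) == pytest.approx((0.028 + 0.052) / 2)


def test_pair_rule_brackets_whole_terminating_pair(rng):
    block = run_block(StubObserver(0.4), "descending", rng=rng)
    # 'pair' averages the last yes (0.62) with the second no (0.18)
    assert block_threshold(block, rule="pair") == pytest.approx((0.62 + 0.18) / 2)


def test_always_no_ascending_exhausts_ladder(rng):
    block = run_block(AlwaysObserver(False), "ascending", rng=rng)
    assert block.exhausted
    assert block.terminal_pair_index is None
    assert block_threshold(block) == 2.0  # flagged at the extreme rung


def test_immediate_termination_uses_extreme(rng):
    """Two opening 'no's in a descending block: no preceding force exists."""
    block = run_block(AlwaysObserver(False), "descending", rng=rng)
    stim = [t for t in block.trials if t.kind == "stimulus"]
    assert [t.force_g for t in stim] == [2.0, 1.15]
    assert block_threshold(block) == pytest.approx(2.0)


@pytest.mark.parametrize("direction,quota", [("ascending", 3), ("descending", 7)])
def test_catch_quota_always_met(direction, quota, rng):
    for _ in range(25):
        block = run_block(StubObserver(0.1), direction, rng=rng)
        assert sum(t.kind == "catch" for t in block.trials) == quota


def test_catch_feedback_on_false_alarms_only(rng):
    block = run_block(StubObserver(0.4, catch_yes=True), "descending", rng=rng)
    for t in block.trials:
        assert t.feedback_given == (t.kind == "catch" and t.response)


def test_catch_trials_do_not_reset_termination(rng):
    """A yes-on-catch between two terminating 'no's must not restart the count."""
    block = run_block(StubObserver(0.4, catch_yes=True), "descending", rng=rng)
    stim = [t for t in block.trials if t.kind == "stimulus"]
    assert [t.force_g for t in stim] == [2.0, 1.15, 0.62, 0.33, 0.18]


def test_session_threshold_examples():
    assert float(np.mean([0.5, 0.5, 0.055, 0.055])) == pytest.approx(0.2775)


def test_session_structure_and_counts(rng):
    s = run_session(StubObserver(0.1), "descending-first", rng=rng)
    assert len(s.blocks) == 4
    directions = [b.direction for b in s.blocks]
    assert directions == ["descending", "ascending", "descending", "ascending"]
    assert s.sdt.n_catch == 20  # 2 x 7 + 2 x 3
    assert s.sdt.n_fa == 0
    assert not s.excluded


def test_session_threshold_is_block_mean(rng):
    s = run_session(StubObserver(0.4), "ascending-first", rng=rng)
    per_block = [block_threshold(b) for b in s.blocks]
    assert s.threshold_g == pytest.approx(np.mean(per_block))
    # permutation invariance of the averaging
    assert s.threshold_g == pytest.approx(np.mean(sorted(per_block)))


def test_always_yes_observer_is_excluded(rng):
    s = run_session(AlwaysObserver(True), "descending-first", rng=rng)
    assert s.excluded
    assert s.threshold_g is None
    assert s.sdt.n_fa == 20


def test_exclusion_boundary_exactly_three_not_excluded(rng):
    """3 catch-yes in a 10-trial window stays in ('more than three' rule)."""

    class ThreeFA(StubObserver):
        def __init__(self):
            super().__init__(0.4)
            self.fa_left = 3

        def respond(self, force, rng):
            if force is None and self.fa_left > 0:
                self.fa_left -= 1
                return True
            return super().respond(force, rng)

    s = run_session(ThreeFA(), "descending-first", rng=rng)
    assert s.sdt.n_fa == 3
    assert not s.excluded


def test_block_rule_switch(rng):
    cfg = ProtocolConfig(exclusion_rule="block")
    blocks = run_session(AlwaysObserver(True), "descending-first", cfg, rng).blocks
    assert exclusion_check(blocks, cfg)


def test_sdt_counts_match_enumeration(rng):
    s = run_session(StubObserver(0.4), "ascending-first", rng=rng)
    n_stim = sum(t.kind == "stimulus" for b in s.blocks for t in b.trials)
    n_hits = sum(
        t.kind == "stimulus" and t.response for b in s.blocks for t in b.trials
    )
    assert (s.sdt.n_stim, s.sdt.n_hits) == (n_stim, n_hits)
    # the stub answers yes exactly to forces >= 0.4 g
    assert n_hits == sum(
        t.kind == "stimulus" and t.force_g >= 0.4 for b in s.blocks for t in b.trials
    )


def test_counterbalance_assign_splits():
    four = counterbalance_assign(list("abcd"), seed=0)
    assert sorted(four.values()).count("ascending-first") == 2
    five = counterbalance_assign(list("abcde"), seed=0)
    counts = list(five.values())
    assert abs(counts.count("ascending-first") - counts.count("descending-first")) == 1
    assert counterbalance_assign(list("abcde"), seed=7) == counterbalance_assign(
        list("abcde"), seed=7
    )
    with pytest.raises(ProtocolError):
        counterbalance_assign([])


def test_blocks_reproducible_under_seed():
    obs = ObserverParams(alpha=0.05, beta=2.0, lam=1.4, lapse=0.02)
    a = run_block(obs, "descending", rng=np.random.default_rng(77))
    b = run_block(obs, "descending", rng=np.random.default_rng(77))
    assert a == b


def test_threshold_within_ladder_range(rng):
    obs = ObserverParams(alpha=0.05, beta=2.0, lam=1.2, lapse=0.02)
    for _ in range(30):
        s = run_session(obs, "ascending-first", rng=rng)
        if s.threshold_g is not None:
            assert DEFAULT_FILAMENTS_G[0] <= s.threshold_g <= DEFAULT_FILAMENTS_G[-1]
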