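import numpy as np
import pytest

from touchlimits.observer import default_cohort_spec, generate_cohort
from touchlimits.protocol import simulate_sessions


class StubObserver:
    """Deterministic observer: yes iff force >= cut; always no on catch."""

    def __init__(self, cut: float, catch_yes: bool = False):
        self.cut = cut
        self.catch_yes = catch_yes

    def respond(self, force, rng):
        if force is None:
            return self.catch_yes
        return force >= self.cut


class AlwaysObserver:
    """Answers the same thing on every trial, stimulus or catch."""

    def __init__(self, answer: bool):
        self.answer = answer

    def respond(self, force, rng):
        return self.answer


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def default_summary():
    """One simulated default cohort with scored sessions (session-scoped)."""
    records = generate_cohort(default_cohort_spec(seed=11))
    sessions, summary = simulate_sessions(records, seed=12)
    return records, sessions, summary
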