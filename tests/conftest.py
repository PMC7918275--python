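"""Shared fixtures: tiny deterministic streams and session-scoped cohorts."""

import numpy as np
import pytest

from chronotap import AnalysisConfig, EventStream, synth


@pytest.fixture
def simple_stream():
    """Three sessions over two hours with hand-checkable latencies."""
    events = []
    # session: screen_on, unlock after 1.5 s, home, app launch after 0.8 s, touches
    def session(t0, intervals_s):
        ev = [(t0, "screen_on"), (t0 + 1.5, "unlock_complete"),
              (t0 + 1.8, "home_shown"), (t0 + 2.6, "app_launch")]
        t = t0 + 2.8
        ev.append((t, "touch"))
        for dt in intervals_s:
            t += dt
            ev.append((t, "touch"))
        ev.append((t + 0.5, "screen_off"))
        return ev

    events += session(100.0, [0.1, 0.2, 0.3, 0.4])
    events += session(700.0, [0.25, 0.25])
    events += session(4000.0, [0.2, 0.2, 0.2])
    events.sort()
    return EventStream(
        "simple",
        np.array([e[0] for e in events]),
        np.array([e[1] for e in events], dtype=object),
    )


@pytest.fixture(scope="session")
def default_cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, 21 days, default generating parameters."""
    cfg = synth.SynthConfig(n_subjects=6, days=21, seed=7)
    return cfg, synth.generate_cohort(cfg)
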