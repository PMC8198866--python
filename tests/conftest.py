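"""Shared fixtures: simulated recordings reused across test modules."""

from datetime import datetime

import numpy as np
import pytest

from popai.sensor_io import EventTimeline, Posture, PostureEvent
from popai.synthetic import BehaviourProfile, simulate_participant

EPOCH = datetime(2021, 3, 1, 0, 0, 0)


@pytest.fixture(scope="session")
def profile() -> BehaviourProfile:
    return BehaviourProfile()


@pytest.fixture(scope="session")
def sim_day(profile):
    """One simulated participant, one day, fixed seed."""
    return simulate_participant(profile, n_days=1, seed=42, participant="S001")


@pytest.fixture(scope="session")
def sim_two_days(profile):
    return simulate_participant(profile, n_days=2, seed=7, participant="S002")


def make_timeline(specs, epoch=EPOCH, start=0.0) -> EventTimeline:
    """Build a contiguous timeline from (duration_s, posture, steps) specs."""
    events = []
    t = start
    for duration, posture, *rest in specs:
        steps = rest[0] if rest else 0
        events.append(PostureEvent(t, duration, posture, steps))
        t += duration
    return EventTimeline(tuple(events), epoch)


@pytest.fixture
def timeline_builder():
    return make_timeline
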