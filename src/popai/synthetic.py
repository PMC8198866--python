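"""Semi-Markov simulator of multi-day dual-sensor recordings.

The generator emulates office-worker-like free-living behaviour recorded
simultaneously by a thigh-worn posture sensor and a waist-worn movement
sensor. Behaviour is modelled as a semi-Markov chain over six states —
one nightly BED block plus five waking states (inactive/active sitting,
inactive/active standing, stepping) with log-normal dwell times. From the
state timeline the simulator derives:

* a posture **event timeline** (the posture sensor sees SIT / STAND / STEP
  only; it cannot see intensity, so both sitting states collapse to SIT and
  both standing states to STAND);
* a per-second tri-axial **counts series** (per-minute gamma draws from the
  occupying state's intensity distribution, spread over seconds);
* two **raw acceleration streams** (posture-dependent gravity orientation
  plus state-dependent movement and white noise), optionally offset by a
  configurable inter-sensor lag;
* a :class:`GroundTruth` object with the state timeline, injected lag and
  non-wear intervals, and exact per-day sedentary/active-sitting totals.

Everything is a pure function of ``(profile, n_days, seed)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .sensor_io import (
    CountsSeries,
    EventTimeline,
    Placement,
    Posture,
    PostureEvent,
    RawRecording,
)

__all__ = [
    "State",
    "BehaviourProfile",
    "GroundTruth",
    "SimulatedParticipant",
    "simulate_participant",
    "simulate_cohort",
    "inject_lag",
    "inject_nonwear",
    "shift_counts",
]

SECONDS_PER_DAY = 86400.0


class State(enum.Enum):
    BED = "bed"
    SIT_INACTIVE = "sit_inactive"
    SIT_ACTIVE = "sit_active"
    STAND_INACTIVE = "stand_inactive"
    STAND_ACTIVE = "stand_active"
    STEP = "step"


WAKE_STATES = (
    State.SIT_INACTIVE,
    State.SIT_ACTIVE,
    State.STAND_INACTIVE,
    State.STAND_ACTIVE,
    State.STEP,
)

STATE_TO_POSTURE = {
    State.BED: Posture.SIT,  # lying: the posture sensor reports sit/lie
    State.SIT_INACTIVE: Posture.SIT,
    State.SIT_ACTIVE: Posture.SIT,
    State.STAND_INACTIVE: Posture.STAND,
    State.STAND_ACTIVE: Posture.STAND,
    State.STEP: Posture.STEP,
}

SIT_STATES = (State.SIT_INACTIVE, State.SIT_ACTIVE)


@dataclass(frozen=True)
class BehaviourProfile:
    """Parameters of the behaviour and signal generator.

    Dwell times are log-normal with the given mean (minutes) and log-space
    sigma; per-state counts are gamma with the given mean (counts per
    minute) and shape. The defaults describe an office-worker day: roughly
    16 h awake of which ~45% is inactive sitting, ~2 h active sitting,
    ~1.5 h inactive standing, and enough stepping for several thousand
    steps per day.
    """

    # mean dwell minutes and log-sigma per waking state
    dwell_mean_min: dict = field(
        default_factory=lambda: {
            State.SIT_INACTIVE: 20.0,
            State.SIT_ACTIVE: 13.0,
            State.STAND_INACTIVE: 6.0,
            State.STAND_ACTIVE: 17.0,
            State.STEP: 5.0,
        }
    )
    dwell_sigma: float = 0.6
    # waking-state transition matrix, row order = WAKE_STATES
    transition: tuple = (
        (0.00, 0.30, 0.25, 0.25, 0.20),
        (0.55, 0.00, 0.15, 0.15, 0.15),
        (0.35, 0.10, 0.00, 0.35, 0.20),
        (0.30, 0.10, 0.25, 0.00, 0.35),
        (0.40, 0.05, 0.25, 0.30, 0.00),
    )
    # per-state counts-per-minute distribution (mean, gamma shape), axis 1
    cpm: dict = field(
        default_factory=lambda: {
            State.BED: (2.0, 1.0),
            State.SIT_INACTIVE: (20.0, 1.5),
            State.SIT_ACTIVE: (250.0, 4.0),
            State.STAND_INACTIVE: (50.0, 2.0),
            State.STAND_ACTIVE: (300.0, 4.0),
            State.STEP: (2500.0, 8.0),
        }
    )
    # raw-signal movement amplitude per state, in g
    movement_amp: dict = field(
        default_factory=lambda: {
            State.BED: 0.004,
            State.SIT_INACTIVE: 0.008,
            State.SIT_ACTIVE: 0.050,
            State.STAND_INACTIVE: 0.012,
            State.STAND_ACTIVE: 0.060,
            State.STEP: 0.250,
        }
    )
    steps_per_minute: float = 110.0
    wake_start_h: float = 6.75  # 06:45
    wake_end_h: float = 22.75  # 22:45
    sampling_rate: float = 10.0
    sensor_noise_g: float = 0.003
    step_cadence_hz: float = 1.9
    lag_s: float = 3.0  # waist sensor delayed relative to thigh sensor
    burst_fraction: float = 0.0  # fraction of a minute's counts in one burst
    recording_epoch: datetime = datetime(2021, 3, 1, 0, 0, 0)

    def __post_init__(self) -> None:
        mat = np.asarray(self.transition, dtype=float)
        if mat.shape != (len(WAKE_STATES),) * 2:
            raise ConfigurationError("transition matrix must be 5x5")
        if np.any(mat < 0) or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("transition matrix rows must sum to 1")
        for s, m in self.dwell_mean_min.items():
            if m <= 0:
                raise ConfigurationError(f"dwell mean for {s} must be > 0")
        if not 0 <= self.burst_fraction <= 1:
            raise ConfigurationError("burst_fraction must be in [0, 1]")
        if not 0 <= self.wake_start_h < self.wake_end_h <= 24:
            raise ConfigurationError("invalid wake span")

    # -- analytic expectations -------------------------------------------

    def stationary_wake_distribution(self) -> np.ndarray:
        """Stationary distribution of the embedded waking-state chain."""
        mat = np.asarray(self.transition, dtype=float)
        vals, vecs = np.linalg.eig(mat.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi) / np.abs(pi).sum()
        return pi

    def expected_state_fractions(self) -> dict:
        """Expected long-run fraction of waking time spent in each state.

        Semi-Markov occupancy: stationary visit probability weighted by
        the mean dwell time.
        """
        pi = self.stationary_wake_distribution()
        w = np.array([pi[i] * self.dwell_mean_min[s] for i, s in enumerate(WAKE_STATES)])
        w = w / w.sum()
        return {s: float(w[i]) for i, s in enumerate(WAKE_STATES)}


@dataclass
class GroundTruth:
    """Exact generator-side record of what was simulated."""

    states: list  # list of (start_s, end_s, State), contiguous
    lag_s: float
    nonwear: dict = field(default_factory=lambda: {Placement.THIGH: [], Placement.WAIST: []})
    wake_spans: list = field(default_factory=list)  # per day (t0, t1)

    def occupancy_in_span(self, t0: float, t1: float, states: Sequence[State]) -> float:
        """Seconds of [t0, t1) spent in any of ``states``."""
        total = 0.0
        for s, e, st in self.states:
            if st in states and e > t0 and s < t1:
                total += min(e, t1) - max(s, t0)
        return total

    def day_span(self, day: int) -> tuple[float, float]:
        return day * SECONDS_PER_DAY, (day + 1) * SECONDS_PER_DAY

    def daily_sedentary_minutes(self, day: int) -> float:
        t0, t1 = self.day_span(day)
        return self.occupancy_in_span(t0, t1, [State.SIT_INACTIVE]) / 60.0

    def daily_active_sitting_minutes(self, day: int) -> float:
        t0, t1 = self.day_span(day)
        return self.occupancy_in_span(t0, t1, [State.SIT_ACTIVE]) / 60.0

    def daily_sit_minutes(self, day: int) -> float:
        """Waking sitting time (both intensities) per day, minutes."""
        t0, t1 = self.day_span(day)
        return self.occupancy_in_span(t0, t1, SIT_STATES) / 60.0

    def sedentary_bout_minutes(self, day: int, min_minutes: float) -> float:
        """Sedentary minutes accumulated in inactive-sitting runs
        lasting at least ``min_minutes`` within the given day."""
        t0, t1 = self.day_span(day)
        total = 0.0
        for s, e, st in self.states:
            if st is State.SIT_INACTIVE and e > t0 and s < t1:
                dur = min(e, t1) - max(s, t0)
                if dur >= min_minutes * 60.0:
                    total += dur
        return total / 60.0

    def minute_true_class(self, n_minutes: int) -> list[str]:
        """Per clock minute, the majority-occupancy class:
        'sedentary', 'active_sitting', 'other' or 'bed'."""
        labels = []
        for m in range(n_minutes):
            t0, t1 = m * 60.0, (m + 1) * 60.0
            occ = {
                "sedentary": self.occupancy_in_span(t0, t1, [State.SIT_INACTIVE]),
                "active_sitting": self.occupancy_in_span(t0, t1, [State.SIT_ACTIVE]),
                "bed": self.occupancy_in_span(t0, t1, [State.BED]),
                "other": self.occupancy_in_span(
                    t0, t1, [State.STAND_INACTIVE, State.STAND_ACTIVE, State.STEP]
                ),
            }
            labels.append(max(occ, key=occ.get))
        return labels


@dataclass
class SimulatedParticipant:
    participant: str
    timeline: EventTimeline
    counts: CountsSeries
    raw_thigh: RawRecording
    raw_waist: RawRecording
    truth: GroundTruth


# ---------------------------------------------------------------------------
# state timeline
# ---------------------------------------------------------------------------


def _simulate_states(profile: BehaviourProfile, n_days: int, rng: np.random.Generator):
    """Contiguous (start, end, State) segments covering n_days."""
    mat = np.asarray(profile.transition, dtype=float)
    pi = profile.stationary_wake_distribution()
    segments: list[tuple[float, float, State]] = []
    wake_spans = []
    t_end = n_days * SECONDS_PER_DAY
    t = 0.0
    for day in range(n_days):
        day0 = day * SECONDS_PER_DAY
        wake0 = day0 + profile.wake_start_h * 3600.0
        wake1 = day0 + profile.wake_end_h * 3600.0
        if t < wake0:
            segments.append((t, wake0, State.BED))
            t = wake0
        wake_spans.append((wake0, wake1))
        state_idx = int(rng.choice(len(WAKE_STATES), p=pi))
        while t < wake1:
            state = WAKE_STATES[state_idx]
            mean_s = profile.dwell_mean_min[state] * 60.0
            sigma = profile.dwell_sigma
            mu = np.log(mean_s) - sigma**2 / 2.0
            dwell = float(rng.lognormal(mu, sigma))
            end = min(t + dwell, wake1)
            segments.append((t, end, state))
            t = end
            state_idx = int(rng.choice(len(WAKE_STATES), p=mat[state_idx]))
    if t < t_end:
        segments.append((t, t_end, State.BED))
    return segments, wake_spans


def _events_from_states(profile, segments, rng) -> EventTimeline:
    """Collapse states to postures and merge abutting same-posture runs."""
    events: list[PostureEvent] = []
    for s, e, st in segments:
        posture = STATE_TO_POSTURE[st]
        if events and events[-1].posture is posture:
            prev = events[-1]
            steps = prev.steps
            if posture is Posture.STEP:
                steps += int(round(profile.steps_per_minute * (e - s) / 60.0))
            events[-1] = PostureEvent(prev.start, e - prev.start, posture, steps)
        else:
            steps = (
                int(round(profile.steps_per_minute * (e - s) / 60.0))
                if posture is Posture.STEP
                else 0
            )
            events.append(PostureEvent(s, e - s, posture, steps))
    return EventTimeline(tuple(events), profile.recording_epoch)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _minute_occupancy(segments, n_minutes: int) -> list[list[tuple[int, float]]]:
    """For each clock minute, list of (wake-state-or-bed index, fraction)."""
    per_min: list[list[tuple[State, float]]] = [[] for _ in range(n_minutes)]
    for s, e, st in segments:
        m0 = int(s // 60)
        m1 = int(np.ceil(e / 60.0))
        for m in range(m0, min(m1, n_minutes)):
            cover = min(e, (m + 1) * 60.0) - max(s, m * 60.0)
            if cover > 0:
                per_min[m].append((st, cover / 60.0))
    return per_min


def _simulate_counts(profile: BehaviourProfile, segments, n_days: int, rng):
    n_minutes = int(n_days * SECONDS_PER_DAY // 60)
    occ = _minute_occupancy(segments, n_minutes)
    n_seconds = n_minutes * 60
    axis1 = np.zeros(n_seconds, dtype=np.int64)
    for m, parts in enumerate(occ):
        cpm_val = 0.0
        for st, frac in parts:
            mean, shape = profile.cpm[st]
            cpm_val += frac * rng.gamma(shape, mean / shape)
        c = int(round(cpm_val))
        if c <= 0:
            continue
        sec = np.full(60, c // 60, dtype=np.int64)
        rem = c - 60 * (c // 60)
        if rem:
            sec[rng.choice(60, size=rem, replace=False)] += 1
        if profile.burst_fraction > 0:
            burst = int(round(profile.burst_fraction * c))
            if burst > 0:
                # move `burst` counts into one contiguous 15-s block
                take = np.minimum(sec, (sec * burst / max(c, 1)).astype(np.int64))
                sec = sec - take
                start = int(rng.integers(0, 46))
                sec[start : start + 15] += int(take.sum()) // 15
                sec[start] += int(take.sum()) % 15
        axis1[m * 60 : (m + 1) * 60] = sec
    axis2 = rng.binomial(axis1, 0.7)
    axis3 = rng.binomial(axis1, 0.5)
    return CountsSeries(
        axis1=axis1,
        axis2=axis2,
        axis3=axis3,
        recording_epoch=profile.recording_epoch,
        epoch_length=1.0,
    )


# ---------------------------------------------------------------------------
# raw signals
# ---------------------------------------------------------------------------

_THIGH_GRAVITY = {
    # channel order: (longitudinal, medio-lateral, anterior-posterior), in g
    "upright": np.array([0.98, 0.05, 0.10]),
    "sitting": np.array([0.15, 0.05, 0.96]),
    "lying": np.array([0.05, 0.95, 0.25]),
}
_WAIST_GRAVITY = {
    "upright": np.array([0.99, 0.03, 0.08]),
    "sitting": np.array([0.92, 0.05, 0.35]),
    "lying": np.array([0.10, 0.95, 0.15]),
}


def _orientation(state: State, placement: Placement) -> np.ndarray:
    table = _THIGH_GRAVITY if placement is Placement.THIGH else _WAIST_GRAVITY
    if state is State.BED:
        return table["lying"]
    if state in SIT_STATES:
        # thigh goes horizontal; the waist sensor tilts mildly on its belt
        return table["sitting"]
    return table["upright"]


def _simulate_raw(profile, segments, n_days, placement: Placement, rng):
    fs = profile.sampling_rate
    n = int(round(n_days * SECONDS_PER_DAY * fs))
    acc = np.empty((n, 3), dtype=np.float32)
    t_axis = None
    for s, e, st in segments:
        i0, i1 = int(round(s * fs)), min(int(round(e * fs)), n)
        if i1 <= i0:
            continue
        seg = np.tile(_orientation(st, placement), (i1 - i0, 1))
        amp = profile.movement_amp[st] * float(rng.lognormal(0.0, 0.2))
        seg += amp * rng.standard_normal((i1 - i0, 3))
        if st is State.STEP:
            # gait periodicity strongest on the longitudinal/vertical axis
            tt = np.arange(i1 - i0) / fs
            gait = 0.35 * np.sin(2 * np.pi * profile.step_cadence_hz * tt)
            seg[:, 0] += gait
            seg[:, 2] += 0.15 * np.sin(4 * np.pi * profile.step_cadence_hz * tt)
        acc[i0:i1] = seg
    acc += profile.sensor_noise_g * rng.standard_normal((n, 3)).astype(np.float32)
    return RawRecording(
        acceleration=acc,
        sampling_rate=fs,
        placement=placement,
        recording_epoch=profile.recording_epoch,
    )


# ---------------------------------------------------------------------------
# lag and non-wear injection
# ---------------------------------------------------------------------------


def inject_lag(raw: RawRecording, lag_s: float) -> RawRecording:
    """Delay a raw stream by ``lag_s`` seconds (negative = advance).

    The shifted signal is padded with its edge value; ``meta['true_lag_s']``
    records the injected lag.
    """
    if abs(lag_s) >= 600:
        raise ValueError("lag must be below 600 s")
    shift = int(round(lag_s * raw.sampling_rate))
    acc = raw.acceleration
    if shift > 0:
        shifted = np.concatenate([np.tile(acc[:1], (shift, 1)), acc[:-shift]])
    elif shift < 0:
        shifted = np.concatenate([acc[-shift:], np.tile(acc[-1:], (-shift, 1))])
    else:
        shifted = acc.copy()
    meta = dict(raw.meta)
    meta["true_lag_s"] = meta.get("true_lag_s", 0.0) + lag_s
    return replace(raw, acceleration=shifted, meta=meta)


def shift_counts(series: CountsSeries, lag_s: float) -> CountsSeries:
    """Shift a counts series in time by ``lag_s`` seconds (epoch-rounded)."""
    shift = int(round(lag_s / series.epoch_length))
    out = {}
    for name in ("axis1", "axis2", "axis3"):
        arr = getattr(series, name)
        if shift > 0:
            out[name] = np.concatenate([np.zeros(shift, dtype=arr.dtype), arr[:-shift]])
        elif shift < 0:
            out[name] = np.concatenate([arr[-shift:], np.zeros(-shift, dtype=arr.dtype)])
        else:
            out[name] = arr.copy()
    return replace(series, **out)


def inject_nonwear(
    sim: SimulatedParticipant, intervals: Sequence[tuple[float, float]]
) -> SimulatedParticipant:
    """Make the waist sensor appear unworn over the given intervals.

    Raw waist channels are held constant at their value just before each
    interval and the counts are zeroed; the ground truth is updated.
    Overlapping intervals are rejected.
    """
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise ValueError("overlapping non-wear intervals")
    if not ivs:
        return sim
    acc = sim.raw_waist.acceleration.copy()
    fs = sim.raw_waist.sampling_rate
    a1 = sim.counts.axis1.copy()
    a2 = sim.counts.axis2.copy()
    a3 = sim.counts.axis3.copy()
    ep = sim.counts.epoch_length
    for t0, t1 in ivs:
        i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), len(acc))
        hold = acc[max(i0 - 1, 0)]
        acc[i0:i1] = hold
        e0, e1 = int(round(t0 / ep)), min(int(round(t1 / ep)), len(a1))
        a1[e0:e1] = 0
        a2[e0:e1] = 0
        a3[e0:e1] = 0
    truth = GroundTruth(
        states=list(sim.truth.states),
        lag_s=sim.truth.lag_s,
        nonwear={
            Placement.THIGH: list(sim.truth.nonwear[Placement.THIGH]),
            Placement.WAIST: sorted(list(sim.truth.nonwear[Placement.WAIST]) + ivs),
        },
        wake_spans=list(sim.truth.wake_spans),
    )
    return SimulatedParticipant(
        participant=sim.participant,
        timeline=sim.timeline,
        counts=replace(sim.counts, axis1=a1, axis2=a2, axis3=a3),
        raw_thigh=sim.raw_thigh,
        raw_waist=replace(sim.raw_waist, acceleration=acc),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


def simulate_participant(
    profile: BehaviourProfile,
    n_days: int = 7,
    seed: int | np.random.SeedSequence = 0,
    participant: str = "P01",
    with_raw: bool = True,
) -> SimulatedParticipant:
    """Simulate one participant's multi-day dual-sensor recording.

    Fully deterministic given ``(profile, n_days, seed)``. With
    ``with_raw=False`` the raw streams are skipped (empty recordings) for
    workflows that only need events and counts.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    segments, wake_spans = _simulate_states(profile, n_days, rng)
    timeline = _events_from_states(profile, segments, rng)
    counts = _simulate_counts(profile, segments, n_days, rng)
    if with_raw:
        raw_thigh = _simulate_raw(profile, segments, n_days, Placement.THIGH, rng)
        raw_waist = _simulate_raw(profile, segments, n_days, Placement.WAIST, rng)
    else:
        empty = np.zeros((1, 3), dtype=np.float32)
        raw_thigh = RawRecording(empty, profile.sampling_rate, Placement.THIGH, profile.recording_epoch)
        raw_waist = RawRecording(empty, profile.sampling_rate, Placement.WAIST, profile.recording_epoch)
    if profile.lag_s and with_raw:
        raw_waist = inject_lag(raw_waist, profile.lag_s)
    if profile.lag_s:
        counts = shift_counts(counts, profile.lag_s)
    truth = GroundTruth(states=segments, lag_s=profile.lag_s, wake_spans=wake_spans)
    return SimulatedParticipant(
        participant=participant,
        timeline=timeline,
        counts=counts,
        raw_thigh=raw_thigh,
        raw_waist=raw_waist,
        truth=truth,
    )


def iter_cohort(
    profile: BehaviourProfile,
    n_participants: int,
    n_days: int = 7,
    seed: int = 0,
    prefix: str = "P",
    with_raw: bool = True,
):
    """Lazily yield cohort participants one at a time.

    Same seed stream as :func:`simulate_cohort`, but recordings can be
    processed and discarded without holding the whole cohort's raw
    signals in memory.
    """
    children = np.random.SeedSequence(seed).spawn(n_participants)
    for i, child in enumerate(children):
        yield simulate_participant(
            profile,
            n_days=n_days,
            seed=child,
            participant=f"{prefix}{i + 1:03d}",
            with_raw=with_raw,
        )


def simulate_cohort(
    profile: BehaviourProfile,
    n_participants: int,
    n_days: int = 7,
    seed: int = 0,
    prefix: str = "P",
    with_raw: bool = True,
) -> list[SimulatedParticipant]:
    """Simulate an independent cohort; per-participant seeds are spawned
    from the cohort seed so any participant is reproducible in isolation."""
    children = np.random.SeedSequence(seed).spawn(n_participants)
    return [
        simulate_participant(
            profile,
            n_days=n_days,
            seed=child,
            participant=f"{prefix}{i + 1:03d}",
            with_raw=with_raw,
        )
        for i, child in enumerate(children)
    ]
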