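"""Pre-processing: valid days, bedtime, synchronization, non-wear.

The pipeline prepares a dual-sensor recording for classification in three
steps:

1. posture-sensor wear-time detection — per-day validity rules (step
   minimum, waking-hours minimum, single-posture cap) and bedtime
   exclusion (heuristic with diary override and review flags);
2. sensor synchronization — the waist sensor's delay relative to the
   thigh sensor is estimated from the raw signals by cross-correlating
   1-s movement envelopes, then removed;
3. waist-sensor non-wear detection — maximal constant-signal runs are
   non-wear when long enough (default >= 90 min) or when the posture
   sensor shows a posture change or locomotion inside them.

What remains — time both sensors were worn, excluding bedtime — is the
wear-time on which every measurement method operates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np

from . import intervals as iv
from .errors import EstimationError
from .sensor_io import CountsSeries, EventTimeline, Posture, RawRecording
from .synthetic import shift_counts
from .intervals import Interval

__all__ = [
    "ValidDayRules",
    "WearMask",
    "BedtimeRecord",
    "BedtimeResult",
    "LagEstimate",
    "detect_valid_days",
    "exclude_bedtime",
    "estimate_lag",
    "synchronize",
    "detect_actigraph_nonwear",
    "build_wear_mask",
    "day_bounds",
]


# ---------------------------------------------------------------------------
# calendar helpers
# ---------------------------------------------------------------------------


def _midnight_offset(epoch: datetime) -> float:
    """Seconds from the midnight preceding the epoch to the epoch."""
    return epoch.hour * 3600 + epoch.minute * 60 + epoch.second + epoch.microsecond / 1e6


def day_bounds(epoch: datetime, day: int) -> Interval:
    """Half-open span of calendar day ``day`` (day 0 = the epoch's date),
    in seconds since recording start."""
    off = _midnight_offset(epoch)
    return day * 86400.0 - off, (day + 1) * 86400.0 - off


def n_calendar_days(epoch: datetime, duration: float) -> int:
    off = _midnight_offset(epoch)
    return int(np.ceil((duration + off) / 86400.0))


# ---------------------------------------------------------------------------
# valid days
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidDayRules:
    """Per-day validity rules for the posture sensor.

    A day counts only with at least ``min_steps`` steps, at least
    ``min_waking_hours`` of waking (non-bedtime) wear, and no single
    posture occupying more than ``max_single_posture_fraction`` of the
    waking wear.
    """

    min_steps: int = 500
    min_waking_hours: float = 12.0
    max_single_posture_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.max_single_posture_fraction <= 1:
            raise ValueError("max_single_posture_fraction must be in (0, 1]")


def detect_valid_days(
    timeline: EventTimeline,
    bedtime: Sequence[Interval],
    rules: ValidDayRules = ValidDayRules(),
) -> set[int]:
    """Return the set of valid calendar-day indices."""
    epoch = timeline.recording_epoch
    recorded = [(timeline.start, timeline.end)]
    valid: set[int] = set()
    for day in range(n_calendar_days(epoch, timeline.end)):
        d0, d1 = day_bounds(epoch, day)
        waking = iv.subtract(iv.clip(recorded, d0, d1), bedtime)
        waking_s = iv.total_duration(waking)
        if waking_s < rules.min_waking_hours * 3600.0:
            continue
        steps = 0.0
        occ = {p: 0.0 for p in Posture}
        for ev in timeline.events_in_span(d0, d1):
            overlap = iv.intersect([(ev.start, ev.end)], waking)
            dur = iv.total_duration(overlap)
            occ[ev.posture] += dur
            steps += ev.steps * dur / ev.duration
        if steps < rules.min_steps:
            continue
        if max(occ.values()) > rules.max_single_posture_fraction * waking_s:
            continue
        valid.add(day)
    return valid


# ---------------------------------------------------------------------------
# bedtime
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BedtimeRecord:
    night: int  # index of the calendar day on which the night begins
    interval: Interval | None
    source: str  # 'heuristic' | 'diary' | 'unresolved'
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class BedtimeResult:
    records: tuple[BedtimeRecord, ...]

    @property
    def intervals(self) -> list[Interval]:
        return iv.normalize([r.interval for r in self.records if r.interval])

    @property
    def flagged(self) -> list[BedtimeRecord]:
        return [r for r in self.records if r.flags]


def exclude_bedtime(
    timeline: EventTimeline,
    diary: dict[int, Interval] | None = None,
    night_window: tuple[float, float] = (22.0, 8.0),
    min_hours: float = 3.0,
    late_start_h: float = 1.0,
    early_end_h: float = 4.5,
) -> BedtimeResult:
    """Mark bedtime for each night of the recording.

    Heuristic: per night, the longest block of contiguous non-stepping
    events overlapping the night window (default 22:00 to 08:00 of the
    next day), clipped to the window, of at least ``min_hours``. A diary
    entry (night index -> interval in recording seconds) overrides the
    heuristic. Nights whose detected bed start falls after ``late_start_h``
    or whose end falls before ``early_end_h`` (clock hours) are flagged
    for manual review — flags are surfaced, never auto-resolved.
    """
    diary = diary or {}
    epoch = timeline.recording_epoch
    # maximal non-STEP blocks
    blocks: list[Interval] = []
    for ev in timeline.events:
        if ev.posture is Posture.STEP:
            continue
        if blocks and abs(ev.start - blocks[-1][1]) <= 1e-6:
            blocks[-1] = (blocks[-1][0], ev.end)
        else:
            blocks.append((ev.start, ev.end))

    records: list[BedtimeRecord] = []
    total_days = n_calendar_days(epoch, timeline.end)
    for night in range(-1, total_days):
        d0, _ = day_bounds(epoch, night)
        w0 = d0 + night_window[0] * 3600.0
        w1 = d0 + (24.0 + night_window[1]) * 3600.0
        if w1 <= timeline.start or w0 >= timeline.end:
            continue
        if night in diary:
            records.append(BedtimeRecord(night, diary[night], "diary"))
            continue
        best: Interval | None = None
        for b0, b1 in blocks:
            c0, c1 = max(b0, w0), min(b1, w1)
            if c1 - c0 >= min_hours * 3600.0:
                if best is None or (c1 - c0) > (best[1] - best[0]):
                    best = (c0, c1)
        if best is None:
            records.append(BedtimeRecord(night, None, "unresolved", ("no_candidate",)))
            continue
        flags = []
        start_clock = (best[0] - d0) / 3600.0  # hours since 00:00 of `night` day
        end_clock = (best[1] - d0) / 3600.0 - 24.0
        if start_clock > 24.0 + late_start_h:
            flags.append("late_start")
        if end_clock < early_end_h and best[1] < timeline.end - 1e-6:
            flags.append("early_end")
        records.append(BedtimeRecord(night, best, "heuristic", tuple(flags)))
    return BedtimeResult(tuple(records))


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LagEstimate:
    lag_s: float  # positive: waist stream delayed relative to thigh stream
    peak_correlation: float
    low_confidence: bool


def _movement_envelope(raw: RawRecording) -> np.ndarray:
    """Per-second standard deviation of the vector magnitude (movement
    intensity envelope, insensitive to gravity orientation)."""
    fs = int(round(raw.sampling_rate))
    vm = raw.vector_magnitude()
    n_sec = len(vm) // fs
    blocks = vm[: n_sec * fs].reshape(n_sec, fs)
    return blocks.std(axis=1)


def estimate_lag(
    raw_thigh: RawRecording,
    raw_waist: RawRecording,
    max_lag_s: float = 60.0,
    min_overlap_s: float = 1800.0,
    confidence_floor: float = 0.2,
) -> LagEstimate:
    """Estimate the waist sensor's delay by cross-correlating envelopes.

    Returns the integer-second lag maximizing the normalized
    cross-correlation of the two 1-s movement envelopes over
    ``±max_lag_s``. A peak correlation below ``confidence_floor`` sets the
    low-confidence flag (and emits a warning).
    """
    env_t = _movement_envelope(raw_thigh)
    env_w = _movement_envelope(raw_waist)
    n = min(len(env_t), len(env_w))
    if n < min_overlap_s:
        raise EstimationError(
            f"only {n} s of overlapping signal; need >= {min_overlap_s:.0f} s"
        )
    env_t, env_w = env_t[:n], env_w[:n]
    max_lag = int(round(max_lag_s))
    best_lag, best_corr = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = env_t[: n - lag], env_w[lag:]
        else:
            a, b = env_t[-lag:], env_w[: n + lag]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        c = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if c > best_corr:
            best_lag, best_corr = lag, c
    low = best_corr < confidence_floor
    if low:
        warnings.warn(
            f"lag estimate low confidence (peak correlation {best_corr:.2f})",
            stacklevel=2,
        )
    return LagEstimate(float(best_lag), best_corr, low)


def synchronize(
    counts: CountsSeries, raw_waist: RawRecording, lag_s: float
) -> tuple[CountsSeries, RawRecording]:
    """Remove an estimated waist delay by shifting the waist streams back.

    One global lag per recording; the device delay is treated as a clock
    offset, not drift.
    """
    from .synthetic import inject_lag  # shares the shifting primitive

    return shift_counts(counts, -lag_s), inject_lag(raw_waist, -lag_s)


# ---------------------------------------------------------------------------
# non-wear
# ---------------------------------------------------------------------------


def _constant_runs_raw(raw: RawRecording, tol_g: float) -> list[Interval]:
    """Maximal runs (1-s resolution) where each axis' per-second std is
    below ``tol_g`` — i.e. the signal is constant up to tolerance."""
    fs = int(round(raw.sampling_rate))
    n_sec = len(raw) // fs
    flat = np.ones(n_sec, dtype=bool)
    for ax in range(3):
        blocks = raw.acceleration[: n_sec * fs, ax].reshape(n_sec, fs)
        flat &= blocks.std(axis=1) < tol_g
    return _runs_to_intervals(flat, 1.0)


def _constant_runs_counts(counts: CountsSeries) -> list[Interval]:
    """Zero-variance (all-zero) runs in counts mode."""
    flat = (counts.axis1 == 0) & (counts.axis2 == 0) & (counts.axis3 == 0)
    return _runs_to_intervals(flat, counts.epoch_length)


def _runs_to_intervals(mask: np.ndarray, step: float) -> list[Interval]:
    out: list[Interval] = []
    diff = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append((s * step, e * step))
    return out


def _timeline_movement_within(timeline: EventTimeline, t0: float, t1: float) -> bool:
    """True if the posture sensor recorded a posture change or any
    stepping strictly within [t0, t1)."""
    evs = timeline.events_in_span(t0, t1)
    if any(ev.posture is Posture.STEP for ev in evs):
        return True
    for a, b in zip(evs, evs[1:]):
        if a.posture is not b.posture and t0 < a.end < t1:
            return True
    return False


def detect_actigraph_nonwear(
    timeline: EventTimeline,
    raw_waist: RawRecording | None = None,
    counts: CountsSeries | None = None,
    min_const_minutes: float = 90.0,
    const_tol_g: float = 1e-3,
    min_candidate_s: float = 60.0,
    movement_qualifies: bool = True,
) -> list[Interval]:
    """Detect waist-sensor non-wear.

    Candidates are maximal constant-signal runs (per-axis std below
    ``const_tol_g`` over 1-s blocks in raw mode; all-zero runs in counts
    mode) of at least ``min_candidate_s``. A candidate is non-wear when
    it lasts at least ``min_const_minutes`` **or** — with
    ``movement_qualifies`` (default) — when the posture sensor recorded a
    posture change or locomotion inside it: a constant waist signal during
    thigh-detected movement can only mean the waist sensor is off. Set
    ``movement_qualifies=False`` for the strict duration-only reading.
    """
    if raw_waist is not None:
        candidates = _constant_runs_raw(raw_waist, const_tol_g)
    elif counts is not None:
        candidates = _constant_runs_counts(counts)
    else:
        raise ValueError("need raw_waist or counts")
    out: list[Interval] = []
    for t0, t1 in candidates:
        if t1 - t0 < min_candidate_s:
            continue
        if t1 - t0 >= min_const_minutes * 60.0:
            out.append((t0, t1))
        elif movement_qualifies and _timeline_movement_within(timeline, t0, t1):
            out.append((t0, t1))
    return iv.normalize(out)


# ---------------------------------------------------------------------------
# wear mask
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WearMask:
    """Per-sensor worn intervals; the joint wear-time is their
    intersection minus bedtime."""

    thigh: tuple[Interval, ...]
    waist: tuple[Interval, ...]
    bedtime: tuple[Interval, ...] = ()

    def joint_wear(self) -> list[Interval]:
        return iv.subtract(iv.intersect(self.thigh, self.waist), self.bedtime)

    def wear_seconds_in(self, t0: float, t1: float) -> float:
        return iv.total_duration(iv.clip(self.joint_wear(), t0, t1))


def build_wear_mask(
    timeline: EventTimeline,
    bedtime: Sequence[Interval],
    waist_nonwear: Sequence[Interval],
) -> WearMask:
    """Assemble the joint wear mask: the thigh sensor (adhesive-attached)
    is worn over the whole event timeline; the waist sensor over the same
    span minus detected non-wear."""
    extent = [(timeline.start, timeline.end)]
    return WearMask(
        thigh=tuple(extent),
        waist=tuple(iv.subtract(extent, waist_nonwear)),
        bedtime=tuple(iv.normalize(bedtime)),
    )
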