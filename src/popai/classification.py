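"""The five sedentary-behaviour measurement methods.

* **POPAI** (dual-sensor reference): each sitting event from the thigh
  sensor is split minute-by-minute into sedentary (inactive sitting) and
  active sitting using the waist counts against a 75 cpm cut-point;
  sub-minute events and the trailing fraction of longer events are judged
  against the corresponding fraction of the cut-point (25 counts for a
  20-s sitting event).
* **activPAL**: every sitting event is sedentary, as a typical field
  study scores the posture sensor alone.
* **activPAL+**: like POPAI, but each minute window is labelled by the
  trained energy-expenditure classifier on the thigh raw signal.
* **ActiGraph**: every clock minute under 100 counts on the vertical axis
  is sedentary, as a typical field study scores the movement sensor alone.
* **ActiGraph+**: a posture model labels each minute sit/stand/step; sit
  minutes are then split sedentary vs active sitting at 75 cpm.

Plus zero-tolerance bout detection (maximal contiguous sedentary runs at
>= 10 / >= 30 min) and per-day summaries averaged over days with at least
10 h of wear.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Protocol, Sequence

import numpy as np

from . import intervals as iv
from .errors import ConfigurationError, RegistryMismatchError
from .features import REGISTRY_VERSION, MinuteWindow
from .intervals import Interval
from .preprocessing import WearMask, day_bounds, n_calendar_days
from .sensor_io import CountsSeries, EventTimeline, Posture, PostureEvent, RawRecording, counts_in_span

__all__ = [
    "Label",
    "ClassifiedTimeline",
    "DailySummary",
    "WindowSpan",
    "minute_posture_labels",
    "partition_event_inference",
    "classify_popai",
    "classify_activpal",
    "classify_activpal_plus",
    "classify_actigraph",
    "classify_actigraph_plus",
    "detect_bouts",
    "summarize_days",
    "participant_mean",
]


class Label(enum.Enum):
    SEDENTARY = "sedentary"
    ACTIVE_SITTING = "active_sitting"
    STANDING_OTHER = "standing_other"
    LOCOMOTION = "locomotion"
    NONWEAR = "nonwear"
    BED = "bed"


LabelledInterval = tuple[float, float, Label]


@dataclass(frozen=True)
class ClassifiedTimeline:
    """Ordered half-open labelled intervals produced by one method."""

    intervals: tuple[LabelledInterval, ...]
    method: str
    recording_epoch: datetime

    def __post_init__(self) -> None:
        # tolerance matches event-file timestamp precision (microseconds)
        ivs = tuple(sorted(self.intervals))
        for (a0, b0, _), (a1, _, _) in zip(ivs, ivs[1:]):
            if a1 < b0 - 1e-5:
                raise ConfigurationError("classified intervals overlap")
        object.__setattr__(self, "intervals", ivs)

    def duration(self, label: Label, t0: float = -np.inf, t1: float = np.inf) -> float:
        """Seconds carrying ``label`` within [t0, t1)."""
        total = 0.0
        for a, b, lab in self.intervals:
            if lab is label and b > t0 and a < t1:
                total += min(b, t1) - max(a, t0)
        return total

    def minutes(self, label: Label, t0: float = -np.inf, t1: float = np.inf) -> float:
        return self.duration(label, t0, t1) / 60.0


def _merge_adjacent(spans: list[LabelledInterval]) -> list[LabelledInterval]:
    out: list[LabelledInterval] = []
    for a, b, lab in sorted(spans):
        if b <= a:
            continue
        if out and out[-1][2] is lab and abs(a - out[-1][1]) <= 1e-6:
            out[-1] = (out[-1][0], b, lab)
        else:
            out.append((a, b, lab))
    return out


def _apply_overlays(
    spans: list[LabelledInterval],
    bedtime: Sequence[Interval] | None,
    nonwear: Sequence[Interval] | None,
) -> list[LabelledInterval]:
    """Relabel bedtime and non-wear portions, splitting spans as needed."""
    overlays: list[tuple[Interval, Label]] = []
    for ivs, lab in ((bedtime, Label.BED), (nonwear, Label.NONWEAR)):
        if ivs:
            overlays.extend(((a, b), lab) for a, b in iv.normalize(ivs))
    for (o0, o1), lab in overlays:
        new: list[LabelledInterval] = []
        for a, b, old in spans:
            if b <= o0 or a >= o1 or old in (Label.BED, Label.NONWEAR):
                new.append((a, b, old))
                continue
            if a < o0:
                new.append((a, o0, old))
            new.append((max(a, o0), min(b, o1), lab))
            if b > o1:
                new.append((o1, b, old))
        spans = new
    return _merge_adjacent(spans)


def minute_posture_labels(
    timeline: EventTimeline, minute_starts: Sequence[float]
) -> list[str]:
    """Majority posture ('sit' / 'stand' / 'step') of each 60-s window,
    read off the thigh event timeline.

    This is how dual-sensor ground truth for a waist posture classifier
    is obtained: the posture sensor labels the movement sensor's minutes.
    """
    out = []
    for t0 in minute_starts:
        occ = {Posture.SIT: 0.0, Posture.STAND: 0.0, Posture.STEP: 0.0}
        for ev in timeline.events_in_span(t0, t0 + 60.0):
            occ[ev.posture] += min(ev.end, t0 + 60.0) - max(ev.start, t0)
        out.append(max(occ, key=occ.get).value)
    return out


# ---------------------------------------------------------------------------
# event partitioning (inference scheme)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpan:
    """A 60-s model-input window and the sub-span it classifies."""

    win_start: float
    win_end: float
    cls_start: float
    cls_end: float


def partition_event_inference(event: PostureEvent) -> list[WindowSpan]:
    """Partition a sitting event into inference windows.

    For events of at least one minute: ``floor(d/60)`` start-aligned 60-s
    windows, each classifying its own span; if the duration is not a
    whole number of minutes, one additional end-aligned 60-s window that
    classifies only the trailing fraction (it overlaps the previous
    window but classifies nothing twice). Sub-minute events get a single
    60-s window centred on the event midpoint, classifying the whole
    event. The classified spans always partition the event exactly.
    """
    if event.posture is not Posture.SIT:
        raise ValueError("only sitting events are partitioned for inference")
    d = event.duration
    s = event.start
    if d < 60.0:
        mid = s + d / 2.0
        return [WindowSpan(mid - 30.0, mid + 30.0, s, s + d)]
    k = int(d // 60.0)
    out = [
        WindowSpan(s + 60.0 * i, s + 60.0 * (i + 1), s + 60.0 * i, s + 60.0 * (i + 1))
        for i in range(k)
    ]
    if d - 60.0 * k > 1e-9:
        out.append(WindowSpan(s + d - 60.0, s + d, s + 60.0 * k, s + d))
    return out


# ---------------------------------------------------------------------------
# POPAI and activPAL family
# ---------------------------------------------------------------------------


def _nonsit_label(posture: Posture) -> Label:
    return Label.LOCOMOTION if posture is Posture.STEP else Label.STANDING_OTHER


def classify_popai(
    timeline: EventTimeline,
    counts: CountsSeries,
    cutpoint: float = 75.0,
    axis: str = "axis1",
    bedtime: Sequence[Interval] | None = None,
    nonwear: Sequence[Interval] | None = None,
) -> ClassifiedTimeline:
    """Dual-sensor reference classification.

    Each sitting event is split by the inference partition; a span of
    length L seconds is sedentary iff its counts are below
    ``cutpoint * L / 60`` (the fraction of the cut-point). Spans beyond
    the counts recording are labelled non-wear.
    """
    spans: list[LabelledInterval] = []
    for ev in timeline.events:
        if ev.posture is not Posture.SIT:
            spans.append((ev.start, ev.end, _nonsit_label(ev.posture)))
            continue
        for ws in partition_event_inference(ev):
            if ws.cls_end > counts.duration + 1e-9:
                spans.append((ws.cls_start, ws.cls_end, Label.NONWEAR))
                continue
            span_len = ws.cls_end - ws.cls_start
            c = counts_in_span(counts, ws.cls_start, ws.cls_end, axis)
            lab = Label.SEDENTARY if c < cutpoint * span_len / 60.0 else Label.ACTIVE_SITTING
            spans.append((ws.cls_start, ws.cls_end, lab))
    spans = _apply_overlays(_merge_adjacent(spans), bedtime, nonwear)
    return ClassifiedTimeline(tuple(spans), "POPAI", timeline.recording_epoch)


def classify_activpal(
    timeline: EventTimeline,
    bedtime: Sequence[Interval] | None = None,
    nonwear: Sequence[Interval] | None = None,
) -> ClassifiedTimeline:
    """Proprietary posture-sensor scoring: all sitting is sedentary."""
    spans = [
        (ev.start, ev.end, Label.SEDENTARY if ev.posture is Posture.SIT else _nonsit_label(ev.posture))
        for ev in timeline.events
    ]
    spans = _apply_overlays(_merge_adjacent(spans), bedtime, nonwear)
    return ClassifiedTimeline(tuple(spans), "activPAL", timeline.recording_epoch)


class WindowModel(Protocol):
    def predict_window(self, window: MinuteWindow) -> int: ...


def _model_label(model, raw: RawRecording, ws: WindowSpan) -> int:
    """Ask the model for a window label; models may expose a span-aware
    hook ``predict_span(win_start, win_end, cls_start, cls_end, window)``
    (used e.g. by count-oracle models that reproduce the fractional
    cut-point rule exactly)."""
    window = MinuteWindow.from_raw(raw, ws.win_start)
    if hasattr(model, "predict_span"):
        return int(model.predict_span(ws.win_start, ws.win_end, ws.cls_start, ws.cls_end, window))
    return int(model.predict_window(window))


def classify_activpal_plus(
    timeline: EventTimeline,
    raw_thigh: RawRecording,
    model,
    bedtime: Sequence[Interval] | None = None,
    nonwear: Sequence[Interval] | None = None,
) -> ClassifiedTimeline:
    """Single-sensor posture method with the energy-expenditure model.

    The partition scheme is identical to POPAI's; each window is labelled
    by the model on the thigh raw signal, and sub-minute / remainder
    spans take their covering window's prediction.
    """
    version = getattr(model, "registry_version", REGISTRY_VERSION)
    if version != REGISTRY_VERSION:
        raise RegistryMismatchError(
            f"model trained on registry {version}, current is {REGISTRY_VERSION}"
        )
    spans: list[LabelledInterval] = []
    sit_spans: list[WindowSpan] = []
    for ev in timeline.events:
        if ev.posture is not Posture.SIT:
            spans.append((ev.start, ev.end, _nonsit_label(ev.posture)))
            continue
        sit_spans.extend(partition_event_inference(ev))
    if hasattr(model, "predict_windows") and not hasattr(model, "predict_span"):
        windows = [MinuteWindow.from_raw(raw_thigh, ws.win_start) for ws in sit_spans]
        preds = model.predict_windows(windows)
    else:
        preds = [_model_label(model, raw_thigh, ws) for ws in sit_spans]
    for ws, pred in zip(sit_spans, preds):
        lab = Label.ACTIVE_SITTING if pred else Label.SEDENTARY
        spans.append((ws.cls_start, ws.cls_end, lab))
    spans = _apply_overlays(_merge_adjacent(spans), bedtime, nonwear)
    return ClassifiedTimeline(tuple(spans), "activPAL+", timeline.recording_epoch)


# ---------------------------------------------------------------------------
# ActiGraph family
# ---------------------------------------------------------------------------


def _minute_grid(counts: CountsSeries, anchor: float = 0.0):
    n_min = int(np.ceil((counts.duration - anchor) / 60.0))
    for m in range(n_min):
        t0 = anchor + 60.0 * m
        t1 = min(anchor + 60.0 * (m + 1), counts.duration)
        yield t0, t1


def classify_actigraph(
    counts: CountsSeries,
    cutpoint: float = 100.0,
    axis: str = "axis1",
    anchor: float = 0.0,
    bedtime: Sequence[Interval] | None = None,
    nonwear: Sequence[Interval] | None = None,
) -> ClassifiedTimeline:
    """Proprietary movement-sensor scoring: minutes under the cut-point
    (default 100 counts on the vertical axis) are sedentary. Minutes are
    clock-aligned, anchored at the recording start; a trailing partial
    minute is judged against the pro-rated cut-point."""
    spans: list[LabelledInterval] = []
    for t0, t1 in _minute_grid(counts, anchor):
        c = counts_in_span(counts, t0, t1, axis)
        lab = Label.SEDENTARY if c < cutpoint * (t1 - t0) / 60.0 else Label.STANDING_OTHER
        spans.append((t0, t1, lab))
    spans = _apply_overlays(_merge_adjacent(spans), bedtime, nonwear)
    return ClassifiedTimeline(tuple(spans), "ActiGraph", counts.recording_epoch)


def classify_actigraph_plus(
    counts: CountsSeries,
    posture_model=None,
    raw_waist: RawRecording | None = None,
    posture_labels: Sequence[str] | None = None,
    cutpoint: float = 75.0,
    axis: str = "axis1",
    anchor: float = 0.0,
    bedtime: Sequence[Interval] | None = None,
    nonwear: Sequence[Interval] | None = None,
) -> ClassifiedTimeline:
    """Single-sensor movement method with a posture model.

    Each clock minute is classified sit/stand/step by the posture model
    (or by pre-computed ``posture_labels``); sitting minutes are then
    split at the 75 cpm cut-point into sedentary vs active sitting, and
    stand/step minutes pass through as standing-other/locomotion.
    """
    grid = list(_minute_grid(counts, anchor))
    if posture_labels is None:
        if posture_model is None or raw_waist is None:
            raise ConfigurationError(
                "classify_actigraph_plus needs a posture model + raw signal "
                "or precomputed posture labels"
            )
        posture_labels = posture_model.predict_minutes(raw_waist, [t0 for t0, _ in grid])
    if len(posture_labels) != len(grid):
        raise ConfigurationError("one posture label per minute required")
    spans: list[LabelledInterval] = []
    for (t0, t1), pos in zip(grid, posture_labels):
        if pos == "sit":
            c = counts_in_span(counts, t0, t1, axis)
            lab = Label.SEDENTARY if c < cutpoint * (t1 - t0) / 60.0 else Label.ACTIVE_SITTING
        elif pos == "step":
            lab = Label.LOCOMOTION
        else:
            lab = Label.STANDING_OTHER
        spans.append((t0, t1, lab))
    spans = _apply_overlays(_merge_adjacent(spans), bedtime, nonwear)
    return ClassifiedTimeline(tuple(spans), "ActiGraph+", counts.recording_epoch)


# ---------------------------------------------------------------------------
# bouts and daily summaries
# ---------------------------------------------------------------------------


def detect_bouts(
    classified: ClassifiedTimeline, min_minutes: float
) -> tuple[list[Interval], float]:
    """Zero-tolerance sedentary bouts.

    A bout is a maximal run of contiguous SEDENTARY intervals — any
    non-sedentary time, however short, breaks it. Returns the bouts of at
    least ``min_minutes`` and their accumulated duration in minutes.
    """
    runs: list[Interval] = []
    for a, b, lab in classified.intervals:
        if lab is not Label.SEDENTARY:
            continue
        if runs and abs(a - runs[-1][1]) <= 1e-9:
            runs[-1] = (runs[-1][0], b)
        else:
            runs.append((a, b))
    bouts = [(a, b) for a, b in runs if b - a >= min_minutes * 60.0 - 1e-9]
    return bouts, sum(b - a for a, b in bouts) / 60.0


@dataclass(frozen=True)
class DailySummary:
    """Per participant-day wear and sedentary totals (minutes)."""

    participant: str
    date: str  # ISO date of the calendar day
    wear_minutes: float
    sedentary_minutes: float
    sedentary_bout10_minutes: float
    sedentary_bout30_minutes: float

    @property
    def sedentary_pct_of_wear(self) -> float:
        return 100.0 * self.sedentary_minutes / self.wear_minutes if self.wear_minutes else 0.0


def summarize_days(
    classified: ClassifiedTimeline,
    wear_mask: WearMask,
    participant: str = "P",
    bout_thresholds: tuple[float, float] = (10.0, 30.0),
) -> list[DailySummary]:
    """Per-calendar-day totals of one classified timeline.

    Bouts are detected on the full timeline (so a bout spanning midnight
    qualifies by its full duration) and attributed to days by overlap.
    """
    epoch = classified.recording_epoch
    end = max((b for _, b, _ in classified.intervals), default=0.0)
    bouts10, _ = detect_bouts(classified, bout_thresholds[0])
    bouts30, _ = detect_bouts(classified, bout_thresholds[1])
    out = []
    for day in range(n_calendar_days(epoch, end)):
        d0, d1 = day_bounds(epoch, day)
        wear_min = wear_mask.wear_seconds_in(d0, d1) / 60.0
        if wear_min == 0:
            continue
        date = (epoch + timedelta(seconds=(d0 + d1) / 2)).date().isoformat()
        out.append(
            DailySummary(
                participant=participant,
                date=date,
                wear_minutes=wear_min,
                sedentary_minutes=classified.minutes(Label.SEDENTARY, d0, d1),
                sedentary_bout10_minutes=iv.total_duration(iv.clip(bouts10, d0, d1)) / 60.0,
                sedentary_bout30_minutes=iv.total_duration(iv.clip(bouts30, d0, d1)) / 60.0,
            )
        )
    return out


def participant_mean(
    summaries: Sequence[DailySummary], min_wear_hours: float = 10.0
) -> dict[str, float] | None:
    """Average daily values over days with enough wear (default >= 10 h).

    Returns None (with a warning) for participants without any
    qualifying day.
    """
    days = [s for s in summaries if s.wear_minutes >= min_wear_hours * 60.0]
    if not days:
        if summaries:
            warnings.warn(
                f"participant {summaries[0].participant}: no day with "
                f">= {min_wear_hours} h wear",
                stacklevel=2,
            )
        return None
    return {
        "n_days": float(len(days)),
        "wear_minutes": float(np.mean([s.wear_minutes for s in days])),
        "sedentary_minutes": float(np.mean([s.sedentary_minutes for s in days])),
        "sedentary_bout10_minutes": float(np.mean([s.sedentary_bout10_minutes for s in days])),
        "sedentary_bout30_minutes": float(np.mean([s.sedentary_bout30_minutes for s in days])),
        "sedentary_pct_of_wear": float(np.mean([s.sedentary_pct_of_wear for s in days])),
    }
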