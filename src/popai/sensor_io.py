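"""Readers, writers and in-memory containers for the two sensor dialects.

The package uses a single time convention everywhere: seconds since the
start of the recording, with half-open intervals ``[start, start + duration)``.
Absolute datetimes appear only at the I/O boundary (the ``recording_epoch``
of each container maps t = 0 to wall-clock time).

Two plain-text dialects are supported:

* posture **event files** (thigh sensor): one row per posture event with a
  timestamp, an interval length in seconds, an activity code
  (0 = sitting/lying, 1 = standing, 2 = stepping) and a cumulative step
  count;
* **counts files** (waist sensor): a short metadata header followed by one
  CSV row of tri-axial counts per epoch (axis 1 is the vertical axis).

Column names, activity codes and header length are configurable through the
dialect objects so that exports from different software versions can be
mapped onto the same containers.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, UnsupportedEpochError

__all__ = [
    "Posture",
    "Placement",
    "PostureEvent",
    "EventTimeline",
    "CountsSeries",
    "RawRecording",
    "EventFileDialect",
    "CountsFileDialect",
    "read_event_file",
    "write_event_file",
    "read_counts_file",
    "write_counts_file",
    "counts_per_minute",
    "counts_in_span",
    "MinuteCounts",
]

#: tolerance for "events abut exactly", in seconds
ABUT_TOL = 1e-6

_TIME_FMT = "%Y-%m-%d %H:%M:%S.%f"


class Posture(enum.Enum):
    """Posture classes a thigh-worn event sensor can report.

    SIT covers sitting, reclining and lying — the sensor cannot separate
    them and the sedentary-behaviour definition treats them alike.
    """

    SIT = "sit"
    STAND = "stand"
    STEP = "step"


class Placement(enum.Enum):
    THIGH = "thigh"
    WAIST = "waist"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PostureEvent:
    """One contiguous posture event.

    Parameters
    ----------
    start : float
        Seconds since recording start (t = 0).
    duration : float
        Event length in seconds, > 0.
    posture : Posture
    steps : int
        Steps accumulated within this event; must be 0 for non-STEP events.
    """

    start: float
    duration: float
    posture: Posture
    steps: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntegrityError(f"event start {self.start} < 0")
        if self.duration <= 0:
            raise IntegrityError(f"event duration {self.duration} <= 0")
        if self.steps < 0:
            raise IntegrityError("negative step count")
        if self.posture is not Posture.STEP and self.steps != 0:
            raise IntegrityError(
                f"{self.posture.name} event carries {self.steps} steps"
            )

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class EventTimeline:
    """Ordered, contiguous sequence of posture events."""

    events: tuple[PostureEvent, ...]
    recording_epoch: datetime

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        prev_end: float | None = None
        for ev in self.events:
            if prev_end is not None and abs(ev.start - prev_end) > ABUT_TOL:
                raise IntegrityError(
                    f"events do not abut: gap/overlap of "
                    f"{ev.start - prev_end:+.6f} s at t={ev.start}"
                )
            prev_end = ev.end

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def start(self) -> float:
        return self.events[0].start if self.events else 0.0

    @property
    def end(self) -> float:
        return self.events[-1].end if self.events else 0.0

    @property
    def total_duration(self) -> float:
        return self.end - self.start

    def total_steps(self) -> int:
        return sum(ev.steps for ev in self.events)

    def events_in_span(self, t0: float, t1: float) -> list[PostureEvent]:
        """Events overlapping the half-open span [t0, t1)."""
        return [ev for ev in self.events if ev.start < t1 and ev.end > t0]


@dataclass(frozen=True)
class CountsSeries:
    """Tri-axial activity counts at a fixed epoch length.

    axis1 is the vertical axis, on which the classic counts-per-minute
    cut-points are defined.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    axis3: np.ndarray
    recording_epoch: datetime
    epoch_length: float = 1.0

    def __post_init__(self) -> None:
        for name in ("axis1", "axis2", "axis3"):
            arr = np.asarray(getattr(self, name))
            if arr.ndim != 1:
                raise IntegrityError(f"{name} must be one-dimensional")
            if np.any(arr < 0):
                raise IntegrityError(f"negative counts in {name}")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise FormatError(f"non-integer counts in {name}")
                arr = arr.astype(np.int64)
            object.__setattr__(self, name, arr)
        if not (len(self.axis1) == len(self.axis2) == len(self.axis3)):
            raise IntegrityError("axes differ in length")
        if self.epoch_length <= 0:
            raise IntegrityError("epoch_length must be positive")

    def __len__(self) -> int:
        return len(self.axis1)

    @property
    def duration(self) -> float:
        return len(self) * self.epoch_length

    def axis(self, choice: str) -> np.ndarray:
        """Return one axis or the vector magnitude ('vm')."""
        if choice in ("axis1", "axis2", "axis3"):
            return getattr(self, choice)
        if choice == "vm":
            return np.sqrt(
                self.axis1.astype(float) ** 2
                + self.axis2.astype(float) ** 2
                + self.axis3.astype(float) ** 2
            )
        raise ValueError(f"unknown axis choice {choice!r}")


@dataclass(frozen=True)
class RawRecording:
    """Raw tri-axial acceleration in g at a fixed sampling rate."""

    acceleration: np.ndarray  # shape (n, 3)
    sampling_rate: float
    placement: Placement
    recording_epoch: datetime
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.acceleration)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise IntegrityError("acceleration must have shape (n, 3)")
        if self.sampling_rate <= 0:
            raise IntegrityError("sampling_rate must be positive")
        object.__setattr__(self, "acceleration", arr)

    def __len__(self) -> int:
        return len(self.acceleration)

    @property
    def duration(self) -> float:
        return len(self) / self.sampling_rate

    def vector_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.acceleration, axis=1)

    def slice_seconds(self, t0: float, t1: float) -> np.ndarray:
        """Samples covering [t0, t1), clipped to the recording."""
        i0 = max(0, int(round(t0 * self.sampling_rate)))
        i1 = min(len(self), int(round(t1 * self.sampling_rate)))
        return self.acceleration[i0:i1]


# ---------------------------------------------------------------------------
# event-file dialect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventFileDialect:
    """Column layout of a posture event file.

    The default mimics the common vendor export: a header row, timestamps
    as datetime strings and activity codes 0/1/2 for sit/stand/step with a
    cumulative step counter.
    """

    time_column: str = "Time"
    interval_column: str = "Interval (s)"
    activity_column: str = "ActivityCode"
    steps_column: str = "CumulativeStepCount"
    activity_codes: tuple[tuple[int, Posture], ...] = (
        (0, Posture.SIT),
        (1, Posture.STAND),
        (2, Posture.STEP),
    )

    def code_to_posture(self) -> dict[int, Posture]:
        return dict(self.activity_codes)

    def posture_to_code(self) -> dict[Posture, int]:
        return {p: c for c, p in self.activity_codes}


DEFAULT_EVENT_DIALECT = EventFileDialect()


def read_event_file(
    path: str | Path, dialect: EventFileDialect = DEFAULT_EVENT_DIALECT
) -> EventTimeline:
    """Parse a posture event file into an :class:`EventTimeline`.

    The cumulative step column is converted to per-event steps; decreasing
    cumulative counts or steps attributed to non-stepping events raise
    :class:`~popai.errors.IntegrityError`.
    """
    df = pd.read_csv(path)
    required = [
        dialect.time_column,
        dialect.interval_column,
        dialect.activity_column,
        dialect.steps_column,
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"event file missing column(s) {missing}")
    if len(df) == 0:
        raise FormatError("event file contains no events")

    times = pd.to_datetime(df[dialect.time_column])
    epoch = times.iloc[0].to_pydatetime()
    starts = (times - times.iloc[0]).dt.total_seconds().to_numpy()
    durations = df[dialect.interval_column].to_numpy(dtype=float)
    codes = df[dialect.activity_column].to_numpy()
    cum_steps = df[dialect.steps_column].to_numpy(dtype=float)
    if np.any(np.diff(cum_steps) < 0):
        raise IntegrityError("cumulative step count decreases")
    per_event = np.diff(np.concatenate([[0.0], cum_steps]))

    code_map = dialect.code_to_posture()
    events = []
    for s, d, c, st in zip(starts, durations, codes, per_event):
        try:
            posture = code_map[int(c)]
        except KeyError:
            raise FormatError(f"unknown activity code {c!r}") from None
        events.append(PostureEvent(s, d, posture, int(round(st))))
    try:
        return EventTimeline(tuple(events), epoch)
    except IntegrityError as exc:
        raise IntegrityError(f"malformed event file {path}: {exc}") from exc


def write_event_file(
    timeline: EventTimeline,
    path: str | Path,
    dialect: EventFileDialect = DEFAULT_EVENT_DIALECT,
) -> None:
    code_map = dialect.posture_to_code()
    rows = []
    cum = 0
    for ev in timeline.events:
        cum += ev.steps
        rows.append(
            {
                dialect.time_column: (
                    timeline.recording_epoch + timedelta(seconds=ev.start)
                ).strftime(_TIME_FMT),
                dialect.interval_column: ev.duration,
                dialect.activity_column: code_map[ev.posture],
                dialect.steps_column: cum,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# counts-file dialect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountsFileDialect:
    """Layout of a counts file: metadata header then CSV epoch rows."""

    header_lines: int = 10
    start_time_key: str = "Start Time"
    start_date_key: str = "Start Date"
    epoch_key: str = "Epoch Period (hh:mm:ss)"
    epoch_count_key: str = "Epoch Count"
    date_format: str = "%d/%m/%Y"


DEFAULT_COUNTS_DIALECT = CountsFileDialect()


def _parse_epoch_period(text: str) -> float:
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise FormatError(f"cannot parse epoch period {text!r}")
    h, m, s = (int(p) for p in parts)
    return h * 3600 + m * 60 + s


def read_counts_file(
    path: str | Path, dialect: CountsFileDialect = DEFAULT_COUNTS_DIALECT
) -> CountsSeries:
    """Parse a counts file (metadata header + per-epoch CSV rows).

    If the header declares an epoch count, it is cross-checked against the
    number of data rows; a mismatch raises :class:`FormatError` since it
    implies the declared epoch length is wrong.
    """
    path = Path(path)
    with open(path) as fh:
        header = [fh.readline() for _ in range(dialect.header_lines)]
        body = fh.read()

    meta: dict[str, str] = {}
    for line in header:
        line = line.strip()
        for key in (
            dialect.start_time_key,
            dialect.start_date_key,
            dialect.epoch_key,
            dialect.epoch_count_key,
        ):
            if line.startswith(key):
                meta[key] = line[len(key):].strip(" :\t")
    for key in (dialect.start_time_key, dialect.start_date_key, dialect.epoch_key):
        if key not in meta:
            raise FormatError(f"counts header missing {key!r}")

    epoch_length = _parse_epoch_period(meta[dialect.epoch_key])
    start = datetime.strptime(
        f"{meta[dialect.start_date_key]} {meta[dialect.start_time_key]}",
        f"{dialect.date_format} %H:%M:%S",
    )

    df = pd.read_csv(io.StringIO(body))
    for col in ("Axis1", "Axis2", "Axis3"):
        if col not in df.columns:
            raise FormatError(f"counts file missing column {col!r}")
        vals = df[col].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise FormatError(f"non-integer counts in {col}")

    if dialect.epoch_count_key in meta:
        declared = int(meta[dialect.epoch_count_key])
        if declared != len(df):
            raise FormatError(
                f"header declares {declared} epochs of {epoch_length} s "
                f"but file has {len(df)} rows"
            )

    return CountsSeries(
        axis1=df["Axis1"].to_numpy(dtype=np.int64),
        axis2=df["Axis2"].to_numpy(dtype=np.int64),
        axis3=df["Axis3"].to_numpy(dtype=np.int64),
        recording_epoch=start,
        epoch_length=epoch_length,
    )


def write_counts_file(
    series: CountsSeries,
    path: str | Path,
    dialect: CountsFileDialect = DEFAULT_COUNTS_DIALECT,
) -> None:
    ep = int(round(series.epoch_length))
    epoch_str = f"{ep // 3600:02d}:{(ep % 3600) // 60:02d}:{ep % 60:02d}"
    header = [
        "------------ Data File Created By popai ------------",
        "Serial Number: SYN00001",
        f"{dialect.start_time_key} {series.recording_epoch.strftime('%H:%M:%S')}",
        f"{dialect.start_date_key} {series.recording_epoch.strftime(dialect.date_format)}",
        f"{dialect.epoch_key} {epoch_str}",
        f"{dialect.epoch_count_key}: {len(series)}",
        "Filter: low-frequency-extension",
        "Mode: 61",
        "Placement: waist",
        "----------------------------------------------------",
    ]
    if len(header) != dialect.header_lines:
        header = header[: dialect.header_lines] + [
            "-" * 20 for _ in range(dialect.header_lines - len(header))
        ]
    df = pd.DataFrame(
        {"Axis1": series.axis1, "Axis2": series.axis2, "Axis3": series.axis3}
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MinuteCounts:
    """Counts aggregated to clock minutes.

    ``fractions[i]`` records how much of minute *i* the recording covers
    (1.0 except possibly for a trailing partial minute).
    """

    values: np.ndarray
    fractions: np.ndarray
    anchor: float  # seconds since recording start of minute 0

    def __len__(self) -> int:
        return len(self.values)


def counts_per_minute(
    series: CountsSeries, axis_choice: str = "axis1", anchor: float = 0.0
) -> MinuteCounts:
    """Sum epoch counts into clock-minute bins.

    Minutes are anchored at ``anchor`` seconds after the recording epoch
    (default: the recording start itself). The epoch length must divide
    60 s; a trailing partial minute is kept with its covered fraction.
    """
    if not math.isclose(60.0 / series.epoch_length, round(60.0 / series.epoch_length)):
        raise UnsupportedEpochError(
            f"epoch length {series.epoch_length} s does not divide 60 s"
        )
    per_min = int(round(60.0 / series.epoch_length))
    vals = series.axis(axis_choice).astype(float)
    off = int(round(anchor / series.epoch_length))
    vals = vals[off:] if off >= 0 else np.concatenate([np.zeros(-off), vals])
    n_full = len(vals) // per_min
    rem = len(vals) - n_full * per_min
    minutes = vals[: n_full * per_min].reshape(n_full, per_min).sum(axis=1)
    fractions = np.ones(n_full)
    if rem:
        minutes = np.concatenate([minutes, [vals[n_full * per_min:].sum()]])
        fractions = np.concatenate([fractions, [rem / per_min]])
    return MinuteCounts(values=minutes, fractions=fractions, anchor=max(anchor, 0.0))


def counts_in_span(
    series: CountsSeries, t0: float, t1: float, axis_choice: str = "axis1"
) -> float:
    """Counts accumulated over [t0, t1), pro-rating partially covered epochs."""
    if t1 <= t0:
        raise ValueError(f"empty span [{t0}, {t1})")
    vals = series.axis(axis_choice).astype(float)
    ep = series.epoch_length
    n = len(vals)
    lo = max(t0 / ep, 0.0)
    hi = min(t1 / ep, float(n))
    if hi <= lo:
        return 0.0
    i0, i1 = int(math.floor(lo)), int(math.ceil(hi))
    total = 0.0
    for i in range(i0, i1):
        cover = min(hi, i + 1) - max(lo, i)
        total += vals[i] * cover
    return total
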