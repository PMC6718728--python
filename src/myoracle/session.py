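"""Domain model for myocontrol sessions.

A *session* is one subject's recording of a sequence of grasp-carry-release
tasks performed under simultaneous-and-proportional (s/p) myocontrol of a
six-motor prosthetic hand.  It bundles synchronized time series — the
4-channel myocontrol prediction trace (each channel in [0, 1]) and the
6-digit hand status trace — together with the task timelines, the ground
truth myocontrol failure instants, and the subject's button presses.

Time is expressed in session-absolute seconds from the start of the traces;
task timelines store absolute times.  Both traces share one uniform sample
grid, so sample ``i`` lives at ``i / sample_rate`` seconds.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_CHANNELS = 4
N_DIGITS = 6

#: Digit order used throughout: five digit flexion motors plus the thumb
#: rotator of the i-LIMB style hand.
DIGIT_NAMES = ("thumb", "index", "middle", "ring", "little", "rotator")

#: Prediction channel driving each digit.  The middle, ring and little
#: fingers are mechanically coupled for the power grasp and share one
#: command channel, which is why four prediction channels suffice for six
#: motors.
DIGIT_CHANNEL = (0, 1, 2, 2, 2, 3)

#: Representative digit for each prediction channel (used when the 6-digit
#: status trace is collapsed to 4 channels).
CHANNEL_DIGITS = (0, 1, 2, 5)


class SessionError(ValueError):
    """Base class for session validation problems."""


class ValidationError(SessionError):
    """A type invariant is violated (ranges, monotone timelines, shapes)."""


class SchemaError(SessionError):
    """A serialized file does not match the expected schema."""


class DigitStatus(enum.IntEnum):
    """Per-motor feedback flag reported by the prosthetic hand."""

    OPENING = 0
    OPEN = 1
    CLOSING = 2
    CLOSED = 3
    STALLED = 4


class Zone(enum.Enum):
    """The three intent zones of a carrying task."""

    PRE_GRASP = "PRE_GRASP"
    GRASP = "GRASP"
    POST_GRASP = "POST_GRASP"


class FailureKind(enum.Enum):
    """Direction of an instability event relative to the user's intent."""

    SPURIOUS_CLOSE = "SPURIOUS_CLOSE"  # channel rises over threshold at rest
    SPURIOUS_OPEN = "SPURIOUS_OPEN"  # grasp channel dips below threshold


@dataclasses.dataclass(frozen=True)
class TaskTimeline:
    """Key instants of one carrying task, in session-absolute seconds.

    The subject rests from ``t_start`` to ``t_grasp``, holds a power grasp
    from ``t_grasp`` to ``t_release``, and rests again until ``t_end``.
    """

    t_start: float
    t_grasp: float
    t_release: float
    t_end: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_grasp < self.t_release < self.t_end):
            raise ValidationError(
                "task timeline must satisfy t_start < t_grasp < t_release "
                f"< t_end, got ({self.t_start}, {self.t_grasp}, "
                f"{self.t_release}, {self.t_end})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def zone_bounds(self, zone: Zone) -> tuple[float, float]:
        if zone is Zone.PRE_GRASP:
            return self.t_start, self.t_grasp
        if zone is Zone.GRASP:
            return self.t_grasp, self.t_release
        return self.t_release, self.t_end


def zone_of(t: float, timeline: TaskTimeline) -> Zone:
    """Map an instant inside a task to its intent zone.

    Zones are half-open on the right: ``[t_start, t_grasp)`` is PRE_GRASP,
    ``[t_grasp, t_release)`` is GRASP and ``[t_release, t_end]`` is
    POST_GRASP, so the grasp instant itself belongs to the GRASP zone and
    every instant of the task maps to exactly one zone.
    """
    if not (timeline.t_start <= t <= timeline.t_end):
        raise ValidationError(
            f"t={t} outside task [{timeline.t_start}, {timeline.t_end}]"
        )
    if t < timeline.t_grasp:
        return Zone.PRE_GRASP
    if t < timeline.t_release:
        return Zone.GRASP
    return Zone.POST_GRASP


@dataclasses.dataclass
class PredictionTrace:
    """4-channel myocontrol prediction signal, each channel in [0, 1]."""

    sample_rate: float
    values: np.ndarray  # shape (4, T)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.values.ndim != 2 or self.values.shape[0] != N_CHANNELS:
            raise ValidationError(
                f"prediction trace must be ({N_CHANNELS}, T), "
                f"got {self.values.shape}"
            )
        bad = np.argwhere((self.values < 0.0) | (self.values > 1.0))
        if bad.size:
            ch, i = bad[0]
            raise ValidationError(
                f"prediction value {self.values[ch, i]} out of [0, 1] on "
                f"channel {ch + 1} at t={i / self.sample_rate:.4f}s"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PredictionTrace):
            return NotImplemented
        return self.sample_rate == other.sample_rate and np.array_equal(
            self.values, other.values
        )


@dataclasses.dataclass
class DigitStatusTrace:
    """6-digit prosthetic hand status flags on the prediction timebase."""

    sample_rate: float
    statuses: np.ndarray  # shape (6, T), values from DigitStatus

    def __post_init__(self) -> None:
        self.statuses = np.asarray(self.statuses, dtype=np.int8)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.statuses.ndim != 2 or self.statuses.shape[0] != N_DIGITS:
            raise ValidationError(
                f"status trace must be ({N_DIGITS}, T), "
                f"got {self.statuses.shape}"
            )
        valid = {int(s) for s in DigitStatus}
        present = set(np.unique(self.statuses).tolist())
        if not present <= valid:
            raise ValidationError(
                f"unknown digit status codes {sorted(present - valid)}"
            )

    @property
    def n_samples(self) -> int:
        return self.statuses.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DigitStatusTrace):
            return NotImplemented
        return self.sample_rate == other.sample_rate and np.array_equal(
            self.statuses, other.statuses
        )


@dataclasses.dataclass(frozen=True)
class FailureEvent:
    """A discrete instability instant: the first moment the hand starts a
    behavior contrary to the user's intent."""

    time: float
    channel: int  # 1-based prediction channel index
    kind: FailureKind

    def __post_init__(self) -> None:
        if not 1 <= self.channel <= N_CHANNELS:
            raise ValidationError(
                f"failure channel must be 1..{N_CHANNELS}, got {self.channel}"
            )


@dataclasses.dataclass(frozen=True)
class ButtonEvent:
    """A short press of the wireless button signalling a perceived failure."""

    time: float


@dataclasses.dataclass
class Session:
    """One subject-session: traces, task timelines, failures, buttons."""

    prediction: PredictionTrace
    digit_status: DigitStatusTrace
    tasks: list[TaskTimeline]
    failures: list[FailureEvent]
    buttons: list[ButtonEvent]
    subject_id: str = "S?"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_rate(self) -> float:
        return self.prediction.sample_rate

    @property
    def duration(self) -> float:
        return (self.prediction.n_samples - 1) / self.sample_rate

    def task_of(self, t: float) -> TaskTimeline | None:
        """Enclosing task of instant ``t``, or None between tasks."""
        for task in self.tasks:
            if task.t_start <= t <= task.t_end:
                return task
        return None

    def validate(self) -> None:
        if self.prediction.sample_rate != self.digit_status.sample_rate:
            raise ValidationError("trace sample rates differ")
        if self.prediction.n_samples != self.digit_status.n_samples:
            raise ValidationError("trace lengths differ")
        if not self.tasks:
            raise ValidationError("session has no tasks")
        for a, b in zip(self.tasks, self.tasks[1:]):
            if a.t_end > b.t_start:
                raise ValidationError(
                    f"tasks overlap or are unordered near t={a.t_end}"
                )
        span_end = self.tasks[-1].t_end
        if self.tasks[0].t_start < 0 or span_end > self.duration + 1e-9:
            raise ValidationError(
                "traces do not cover the union of task spans "
                f"(tasks end {span_end}, traces end {self.duration})"
            )
        for ev in self.failures:
            if self.task_of(ev.time) is None:
                raise ValidationError(
                    f"failure at t={ev.time} lies outside every task"
                )
        for b in self.buttons:
            if not 0 <= b.time <= self.duration:
                raise ValidationError(f"button at t={b.time} outside session")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.prediction == other.prediction
            and self.digit_status == other.digit_status
            and self.tasks == other.tasks
            and self.failures == other.failures
            and self.buttons == other.buttons
        )


# ---------------------------------------------------------------------------
# Serialization: traces CSV + metadata JSON
# ---------------------------------------------------------------------------

TRACES_FILE = "traces.csv"
META_FILE = "metadata.json"

_CSV_COLUMNS = (
    ["time"]
    + [f"p{i + 1}" for i in range(N_CHANNELS)]
    + [f"d{i + 1}" for i in range(N_DIGITS)]
)


def write_session(session: Session, path: str | Path) -> None:
    """Write a session as ``traces.csv`` + ``metadata.json`` in ``path``.

    Floats are serialized with ``repr`` round-trip precision, so reading
    the files back reproduces the session exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    cols: dict[str, object] = {"time": session.prediction.times}
    for i in range(N_CHANNELS):
        cols[f"p{i + 1}"] = session.prediction.values[i]
    for i in range(N_DIGITS):
        cols[f"d{i + 1}"] = [
            DigitStatus(s).name for s in session.digit_status.statuses[i]
        ]
    pd.DataFrame(cols, columns=_CSV_COLUMNS).to_csv(
        path / TRACES_FILE, index=False
    )

    meta = {
        "subject_id": session.subject_id,
        "sample_rate": session.sample_rate,
        "tasks": [dataclasses.asdict(t) for t in session.tasks],
        "failures": [
            {"time": f.time, "channel": f.channel, "kind": f.kind.value}
            for f in session.failures
        ],
        "buttons": [{"time": b.time} for b in session.buttons],
    }
    (path / META_FILE).write_text(json.dumps(meta, indent=1))


def read_session(path: str | Path) -> Session:
    """Read and validate a session written by :func:`write_session`.

    Status strings are parsed case-insensitively; unknown statuses raise a
    :class:`SchemaError` naming the offending row.
    """
    path = Path(path)
    meta = json.loads((path / META_FILE).read_text())
    df = pd.read_csv(path / TRACES_FILE, float_precision="round_trip")

    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"traces CSV missing columns {missing}")

    values = df[[f"p{i + 1}" for i in range(N_CHANNELS)]].to_numpy(float).T

    name_to_code = {s.name: int(s) for s in DigitStatus}
    statuses = np.empty((N_DIGITS, len(df)), dtype=np.int8)
    for i in range(N_DIGITS):
        col = df[f"d{i + 1}"].astype(str).str.upper()
        unknown = ~col.isin(name_to_code)
        if unknown.any():
            row = int(np.flatnonzero(unknown)[0])
            raise SchemaError(
                f"unknown digit status {col.iloc[row]!r} in column "
                f"d{i + 1}, data row {row}"
            )
        statuses[i] = col.map(name_to_code).to_numpy()

    rate = float(meta["sample_rate"])
    tasks = [TaskTimeline(**t) for t in meta["tasks"]]
    failures = [
        FailureEvent(
            time=f["time"], channel=f["channel"], kind=FailureKind(f["kind"])
        )
        for f in meta["failures"]
    ]
    buttons = [ButtonEvent(time=b["time"]) for b in meta["buttons"]]
    return Session(
        prediction=PredictionTrace(sample_rate=rate, values=values),
        digit_status=DigitStatusTrace(sample_rate=rate, statuses=statuses),
        tasks=tasks,
        failures=failures,
        buttons=buttons,
        subject_id=str(meta["subject_id"]),
    )
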