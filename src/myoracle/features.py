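"""Sliding-window failure-detection features.

Two count features are computed per prediction channel over a running
window:

* **TC** (threshold crossings) — how often the myocontrol prediction signal
  crosses the actuation threshold within the window; instability shows up
  as oscillation around the threshold.
* **SC** (status changes) — how often the binarized (flexing/extending)
  digit status changes within the window; the same oscillation seen through
  the hand's electromechanics.

Both give 4-dimensional count vectors (one entry per prediction channel);
TC+SC is their 8-dimensional concatenation.  Windows restart at each task's
``t_start``, never span task boundaries, and are labeled 1 (failure) when a
ground-truth failure instant falls inside them, else 0 (success).
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .session import (
    CHANNEL_DIGITS,
    N_CHANNELS,
    DigitStatus,
    DigitStatusTrace,
    FailureEvent,
    Session,
)

_EPS = 1e-9

#: Window lengths evaluated in the study, seconds.
WINDOW_LENGTHS = (0.5, 1.0, 3.0)


class Overlap(enum.Enum):
    NONE = "none"
    HALF = "half"


class FeatureType(enum.Enum):
    TC = "tc"
    SC = "sc"
    TCSC = "tcsc"

    @property
    def dimension(self) -> int:
        return 8 if self is FeatureType.TCSC else 4


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Running-window geometry: length and overlap (none or half)."""

    length: float
    overlap: Overlap = Overlap.NONE

    @property
    def step(self) -> float:
        return self.length if self.overlap is Overlap.NONE else self.length / 2.0


@dataclasses.dataclass
class FeatureVector:
    """Counts for one window plus its success/failure label."""

    window_start: float
    window_end: float
    counts: np.ndarray  # non-negative ints, dim 4 (TC or SC) or 8 (TC+SC)
    label: int  # 0 = success, 1 = failure

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("feature counts must be non-negative")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (success) or 1 (failure)")


@dataclasses.dataclass
class FilteredStatusTrace:
    """Binarized digit status: 0 = extending, 1 = flexing, 4 channels."""

    sample_rate: float
    values: np.ndarray  # (4, T) of {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[0] != N_CHANNELS:
            raise ValueError(
                f"filtered trace must be ({N_CHANNELS}, T), got {self.values.shape}"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("filtered status values must be binary")


def filter_digit_status(trace: DigitStatusTrace) -> FilteredStatusTrace:
    """Collapse the 6-digit status trace to a binary 4-channel trace.

    CLOSING/CLOSED map to flexing (1), OPENING/OPEN to extending (0).  A
    STALLED digit holds its previous binary value (an initial STALLED reads
    as extending) — a stall preserves the last motion direction rather than
    inventing a phantom status change.  The six digits collapse to the four
    prediction channels via their representative digits, the coupled
    middle/ring/little fingers contributing through the middle digit.
    """
    sel = trace.statuses[list(CHANNEL_DIGITS), :].astype(float)
    mapped = np.empty_like(sel)
    mapped[np.isin(sel, (DigitStatus.OPENING, DigitStatus.OPEN))] = 0.0
    mapped[np.isin(sel, (DigitStatus.CLOSING, DigitStatus.CLOSED))] = 1.0
    mapped[sel == DigitStatus.STALLED] = np.nan
    filled = (
        pd.DataFrame(mapped.T).ffill().fillna(0.0).to_numpy().T
    )  # hold-last across STALLED runs
    return FilteredStatusTrace(sample_rate=trace.sample_rate, values=filled)


def count_threshold_crossings(window: np.ndarray, threshold: float) -> np.ndarray:
    """Per-channel threshold-crossing counts over a window of the
    prediction trace (channels x samples).

    A crossing is a sign change of ``x - threshold`` between consecutive
    samples, counted in both directions; samples exactly at the threshold
    are treated as below it.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] == 0:
        raise ValueError("window must be a non-empty (channels, samples) array")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    above = window > threshold
    return (above[:, 1:] != above[:, :-1]).sum(axis=1)


def count_status_changes(window: np.ndarray) -> np.ndarray:
    """Per-channel count of value changes of the filtered status trace."""
    window = np.asarray(window)
    if window.ndim != 2 or window.shape[1] == 0:
        raise ValueError("window must be a non-empty (channels, samples) array")
    return (window[:, 1:] != window[:, :-1]).sum(axis=1)


def make_windows(span: tuple[float, float], spec: WindowSpec) -> list[tuple[float, float]]:
    """Tile ``[t0, t1]`` with half-open windows of the given spec.

    Windows start at ``t0`` and advance by the spec's step; a trailing
    window that would extend past ``t1`` is dropped so that counts remain
    comparable across window sizes.  Returns an empty list when the span is
    shorter than one window.
    """
    t0, t1 = span
    if t1 - t0 + _EPS < spec.length:
        return []
    n = int(np.floor((t1 - t0 - spec.length) / spec.step + _EPS)) + 1
    return [
        (t0 + k * spec.step, t0 + k * spec.step + spec.length) for k in range(n)
    ]


def label_window(
    window: tuple[float, float], failures: Sequence[FailureEvent]
) -> int:
    """1 iff any failure instant falls in the half-open window [start, end)."""
    start, end = window
    return int(any(start <= f.time < end for f in failures))


def extract_dataset(
    session: Session,
    spec: WindowSpec,
    feature_type: FeatureType,
    threshold: float = 0.3,
) -> list[FeatureVector]:
    """Enumerate labeled feature vectors over all tasks of a session.

    Windows are tiled per task from its ``t_start`` and never cross task
    boundaries (tasks are separated by seated pauses).  Sample membership
    follows the half-open window convention on the shared sample grid.
    """
    if not isinstance(feature_type, FeatureType):
        raise ValueError(f"unknown feature type {feature_type!r}")
    rate = session.sample_rate
    pred = session.prediction.values
    filt = filter_digit_status(session.digit_status).values

    out: list[FeatureVector] = []
    for task in session.tasks:
        for start, end in make_windows((task.t_start, task.t_end), spec):
            i0 = int(np.ceil(start * rate - _EPS))
            i1 = int(np.ceil(end * rate - _EPS))
            parts = []
            if feature_type in (FeatureType.TC, FeatureType.TCSC):
                parts.append(count_threshold_crossings(pred[:, i0:i1], threshold))
            if feature_type in (FeatureType.SC, FeatureType.TCSC):
                parts.append(count_status_changes(filt[:, i0:i1]))
            out.append(
                FeatureVector(
                    window_start=start,
                    window_end=end,
                    counts=np.concatenate(parts),
                    label=label_window((start, end), session.failures),
                )
            )
    return out


def all_feature_sets() -> list[tuple[FeatureType, WindowSpec]]:
    """The 18 feature sets: 3 feature types x 3 lengths x 2 overlaps."""
    return [
        (ft, WindowSpec(length, overlap))
        for ft in FeatureType
        for length in WINDOW_LENGTHS
        for overlap in Overlap
    ]


# ---------------------------------------------------------------------------
# Dataset (de)serialization: one CSV row per window
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ["start", "end"] + [f"c{i + 1}" for i in range(8)] + ["label"]


def dataset_to_frame(dataset: Sequence[FeatureVector]) -> pd.DataFrame:
    rows = []
    for fv in dataset:
        counts = list(fv.counts) + [np.nan] * (8 - len(fv.counts))
        rows.append([fv.window_start, fv.window_end, *counts, fv.label])
    return pd.DataFrame(rows, columns=_FEATURE_COLUMNS)


def write_features(dataset: Sequence[FeatureVector], path: str | Path) -> None:
    dataset_to_frame(dataset).to_csv(Path(path), index=False)


def read_features(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        counts = row[[f"c{i + 1}" for i in range(8)]].dropna().to_numpy()
        out.append(
            FeatureVector(
                window_start=float(row["start"]),
                window_end=float(row["end"]),
                counts=counts.astype(int),
                label=int(row["label"]),
            )
        )
    return out
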