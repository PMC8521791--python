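"""Data model and CSV I/O for 9-channel wrist-IMU streams.

A stream carries the nine channels a wrist-worn device reports at a nominal
50 Hz: user (gravity-compensated) acceleration on three axes in G, the three
attitude angles (yaw/roll/pitch) in radians, and the three rotation-rate
components in rad/s.  Channels live in a fixed canonical order everywhere in
the package; readers reorder file columns to it.

Timestamps are validated (strict monotonicity, jitter against the nominal
rate) but all downstream windowing is done by sample count at the nominal
rate: observed sampling jitter on the target hardware is well under 10 ms,
so timestamp-based resampling would add complexity without information.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyStreamError,
    MalformedRowError,
    MissingChannelError,
    NonMonotoneTimestampsError,
    UnwritablePathError,
)

#: Canonical channel order (acceleration, attitude, rotation rate).
CHANNELS: tuple[str, ...] = (
    "user_accel_x_g",
    "user_accel_y_g",
    "user_accel_z_g",
    "yaw_rad",
    "roll_rad",
    "pitch_rad",
    "rot_rate_x_rad_s",
    "rot_rate_y_rad_s",
    "rot_rate_z_rad_s",
)

#: Unit tag per canonical channel.
CHANNEL_UNITS: dict[str, str] = {
    "user_accel_x_g": "G",
    "user_accel_y_g": "G",
    "user_accel_z_g": "G",
    "yaw_rad": "rad",
    "roll_rad": "rad",
    "pitch_rad": "rad",
    "rot_rate_x_rad_s": "rad/s",
    "rot_rate_y_rad_s": "rad/s",
    "rot_rate_z_rad_s": "rad/s",
}

N_CHANNELS = len(CHANNELS)

#: Canonical 7-class activity label set: walking, standing, reading, typing,
#: writing, sitting, lying.  Reading/typing/writing carry no posture
#: attribute — the sitting and standing variants map to the same class.
ACTIVITY_CLASSES: tuple[str, ...] = ("W_N", "St_N", "Re", "Ty", "Wr", "Si_N", "L_N")

#: The subset of classes that counts as "working".
WORKING_CLASSES: tuple[str, ...] = ("Re", "Ty", "Wr")

TIMESTAMP_COLUMN = "timestamp_s"
LABEL_COLUMN = "label"
SUBJECT_COLUMN = "subject_id"
EPISODE_COLUMN = "episode_id"

DEFAULT_RATE_HZ = 50.0


@dataclass
class SensorStream:
    """A timestamped 9-channel recording for one subject.

    Attributes
    ----------
    subject_id:
        Identifier of the wearer.
    timestamps:
        Strictly increasing sample times in seconds, shape ``(T,)``.
    values:
        ``(T, 9)`` float array in canonical :data:`CHANNELS` order.
    nominal_rate:
        Nominal sampling rate in Hz (default 50).
    labels:
        Optional per-sample activity labels (length ``T``).
    episode_ids:
        Optional per-sample protocol-episode indices (length ``T``);
        windowing never crosses an episode boundary when present.
    """

    subject_id: str
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float = DEFAULT_RATE_HZ
    labels: np.ndarray | None = None
    episode_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(f"values must be (T, {N_CHANNELS}), got {self.values.shape}")
        if self.timestamps.shape[0] != self.values.shape[0]:
            raise ValueError("timestamps and values disagree in length")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise NonMonotoneTimestampsError(
                f"timestamps of subject {self.subject_id!r} are not strictly increasing"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != self.timestamps.shape[0]:
                raise ValueError("labels length differs from timestamps")
        if self.episode_ids is not None:
            self.episode_ids = np.asarray(self.episode_ids, dtype=int)
            if self.episode_ids.shape[0] != self.timestamps.shape[0]:
                raise ValueError("episode_ids length differs from timestamps")

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.nominal_rate

    def __eq__(self, other: object) -> bool:  # full-precision equality
        if not isinstance(other, SensorStream):
            return NotImplemented
        same_opt = (
            (self.labels is None) == (other.labels is None)
            and (self.episode_ids is None) == (other.episode_ids is None)
        )
        if not same_opt:
            return False
        return (
            self.subject_id == other.subject_id
            and self.nominal_rate == other.nominal_rate
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.values, other.values)
            and (self.labels is None or bool(np.all(self.labels == other.labels)))
            and (self.episode_ids is None or np.array_equal(self.episode_ids, other.episode_ids))
        )


@dataclass(frozen=True)
class SamplingReport:
    """Result of :func:`validate_sampling`."""

    nominal_rate: float
    jitter_tol_s: float
    max_jitter_s: float
    n_violations: int
    n_intervals: int
    passed: bool = field(default=False)


def read_stream_csv(path: str | os.PathLike) -> SensorStream:
    """Read a stream CSV, reordering columns to canonical channel order.

    The file must contain ``timestamp_s`` and all nine channel columns;
    ``label``, ``subject_id`` and ``episode_id`` columns are loaded when
    present.  Any missing or non-numeric cell in a numeric column raises
    :class:`MalformedRowError`; non-increasing timestamps raise
    :class:`NonMonotoneTimestampsError`.
    """
    frame = pd.read_csv(
        path, dtype={LABEL_COLUMN: str, SUBJECT_COLUMN: str}, float_precision="round_trip"
    )
    required = (TIMESTAMP_COLUMN,) + CHANNELS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise MissingChannelError(f"{path}: missing required column(s) {missing}")

    numeric_cols = list(required)
    if EPISODE_COLUMN in frame.columns:
        numeric_cols.append(EPISODE_COLUMN)
    numeric = frame[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MalformedRowError(
            f"{path}: non-numeric or missing value at row {r}, column {numeric.columns[c]!r}"
        )

    timestamps = numeric[TIMESTAMP_COLUMN].to_numpy(dtype=float)
    if timestamps.size > 1 and not np.all(np.diff(timestamps) > 0):
        raise NonMonotoneTimestampsError(f"{path}: timestamps are not strictly increasing")

    labels = None
    if LABEL_COLUMN in frame.columns:
        labels = frame[LABEL_COLUMN].to_numpy(dtype=object)
        if pd.isna(labels).any():
            raise MalformedRowError(f"{path}: missing label cell")
    episode_ids = None
    if EPISODE_COLUMN in frame.columns:
        episode_ids = numeric[EPISODE_COLUMN].to_numpy(dtype=int)
    subject_id = ""
    if SUBJECT_COLUMN in frame.columns and len(frame):
        subject_id = str(frame[SUBJECT_COLUMN].iloc[0])

    rate = DEFAULT_RATE_HZ
    if timestamps.size > 1:
        median_dt = float(np.median(np.diff(timestamps)))
        if median_dt > 0:
            rate = round(1.0 / median_dt, 6)

    return SensorStream(
        subject_id=subject_id,
        timestamps=timestamps,
        values=numeric[list(CHANNELS)].to_numpy(dtype=float),
        nominal_rate=rate,
        labels=labels,
        episode_ids=episode_ids,
    )


def write_stream_csv(stream: SensorStream, path: str | os.PathLike) -> None:
    """Write a stream in the canonical CSV dialect (deterministic column order).

    Column order is ``timestamp_s``, the nine channels, then ``label``,
    ``subject_id`` and ``episode_id`` when present.  Floats are written with
    shortest round-trip precision, so ``read_stream_csv`` recovers the stream
    exactly.
    """
    data: dict[str, np.ndarray | list] = {TIMESTAMP_COLUMN: stream.timestamps}
    for j, name in enumerate(CHANNELS):
        data[name] = stream.values[:, j]
    if stream.labels is not None:
        data[LABEL_COLUMN] = stream.labels
    if stream.subject_id:
        data[SUBJECT_COLUMN] = [stream.subject_id] * stream.n_samples
    if stream.episode_ids is not None:
        data[EPISODE_COLUMN] = stream.episode_ids
    frame = pd.DataFrame(data)
    try:
        # %.17g guarantees binary64 round-trip through text
        frame.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise UnwritablePathError(f"cannot write {path}: {exc}") from exc


def validate_sampling(stream: SensorStream, jitter_tol: float = 0.010) -> SamplingReport:
    """Check observed sampling intervals against the nominal rate.

    Reports the maximum deviation of any interval from ``1/nominal_rate``
    and the count of intervals whose deviation exceeds ``jitter_tol``
    seconds (default 10 ms, the jitter bound the target hardware meets).
    """
    if stream.n_samples < 2:
        raise EmptyStreamError("need at least 2 samples to validate sampling")
    expected = 1.0 / stream.nominal_rate
    jitter = np.abs(np.diff(stream.timestamps) - expected)
    n_violations = int(np.sum(jitter > jitter_tol))
    return SamplingReport(
        nominal_rate=stream.nominal_rate,
        jitter_tol_s=jitter_tol,
        max_jitter_s=float(jitter.max()),
        n_violations=n_violations,
        n_intervals=int(jitter.size),
        passed=n_violations == 0,
    )
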