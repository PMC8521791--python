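"""Streaming inference: window buffer, prediction timeline, working judge.

The online path mirrors the offline pipeline exactly: every 2 s a feature
vector is computed from the newest basic window and pushed into a small
buffer; once four consecutive (gap-free) vectors are held they are stacked
into a 4xN matrix and classified.  In the default tumbling mode the buffer
then clears, producing one prediction per 8 s — the same non-overlapping
grouping the model was trained on.  A sliding mode (emit on every new
vector once warm) is available for lower latency.

On top of the prediction timeline sits a deliberately simple statistical
judge: the user counts as working at time t when at least a threshold
fraction of the predictions in the trailing horizon fall in {Re, Ty, Wr}.
Nudges fire when cumulative working time since the last qualifying break
reaches a limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyTimelineError, FeatureModeMismatchError
from .features import (
    BASIC_INTERVAL_S,
    ROWS_PER_SAMPLE,
    FeatureMatrix,
    WindowFeatures,
    featurize_stream,
)
from .models import TrainedModel
from .streams import WORKING_CLASSES, SensorStream


@dataclass
class StreamBuffer:
    """Rolling store of recent window feature vectors.

    Emits a 4-row matrix only from gap-free consecutive windows; any gap in
    window start positions resets the buffer.  In tumbling mode each vector
    belongs to at most one emitted matrix.
    """

    n_features: int
    mode: str = "tumbling"  # or "sliding"
    capacity: int = ROWS_PER_SAMPLE
    _held: list[WindowFeatures] = field(default_factory=list)

    def push(self, vector: WindowFeatures) -> FeatureMatrix | None:
        """Add one window's features; return a sample when one completes."""
        if vector.n_features != self.n_features:
            raise FeatureModeMismatchError(
                f"vector has {vector.n_features} features, buffer expects {self.n_features}"
            )
        if self._held:
            prev = self._held[-1]
            contiguous = (
                vector.index == prev.index + 1
                and vector.episode_id == prev.episode_id
                and vector.start_sample > prev.start_sample
            )
            if not contiguous:
                self._held.clear()
        self._held.append(vector)
        if len(self._held) < self.capacity:
            return None
        block = self._held[-self.capacity :]
        matrix = FeatureMatrix(
            values=np.stack([f.vector for f in block]),
            label=block[0].label,
            subject_id=block[0].subject_id,
            episode_id=block[0].episode_id,
        )
        if self.mode == "tumbling":
            self._held.clear()
        else:
            self._held = self._held[-self.capacity :]
        return matrix

    def reset(self) -> None:
        self._held.clear()


@dataclass
class WorkingTimeline:
    """Per-prediction record of the online session."""

    times: np.ndarray  # emission time (end of the 8-s block), seconds
    labels: np.ndarray  # predicted ActivityClass per emission
    working: np.ndarray | None = None  # judge output, filled by judge_working

    def __len__(self) -> int:
        return int(self.times.shape[0])


def stream_predict(
    stream: SensorStream, model: TrainedModel, mode: str = "tumbling"
) -> WorkingTimeline:
    """Replay a stream through the online path and classify every emission.

    Episode metadata on the stream (labels/episode ids) is honoured for
    window alignment, so replaying a recorded session reproduces the batch
    pipeline's predictions exactly; an unlabeled stream is treated as one
    continuous episode.
    """
    cooperativity = model.n_features == 27
    buffer = StreamBuffer(n_features=model.n_features, mode=mode)
    times, labels = [], []
    window_len = BASIC_INTERVAL_S
    for wf in featurize_stream(stream, cooperativity=cooperativity):
        matrix = buffer.push(wf)
        if matrix is not None:
            end_sample = wf.start_sample + int(round(window_len * stream.nominal_rate))
            times.append(end_sample / stream.nominal_rate)
            labels.append(model.predict_label(matrix))
    return WorkingTimeline(
        times=np.asarray(times, dtype=float), labels=np.asarray(labels, dtype=object)
    )


def judge_working(
    timeline: WorkingTimeline, horizon: float = 300.0, theta: float = 0.5
) -> np.ndarray:
    """Boolean working flag per timeline entry.

    The flag at time t is true iff the fraction of predictions in
    ``(t - horizon, t]`` belonging to {Re, Ty, Wr} is >= ``theta``
    (inclusive boundary).  Each flag depends only on predictions at or
    before its own timestamp.
    """
    if len(timeline) == 0:
        raise EmptyTimelineError("timeline holds no predictions")
    is_working = np.isin(timeline.labels.astype(str), WORKING_CLASSES)
    flags = np.zeros(len(timeline), dtype=bool)
    for i, t in enumerate(timeline.times):
        in_horizon = (timeline.times > t - horizon) & (timeline.times <= t)
        frac = float(is_working[in_horizon].mean())
        flags[i] = frac >= theta
    timeline.working = flags
    return flags


def nudge_events(
    times: np.ndarray,
    flags: np.ndarray,
    max_continuous: float = 3600.0,
    break_reset: float = 300.0,
) -> list[float]:
    """Times at which a take-a-break nudge fires.

    Working time accumulates over flagged entries (each entry covers the
    interval since the previous one; the first covers one median step).  A
    contiguous non-working stretch of at least ``break_reset`` seconds
    resets the accumulator, as does each nudge.
    """
    times = np.asarray(times, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if times.shape != flags.shape:
        raise ValueError("times and flags must have equal length")
    if times.size == 0:
        return []
    steps = np.diff(times)
    first = float(np.median(steps)) if steps.size else 0.0
    durations = np.r_[first, steps]

    nudges: list[float] = []
    work_acc = 0.0
    break_acc = 0.0
    for t, flag, dt in zip(times, flags, durations):
        if flag:
            work_acc += dt
            break_acc = 0.0
            if work_acc >= max_continuous:
                nudges.append(float(t))
                work_acc = 0.0
        else:
            break_acc += dt
            if break_acc >= break_reset:
                work_acc = 0.0
    return nudges
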