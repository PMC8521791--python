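"""Window-level statistical and cooperativity features.

The raw 50 Hz stream is cut into non-overlapping 2-s basic windows (100
samples).  For each window three per-channel feature families are computed:

* ``mu`` — the 9 channel means,
* ``sigma`` — the 9 channel sample standard deviations (N-1 denominator),
* ``eps`` — the unit eigenvector of the largest eigenvalue of the 9x9
  pairwise Pearson correlation matrix, a descriptor of how strongly the
  channels move together ("cooperativity").

The window feature vector is the concatenation (eps, mu, sigma) of length 27,
or (mu, sigma) of length 18 with cooperativity disabled.  Four consecutive
same-episode vectors are stacked row-wise into a 4x27 (or 4x18) feature
matrix covering 8 s — one classification sample.  Windows and samples are
tumbling (non-overlapping); trailing remainders are dropped and no window or
sample ever spans an episode boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyClassError, NonFiniteMatrixError, UnlabeledStreamError
from .streams import ACTIVITY_CLASSES, N_CHANNELS, SensorStream

BASIC_INTERVAL_S = 2.0
ROWS_PER_SAMPLE = 4  # 4 x 2 s = 8 s per classification sample


@dataclass(frozen=True)
class BasicWindow:
    """One 2-s block of raw samples (rows = time, columns = channels)."""

    values: np.ndarray
    subject_id: str
    index: int  # sequential window counter within the stream
    start_sample: int  # offset of the first raw sample in the stream
    label: str | None = None
    episode_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError("window values must be (k, 9)")


@dataclass(frozen=True)
class WindowFeatures:
    """Feature vector of one basic window plus bookkeeping."""

    vector: np.ndarray
    subject_id: str
    index: int
    start_sample: int
    label: str | None
    episode_id: int

    @property
    def n_features(self) -> int:
        return int(self.vector.shape[0])


@dataclass(frozen=True)
class FeatureMatrix:
    """One classification sample: 4 consecutive window feature vectors."""

    values: np.ndarray  # (4, n)
    label: str | None
    subject_id: str
    episode_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or self.values.shape[0] != ROWS_PER_SAMPLE:
            raise ValueError(f"feature matrix must have {ROWS_PER_SAMPLE} rows")


@dataclass
class Dataset:
    """Array-backed collection of labeled feature matrices.

    ``X`` is ``(N, 4, n)``; ``labels`` and ``subjects`` are length-``N``
    object arrays.  ``n_features`` is 27 (cooperativity on) or 18 (off).
    """

    X: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    n_features: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).reshape(-1, ROWS_PER_SAMPLE, self.n_features)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)

    def __len__(self) -> int:
        return int(self.X.shape[0])

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in ACTIVITY_CLASSES}

    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(str(s))
        return list(seen)

    def subset(self, mask: np.ndarray) -> "Dataset":
        return Dataset(self.X[mask], self.labels[mask], self.subjects[mask], self.n_features)


def segment_basic_windows(
    stream: SensorStream, basic_interval: float = BASIC_INTERVAL_S
) -> list[BasicWindow]:
    """Cut a stream into consecutive non-overlapping basic windows.

    Windows restart at every episode boundary (``episode_ids`` when present,
    else label runs); trailing partial blocks are dropped.  A stream shorter
    than one window yields an empty list.
    """
    k = int(round(basic_interval * stream.nominal_rate))
    if stream.episode_ids is not None:
        run_ids = stream.episode_ids
    elif stream.labels is not None:
        run_ids = np.cumsum(np.r_[0, stream.labels[1:] != stream.labels[:-1]])
    else:
        run_ids = np.zeros(stream.n_samples, dtype=int)

    windows: list[BasicWindow] = []
    idx = 0
    for run in _run_slices(run_ids):
        start, stop = run
        for ws in range(start, stop - k + 1, k):
            label = str(stream.labels[ws]) if stream.labels is not None else None
            windows.append(
                BasicWindow(
                    values=stream.values[ws : ws + k],
                    subject_id=stream.subject_id,
                    index=idx,
                    start_sample=ws,
                    label=label,
                    episode_id=int(run_ids[ws]),
                )
            )
            idx += 1
    return windows


def _run_slices(run_ids: np.ndarray) -> list[tuple[int, int]]:
    if run_ids.size == 0:
        return []
    change = np.flatnonzero(np.diff(run_ids)) + 1
    bounds = np.r_[0, change, run_ids.size]
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]


def window_stats(window: BasicWindow | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and sample standard deviation (N-1 denominator)."""
    values = window.values if isinstance(window, BasicWindow) else np.asarray(window, float)
    return values.mean(axis=0), values.std(axis=0, ddof=1)


def pearson_correlation_matrix(window: BasicWindow | np.ndarray) -> np.ndarray:
    """9x9 pairwise Pearson correlation matrix of a basic window.

    A zero-variance channel has no defined correlation; its off-diagonal
    entries are set to 0 and its diagonal entry to 1, keeping the matrix
    symmetric with unit trace contribution.
    """
    values = window.values if isinstance(window, BasicWindow) else np.asarray(window, float)
    sd = values.std(axis=0)
    r = np.eye(N_CHANNELS)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(values[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(ok)
        r[np.ix_(idx, idx)] = np.clip(sub, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def max_eigenvector(r: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue of a symmetric matrix.

    The sign is normalized so the component of largest absolute value is
    positive (ties broken toward the lowest index); for degenerate spectra
    the output is the deterministic choice of the symmetric eigensolver
    under that same sign rule.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise NonFiniteMatrixError("correlation matrix contains non-finite entries")
    w, v = np.linalg.eigh(r)
    eps = v[:, -1]
    pivot = int(np.argmax(np.abs(np.round(eps, 12))))
    if eps[pivot] < 0:
        eps = -eps
    return eps


def window_feature_vector(window: BasicWindow, cooperativity: bool = True) -> np.ndarray:
    """Concatenated (eps, mu, sigma) 27-vector, or (mu, sigma) 18-vector."""
    mu, sigma = window_stats(window)
    if not cooperativity:
        return np.concatenate([mu, sigma])
    eps = max_eigenvector(pearson_correlation_matrix(window))
    return np.concatenate([eps, mu, sigma])


def featurize_stream(stream: SensorStream, cooperativity: bool = True) -> list[WindowFeatures]:
    """Segment a stream and compute one feature vector per basic window."""
    return [
        WindowFeatures(
            vector=window_feature_vector(w, cooperativity),
            subject_id=w.subject_id,
            index=w.index,
            start_sample=w.start_sample,
            label=w.label,
            episode_id=w.episode_id,
        )
        for w in segment_basic_windows(stream)
    ]


def assemble_feature_matrices(
    features: list[WindowFeatures], m: int = ROWS_PER_SAMPLE
) -> list[FeatureMatrix]:
    """Stack consecutive groups of ``m`` same-episode vectors into samples.

    Groups are tumbling within each episode; remainders are dropped, and no
    sample ever mixes episodes (hence never mixes labels).
    """
    matrices: list[FeatureMatrix] = []
    by_episode: dict[tuple[str, int], list[WindowFeatures]] = {}
    for f in features:
        by_episode.setdefault((f.subject_id, f.episode_id), []).append(f)
    for (subject_id, episode_id), group in by_episode.items():
        group = sorted(group, key=lambda f: f.index)
        for i in range(0, len(group) - m + 1, m):
            block = group[i : i + m]
            matrices.append(
                FeatureMatrix(
                    values=np.stack([f.vector for f in block]),
                    label=block[0].label,
                    subject_id=subject_id,
                    episode_id=episode_id,
                )
            )
    return matrices


def build_dataset(streams: list[SensorStream], cooperativity: bool = True) -> Dataset:
    """Full offline pipeline: segment, featurize and assemble every stream."""
    n = 27 if cooperativity else 18
    mats: list[FeatureMatrix] = []
    for stream in streams:
        if stream.labels is None:
            raise UnlabeledStreamError(
                f"stream of subject {stream.subject_id!r} has no labels"
            )
        mats.extend(assemble_feature_matrices(featurize_stream(stream, cooperativity)))
    if not mats:
        return Dataset(np.empty((0, ROWS_PER_SAMPLE, n)), np.empty(0, object), np.empty(0, object), n)
    return Dataset(
        np.stack([m.values for m in mats]),
        np.array([m.label for m in mats], dtype=object),
        np.array([m.subject_id for m in mats], dtype=object),
        n,
    )


def class_mean_matrix(dataset: Dataset, label: str) -> np.ndarray:
    """Element-wise mean feature matrix over all samples of one class."""
    mask = dataset.labels == label
    if not mask.any():
        raise EmptyClassError(f"no samples of class {label!r}")
    return dataset.X[mask].mean(axis=0)


def class_mean_distances(dataset: Dataset) -> pd.DataFrame:
    """Pairwise Euclidean distances between flattened class-mean matrices."""
    present = [c for c in ACTIVITY_CLASSES if (dataset.labels == c).any()]
    means = {c: class_mean_matrix(dataset, c).ravel() for c in present}
    out = pd.DataFrame(0.0, index=present, columns=present)
    for a in present:
        for b in present:
            out.loc[a, b] = float(np.linalg.norm(means[a] - means[b]))
    return out


def export_features_csv(features: list[WindowFeatures], path) -> None:
    """One row per basic window: subject, window index, label, f1..fn."""
    if not features:
        pd.DataFrame().to_csv(path, index=False)
        return
    n = features[0].n_features
    rows = {
        "subject_id": [f.subject_id for f in features],
        "window_index": [f.index for f in features],
        "episode_id": [f.episode_id for f in features],
        "label": [f.label for f in features],
    }
    vectors = np.stack([f.vector for f in features])
    for j in range(n):
        rows[f"f{j + 1}"] = vectors[:, j]
    pd.DataFrame(rows).to_csv(path, index=False)
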