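"""Classifiers over 4xN feature matrices: shallow 2D CNN family + baselines.

Three CNN variants share one stack and differ only in depth:

* layer 1 — 2D convolution with a kernel spanning 2 time rows x the full
  feature width (32 filters, stride 1, ReLU).  A two-window kernel gives
  each filter 4 s of context, enough to cover one bout of a hand action;
  the output height is 3.
* layer 2 — kernel of 3 time rows x 1 (32 filters, ReLU), covering the whole
  remaining time extent; output height 1.
* layer 3 — mixes each feature map with its two neighbours (a kernel of 3
  along the map axis, zero-padded, one weight triple per output map, ReLU),
  abstracting groups of three adjacent maps.
* head — flatten, dropout 0.2, dense 64 ReLU, dense 7 softmax.

CNN(1)/CNN(2)/CNN(3) keep the first one/two/three convolutional layers.
Training is cross-entropy with Adam (3e-3), batch 64, at most 100 epochs
with early stopping (patience 5) on a 10% stratified validation split; all
randomness flows from one seed, so training is reproducible.  The network
is small enough that plain NumPy forward/backward passes train it in
seconds on one CPU core.

The SVM (RBF kernel, C = 1.5) and random-forest (200 trees, depth <= 10)
baselines consume the same matrices flattened to 4N vectors via
scikit-learn.  All variants see identical per-feature z-score normalization
computed on the training split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .errors import (
    BadFeatureCountError,
    EmptyDatasetError,
    FeatureModeMismatchError,
    ShapeMismatchError,
    UnknownVariantError,
)
from .features import ROWS_PER_SAMPLE, Dataset, FeatureMatrix
from .streams import ACTIVITY_CLASSES

VARIANTS = ("CNN1", "CNN2", "CNN3", "SVM", "RF")
VALID_FEATURE_COUNTS = (27, 18)


@dataclass(frozen=True)
class ModelConfig:
    """Concrete architecture + training recipe for one variant."""

    variant: str
    n_features: int
    seed: int = 0
    options: dict[str, Any] = field(default_factory=dict)

    @property
    def n_conv_layers(self) -> int:
        return {"CNN1": 1, "CNN2": 2, "CNN3": 3}.get(self.variant, 0)


def build_model_config(variant: str, n_features: int, seed: int = 0, **options) -> ModelConfig:
    """Validate and concretize a model configuration.

    CNN options: ``filters`` (32), ``dense_units`` (64), ``dropout`` (0.2),
    ``lr`` (3e-3), ``batch_size`` (64), ``max_epochs`` (100), ``patience``
    (5), ``val_fraction`` (0.1).  SVM is fixed to an RBF kernel with
    C = 1.5 and the "scale" bandwidth heuristic; RF to 200 trees of depth
    at most 10; both may be overridden explicitly through ``options``.
    """
    if variant not in VARIANTS:
        raise UnknownVariantError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if n_features not in VALID_FEATURE_COUNTS:
        raise BadFeatureCountError(f"n_features must be one of {VALID_FEATURE_COUNTS}")
    defaults: dict[str, Any]
    if variant.startswith("CNN"):
        defaults = dict(
            filters=32, dense_units=64, dropout=0.2, lr=3e-3,
            batch_size=64, max_epochs=100, patience=5, val_fraction=0.1,
        )
    elif variant == "SVM":
        defaults = dict(C=1.5, kernel="rbf", gamma="scale")
    else:  # RF
        defaults = dict(n_estimators=200, max_depth=10)
    defaults.update(options)
    return ModelConfig(variant=variant, n_features=n_features, seed=seed, options=defaults)


# ---------------------------------------------------------------------------
# NumPy shallow CNN
# ---------------------------------------------------------------------------


class _ShallowCNN:
    """Minimal 2D CNN (depth 1-3) with hand-written backprop and Adam."""

    def __init__(self, n_layers: int, n_features: int, n_classes: int, opts: dict, seed: int):
        self.n_layers = n_layers
        self.n_features = n_features
        self.n_classes = n_classes
        self.opts = opts
        self.seed = seed
        f = opts["filters"]
        d = opts["dense_units"]
        rng = np.random.default_rng(seed)
        flat = {1: 3 * f, 2: f, 3: f}[n_layers]
        he = lambda *shape: rng.standard_normal(shape) * np.sqrt(2.0 / np.prod(shape[1:]))
        self.p: dict[str, np.ndarray] = {
            "W1": he(f, 2, n_features), "b1": np.zeros(f),
            "Wd": he(d, flat), "bd": np.zeros(d),
            "Wo": he(n_classes, d), "bo": np.zeros(n_classes),
        }
        if n_layers >= 2:
            self.p["W2"], self.p["b2"] = he(f, 3, f), np.zeros(f)
        if n_layers >= 3:
            self.p["W3"], self.p["b3"] = rng.standard_normal((f, 3)) * np.sqrt(2.0 / 3), np.zeros(f)
        self._rng = rng

    # -- forward -------------------------------------------------------

    def _forward(self, X: np.ndarray, drop_mask: np.ndarray | None = None) -> dict:
        p = self.p
        # sliding 2-row views of the 4-row input: (B, 3, 2, n)
        Xw = np.stack([X[:, t : t + 2, :] for t in range(3)], axis=1)
        z1 = np.einsum("btrc,frc->btf", Xw, p["W1"]) + p["b1"]
        h1 = np.maximum(z1, 0.0)
        cache: dict[str, Any] = {"Xw": Xw, "h1": h1}
        if self.n_layers == 1:
            flat = h1.reshape(len(X), -1)
        else:
            z2 = np.einsum("btc,ftc->bf", h1, p["W2"]) + p["b2"]
            h2 = np.maximum(z2, 0.0)
            cache["h2"] = h2
            if self.n_layers == 2:
                flat = h2
            else:
                F = h2.shape[1]
                hp = np.pad(h2, ((0, 0), (1, 1)))
                z3 = sum(hp[:, d : d + F] * p["W3"][:, d] for d in range(3)) + p["b3"]
                h3 = np.maximum(z3, 0.0)
                cache["hp"], cache["h3"] = hp, h3
                flat = h3
        if drop_mask is not None:
            flat = flat * drop_mask
        cache["flat"] = flat
        a1 = np.maximum(flat @ p["Wd"].T + p["bd"], 0.0)
        logits = a1 @ p["Wo"].T + p["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        cache["a1"], cache["proba"] = a1, expz / expz.sum(axis=1, keepdims=True)
        return cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X)["proba"]

    # -- backward ------------------------------------------------------

    def _gradients(self, X, y_onehot, drop_mask):
        p = self.p
        c = self._forward(X, drop_mask)
        B = len(X)
        g: dict[str, np.ndarray] = {}
        dlogits = (c["proba"] - y_onehot) / B
        g["Wo"] = dlogits.T @ c["a1"]
        g["bo"] = dlogits.sum(axis=0)
        da1 = dlogits @ p["Wo"]
        dz = da1 * (c["a1"] > 0)
        g["Wd"] = dz.T @ c["flat"]
        g["bd"] = dz.sum(axis=0)
        dflat = (dz @ p["Wd"]) * drop_mask

        if self.n_layers == 1:
            dh1 = dflat.reshape(c["h1"].shape)
        else:
            if self.n_layers == 2:
                dh2 = dflat
            else:
                dz3 = dflat * (c["h3"] > 0)
                F = c["h2"].shape[1]
                g["W3"] = np.stack(
                    [(dz3 * c["hp"][:, d : d + F]).sum(axis=0) for d in range(3)], axis=1
                )
                g["b3"] = dz3.sum(axis=0)
                dhp = np.zeros_like(c["hp"])
                for d in range(3):
                    dhp[:, d : d + F] += dz3 * p["W3"][:, d]
                dh2 = dhp[:, 1 : 1 + F]
            dz2 = dh2 * (c["h2"] > 0)
            g["W2"] = np.einsum("bf,btc->ftc", dz2, c["h1"])
            g["b2"] = dz2.sum(axis=0)
            dh1 = np.einsum("bf,ftc->btc", dz2, self.p["W2"])
        dz1 = dh1 * (c["h1"] > 0)
        g["W1"] = np.einsum("btf,btrc->frc", dz1, c["Xw"])
        g["b1"] = dz1.sum(axis=(0, 1))
        loss = -np.mean(np.sum(y_onehot * np.log(c["proba"] + 1e-12), axis=1))
        return loss, g

    # -- training ------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> dict:
        """Train with Adam + early stopping; returns training metadata."""
        opts = self.opts
        rng = self._rng
        n_classes = self.n_classes
        onehot = np.eye(n_classes)[y]

        # stratified validation split
        val_idx: list[int] = []
        for cls in range(n_classes):
            members = np.flatnonzero(y == cls)
            members = members[rng.permutation(len(members))]
            n_val = max(1, int(round(opts["val_fraction"] * len(members)))) if len(members) > 1 else 0
            val_idx.extend(members[:n_val])
        val_mask = np.zeros(len(y), dtype=bool)
        val_mask[val_idx] = True
        Xtr, ytr = X[~val_mask], onehot[~val_mask]
        Xval, yval = X[val_mask], onehot[val_mask]
        if len(Xval) == 0:
            Xval, yval = Xtr, ytr

        m = {k: np.zeros_like(v) for k, v in self.p.items()}
        v = {k: np.zeros_like(va) for k, va in self.p.items()}
        lr, b1, b2, eps = opts["lr"], 0.9, 0.999, 1e-8
        batch, keep = opts["batch_size"], 1.0 - opts["dropout"]
        best_loss, best_params, patience_left = np.inf, None, opts["patience"]
        step = 0
        epochs_run = 0
        for epoch in range(opts["max_epochs"]):
            epochs_run = epoch + 1
            order = rng.permutation(len(Xtr))
            for lo in range(0, len(Xtr), batch):
                idx = order[lo : lo + batch]
                xb, yb = Xtr[idx], ytr[idx]
                flat_dim = self.p["Wd"].shape[1]
                mask = (rng.random((len(xb), flat_dim)) < keep) / keep
                _, g = self._gradients(xb, yb, mask)
                step += 1
                for k in self.p:
                    m[k] = b1 * m[k] + (1 - b1) * g[k]
                    v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.p[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            proba = self.predict_proba(Xval)
            val_loss = -np.mean(np.sum(yval * np.log(proba + 1e-12), axis=1))
            if val_loss < best_loss - 1e-6:
                best_loss, patience_left = val_loss, opts["patience"]
                best_params = {k: va.copy() for k, va in self.p.items()}
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_params is not None:
            self.p = best_params
        return {"epochs": epochs_run, "best_val_loss": float(best_loss)}


# ---------------------------------------------------------------------------
# Unified training/prediction contract
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted classifier with its normalization statistics.

    ``predict_proba`` returns a length-7 probability vector in canonical
    class order; ``predict_label`` is its argmax with ties broken toward
    the earlier class.
    """

    config: ModelConfig
    classes: tuple[str, ...]
    norm_mean: np.ndarray  # (n_features,)
    norm_sd: np.ndarray  # (n_features,)
    impl: Any
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.config.n_features

    def _prepare(self, samples: np.ndarray) -> np.ndarray:
        samples = np.asarray(samples, dtype=float)
        if samples.ndim == 2:
            samples = samples[None]
        if samples.shape[1:] != (ROWS_PER_SAMPLE, self.n_features):
            raise ShapeMismatchError(
                f"expected samples of shape (4, {self.n_features}), got {samples.shape[1:]}"
            )
        return (samples - self.norm_mean) / self.norm_sd

    def predict_proba_batch(self, samples: np.ndarray) -> np.ndarray:
        X = self._prepare(samples)
        if self.config.variant.startswith("CNN"):
            return self.impl.predict_proba(X)
        flat = X.reshape(len(X), -1)
        proba = self.impl.predict_proba(flat)
        # map from the estimator's class order to canonical order
        out = np.zeros((len(X), len(self.classes)))
        for j, cls in enumerate(self.impl.classes_):
            out[:, self.classes.index(cls)] = proba[:, j]
        return out

    def predict_proba(self, sample: FeatureMatrix | np.ndarray) -> np.ndarray:
        values = np.asarray(sample.values if isinstance(sample, FeatureMatrix) else sample, float)
        return self.predict_proba_batch(values[None])[0]

    def predict_label_batch(self, samples: np.ndarray) -> np.ndarray:
        proba = self.predict_proba_batch(samples)
        return np.array([self.classes[i] for i in proba.argmax(axis=1)], dtype=object)

    def predict_label(self, sample: FeatureMatrix | np.ndarray) -> str:
        values = sample.values if isinstance(sample, FeatureMatrix) else np.asarray(sample)
        return str(self.predict_label_batch(values[None])[0])

    def save(self, path) -> None:
        joblib.dump(
            {
                "config": self.config,
                "classes": self.classes,
                "norm_mean": self.norm_mean,
                "norm_sd": self.norm_sd,
                "impl": self.impl,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        d = joblib.load(path)
        return cls(
            config=d["config"], classes=tuple(d["classes"]), norm_mean=d["norm_mean"],
            norm_sd=d["norm_sd"], impl=d["impl"], metadata=d["metadata"],
        )


def train_classifier(config: ModelConfig, dataset: Dataset) -> TrainedModel:
    """Fit one variant on a dataset; deterministic given (config.seed, data).

    Normalization (per-feature z-score over all window rows of the training
    data) is computed here and stored on the model; the dataset itself is
    never mutated.
    """
    if len(dataset) == 0:
        raise EmptyDatasetError("cannot train on an empty dataset")
    if dataset.n_features != config.n_features:
        raise FeatureModeMismatchError(
            f"dataset has {dataset.n_features} features, config expects {config.n_features}"
        )
    classes = tuple(ACTIVITY_CLASSES)
    mean = dataset.X.reshape(-1, dataset.n_features).mean(axis=0)
    sd = dataset.X.reshape(-1, dataset.n_features).std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X = (dataset.X - mean) / sd
    y = np.array([classes.index(l) for l in dataset.labels])

    metadata: dict[str, Any] = {"seed": config.seed, "n_train": len(dataset)}
    if config.variant.startswith("CNN"):
        impl = _ShallowCNN(
            config.n_conv_layers, config.n_features, len(classes), config.options, config.seed
        )
        metadata.update(impl.fit(X, y))
    elif config.variant == "SVM":
        impl = SVC(
            C=config.options["C"], kernel=config.options["kernel"],
            gamma=config.options["gamma"], probability=True, random_state=config.seed,
        )
        with warnings.catch_warnings():
            # native Platt-scaled probabilities are part of the model contract
            warnings.simplefilter("ignore", FutureWarning)
            impl.fit(X.reshape(len(X), -1), dataset.labels.astype(str))
    else:  # RF
        impl = RandomForestClassifier(
            n_estimators=config.options["n_estimators"],
            max_depth=config.options["max_depth"],
            random_state=config.seed,
        )
        impl.fit(X.reshape(len(X), -1), dataset.labels.astype(str))

    return TrainedModel(
        config=config, classes=classes, norm_mean=mean, norm_sd=sd, impl=impl, metadata=metadata
    )
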