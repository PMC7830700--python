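"""Feed-forward motion classifier on 4-channel RMS features.

The recognizer is a small fully connected network, 4 inputs -> 128 ->
32 -> 4 softmax outputs, with ReLU hidden activations, dropout 0.4
after each hidden layer, categorical cross-entropy loss and mini-batch
stochastic gradient descent (batch size 16, learning rate 0.01).  It is
implemented directly in numpy: the network is small enough that a
hand-rolled implementation is both fast and exactly reproducible under
a fixed seed.

Inputs are z-scored per channel with statistics taken from the training
split; the standardization is stored inside the trained model, so
prediction takes raw RMS microvolt features.

A note on the momentum/decay defaults: the reference settings report
momentum 1e-6 and learning-rate decay 0.9, which are transposed
relative to conventional SGD practice (momentum 0.9, decay 1e-6).
Under the reported values the learning rate collapses within the first
epoch (decay follows the common schedule ``lr_t = lr / (1 + decay*t)``
with t the update counter) and the network cannot fit even perfectly
separable data, so :class:`ClassifierConfig` defaults to the
conventional reading; :meth:`ClassifierConfig.reported_sgd` builds the
as-reported variant for comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import InsufficientDataError, InvalidConfigError
from .features import FeatureMatrix
from .motions import MOTION_INDEX, MOTION_ORDER, Motion
from .recording import N_CHANNELS


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyper-parameters of the feed-forward network."""

    hidden_sizes: tuple[int, ...] = (128, 32)
    dropout: float = 0.4
    learning_rate: float = 0.01
    momentum: float = 0.9
    decay: float = 0.000001
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise InvalidConfigError("hidden sizes must be positive")
        for name in ("dropout", "momentum"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1]; got {v}")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise InvalidConfigError("learning_rate, batch_size must be positive")

    @classmethod
    def reported_sgd(cls, **overrides) -> "ClassifierConfig":
        """Variant with the transposed-looking reported settings
        (momentum 1e-6, decay 0.9); undertrains badly, kept for comparison."""
        return cls(**{"momentum": 0.000001, "decay": 0.9, **overrides})


def split_dataset(
    features: FeatureMatrix, train_fraction: float = 0.7, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified-by-class random split into train/test FeatureMatrix pair.

    The two parts are disjoint and their union is the input.  With
    ``train_fraction == 1`` the test part is empty.
    """
    if not features.is_labeled:
        raise InsufficientDataError("split requires labeled features")
    if not 0 < train_fraction <= 1:
        raise InvalidConfigError("train_fraction must be in (0, 1]")
    labels = features.labels
    if train_fraction == 1.0:
        empty = FeatureMatrix(
            np.empty((0, N_CHANNELS)), np.empty(0, dtype="U1"),
            features.window_ms, features.samples_per_window,
        )
        return features, empty
    codes, counts = np.unique(labels, return_counts=True)
    thin = codes[counts < 2]
    if thin.size:
        raise InsufficientDataError(
            f"classes with < 2 windows cannot be split: {', '.join(thin)}"
        )
    idx_train, idx_test = train_test_split(
        np.arange(features.n_windows),
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
    )
    idx_train.sort()
    idx_test.sort()

    def take(idx: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            features.values[idx], labels[idx],
            features.window_ms, features.samples_per_window,
        )

    return take(idx_train), take(idx_test)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedModel:
    """Fitted network parameters plus the preprocessing statistics.

    ``predict_proba`` returns rows on the probability simplex;
    ``predict`` takes the argmax under the canonical class ordering
    (E, R, S, F), so probability ties resolve to the lowest class index.
    """

    config: ClassifierConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    classes: tuple[str, ...] = tuple(m.value for m in MOTION_ORDER)
    train_accuracy: list[float] = field(default_factory=list)

    def _forward(self, x: np.ndarray) -> np.ndarray:
        a = (x - self.feature_mean) / self.feature_std
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _relu(a @ w + b)
        return _softmax(a @ self.weights[-1] + self.biases[-1])

    def predict_proba(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        x = features.values if isinstance(features, FeatureMatrix) else np.atleast_2d(features)
        if x.shape[1] != N_CHANNELS:
            raise InvalidConfigError(
                f"expected {N_CHANNELS}-channel features; got shape {x.shape}"
            )
        return self._forward(np.asarray(x, dtype=float))

    def predict(self, features: FeatureMatrix | np.ndarray) -> list[Motion]:
        probs = self.predict_proba(features)
        return [Motion(self.classes[i]) for i in probs.argmax(axis=1)]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "classes": list(self.classes),
            "train_accuracy": self.train_accuracy,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        return cls(
            config=ClassifierConfig(**cfg),
            weights=[np.asarray(w) for w in payload["weights"]],
            biases=[np.asarray(b) for b in payload["biases"]],
            feature_mean=np.asarray(payload["feature_mean"]),
            feature_std=np.asarray(payload["feature_std"]),
            classes=tuple(payload["classes"]),
            train_accuracy=list(payload["train_accuracy"]),
        )


def train_classifier(
    train: FeatureMatrix, cfg: ClassifierConfig | None = None
) -> TrainedModel:
    """Fit the network on labeled RMS features; deterministic given cfg.seed.

    Weight initialization is He-normal (ReLU-appropriate), seeded from
    the config seed; the same generator drives batch shuffling and
    dropout masks, so training is exactly reproducible.
    """
    cfg = cfg or ClassifierConfig()
    if not train.is_labeled or train.n_windows == 0:
        raise InsufficientDataError("training requires a nonempty labeled FeatureMatrix")
    present = np.unique(train.labels)
    if present.size == 1:
        warnings.warn(
            f"training set contains a single class ({present[0]}); "
            "the fitted model is degenerate",
            stacklevel=2,
        )

    x = np.asarray(train.values, dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    xz = (x - mean) / std
    y = np.array([MOTION_INDEX[Motion(l)] for l in train.labels])
    n, n_classes = x.shape[0], len(MOTION_ORDER)
    onehot = np.eye(n_classes)[y]

    rng = np.random.default_rng(cfg.seed)
    sizes = (N_CHANNELS, *cfg.hidden_sizes, n_classes)
    weights = [
        rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
    ]
    biases = [np.zeros(fan_out) for fan_out in sizes[1:]]
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    keep = 1.0 - cfg.dropout
    n_hidden = len(cfg.hidden_sizes)

    model = TrainedModel(
        config=cfg, weights=weights, biases=biases,
        feature_mean=mean, feature_std=std,
    )

    update = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = xz[idx], onehot[idx]
            m = len(idx)

            # forward with inverted dropout on hidden activations
            acts = [xb]
            masks = []
            a = xb
            for layer in range(n_hidden):
                a = _relu(a @ weights[layer] + biases[layer])
                if keep < 1.0:
                    mask = (rng.random(a.shape) < keep) / keep
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(a)
            probs = _softmax(a @ weights[-1] + biases[-1])

            # backward: cross-entropy + softmax gives (p - y) at the logits
            delta = (probs - yb) / m
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            for layer in range(n_hidden, -1, -1):
                grads_w[layer] = acts[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = delta @ weights[layer].T
                    if masks[layer - 1] is not None:
                        delta = delta * masks[layer - 1]
                    delta = delta * (acts[layer] > 0)

            lr_t = cfg.learning_rate / (1.0 + cfg.decay * update)
            for layer in range(len(weights)):
                vel_w[layer] = cfg.momentum * vel_w[layer] - lr_t * grads_w[layer]
                vel_b[layer] = cfg.momentum * vel_b[layer] - lr_t * grads_b[layer]
                weights[layer] += vel_w[layer]
                biases[layer] += vel_b[layer]
            update += 1

        pred = model.predict_proba(x).argmax(axis=1)
        model.train_accuracy.append(float(np.mean(pred == y)))

    return model


def predict(
    model: TrainedModel, features: FeatureMatrix
) -> tuple[list[Motion], np.ndarray]:
    """Per-window motion labels plus the probability matrix."""
    probs = model.predict_proba(features)
    labels = [Motion(model.classes[i]) for i in probs.argmax(axis=1)]
    return labels, probs
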