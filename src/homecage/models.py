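"""The four injury-state classifiers.

* ``deep`` — a dual-branch network: raw bin sequences pass through two
  Conv1D blocks (conv → batch-norm → ReLU → max-pool) and an LSTM; the CWT
  scaleogram images pass through two Conv2D blocks; both branches are
  concatenated into a dense layer, dropout, and a 3-way softmax. L2
  regularisation is attached to convolutional, LSTM and dense kernels.
* ``ffnn`` — dense → batch-norm → dense → batch-norm → dense(softmax) on the
  4 per-bin mean features.
* ``svm`` — support vector classifier, one-vs-one multi-class scheme, C=1.0.
* ``rf`` — random forest with maximum tree depth 4.

All predictors expose ``fit(inputs, labels, class_weight)``, ``predict`` and
(where meaningful) ``predict_proba`` returning row-stochastic N x 3 matrices.
Unreported hyperparameters (filter counts, LSTM width, dropout, L2, optimiser
settings) are explicit, configurable defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import nn

N_CLASSES = 3


@dataclass
class DeepModelSpec:
    """Hyperparameters of the dual-branch deep network."""

    conv1d: tuple[tuple[int, int], ...] = ((32, 3), (64, 3))  # (filters, kernel)
    lstm_units: int = 64
    conv2d: tuple[tuple[int, tuple[int, int]], ...] = ((16, (3, 3)), (32, (3, 3)))
    dense_units: int = 64
    dropout_rate: float = 0.3
    l2_lambda: float = 1e-3
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv1d) != 2 or len(self.conv2d) != 2:
            raise ValueError("the architecture uses exactly two Conv1D and two Conv2D blocks")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


@dataclass
class FFNNSpec:
    """Hyperparameters of the feed-forward baseline network."""

    hidden: tuple[int, int] = (32, 32)
    l2_lambda: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0


def conv_block_1d(
    n_in: int, filters: int, kernel_size: int, rng: np.random.Generator, l2: float = 0.0
) -> list[nn.Layer]:
    """One temporal convolutional block: conv → batch-norm → ReLU → max-pool(2).

    The pooling halves (floor) the time dimension.
    """
    return [
        nn.Conv1D(n_in, filters, kernel_size, rng, l2=l2),
        nn.BatchNorm(filters),
        nn.ReLU(),
        nn.MaxPool1D(2),
    ]


def conv_block_2d(
    n_in: int, filters: int, kernel_size: tuple[int, int], rng: np.random.Generator,
    l2: float = 0.0,
) -> list[nn.Layer]:
    """One image convolutional block: conv → batch-norm → ReLU → max-pool(2x2)."""
    return [
        nn.Conv2D(n_in, filters, kernel_size, rng, l2=l2),
        nn.BatchNorm(filters),
        nn.ReLU(),
        nn.MaxPool2D(2),
    ]


class _NNClassifier:
    """Shared fit/predict wrapper over a network built by a subclass."""

    network: nn.Layer | nn.DualBranchNet
    _train_rng: np.random.Generator

    def __init__(self, spec):
        self.spec = spec
        self.history: list[float] | None = None

    def fit(self, inputs, labels, class_weight: dict[int, float] | None = None):
        self.history = nn.train(
            self.network,
            inputs,
            labels,
            epochs=self.spec.epochs,
            batch_size=self.spec.batch_size,
            lr=self.spec.learning_rate,
            rng=self._train_rng,
            class_weight=class_weight,
        )
        return self

    def predict_proba(self, inputs) -> np.ndarray:
        return nn.predict_proba(self.network, inputs)

    def predict(self, inputs) -> np.ndarray:
        # ties broken toward the lowest class index (argmax convention)
        return self.predict_proba(inputs).argmax(axis=1)


class DeepClassifier(_NNClassifier):
    """Dual-branch CNN-LSTM consuming (sequence, scaleogram) input pairs."""

    def __init__(self, seq_shape: tuple[int, int], scaleo_shape: tuple[int, int, int],
                 spec: DeepModelSpec | None = None):
        super().__init__(spec or DeepModelSpec())
        spec = self.spec
        init_rng = np.random.default_rng(spec.seed)
        self._train_rng = np.random.default_rng(spec.seed + 1)
        self.seq_shape = tuple(seq_shape)
        self.scaleo_shape = tuple(scaleo_shape)
        lam = spec.l2_lambda

        seq_len, seq_ch = seq_shape
        layers_a: list[nn.Layer] = []
        c_in = seq_ch
        for filters, kernel in spec.conv1d:
            layers_a += conv_block_1d(c_in, filters, kernel, init_rng, l2=lam)
            c_in = filters
        layers_a.append(nn.LSTM(c_in, spec.lstm_units, init_rng, l2=lam))
        branch_a = nn.Sequential(layers_a)

        n_scales, s_len, s_ch = scaleo_shape
        layers_b: list[nn.Layer] = []
        c_in = s_ch
        h, w = n_scales, s_len
        for filters, kernel in spec.conv2d:
            layers_b += conv_block_2d(c_in, filters, kernel, init_rng, l2=lam)
            c_in = filters
            h, w = h // 2, w // 2
        layers_b.append(nn.Flatten())
        branch_b = nn.Sequential(layers_b)

        concat_dim = spec.lstm_units + h * w * c_in
        dropout_rng = np.random.default_rng(spec.seed + 2)
        head = nn.Sequential(
            [
                nn.Dense(concat_dim, spec.dense_units, init_rng, l2=lam),
                nn.ReLU(),
                nn.Dropout(spec.dropout_rate, dropout_rng),
                nn.Dense(spec.dense_units, N_CLASSES, init_rng, l2=lam),
            ]
        )
        self.network = nn.DualBranchNet(branch_a, branch_b, head)

    def fit(self, inputs, labels, class_weight=None):
        seq, scal = inputs
        if seq.shape[1:] != self.seq_shape or scal.shape[1:] != self.scaleo_shape:
            raise ValueError(
                f"input shapes {seq.shape[1:]}/{scal.shape[1:]} do not match the "
                f"declared {self.seq_shape}/{self.scaleo_shape}"
            )
        return super().fit(inputs, labels, class_weight)


class FFNNClassifier(_NNClassifier):
    """Feed-forward baseline on the 4 record features."""

    def __init__(self, input_dim: int = 4, spec: FFNNSpec | None = None):
        super().__init__(spec or FFNNSpec())
        spec = self.spec
        init_rng = np.random.default_rng(spec.seed)
        self._train_rng = np.random.default_rng(spec.seed + 1)
        h1, h2 = spec.hidden
        self.network = nn.Sequential(
            [
                nn.Dense(input_dim, h1, init_rng, l2=spec.l2_lambda),
                nn.BatchNorm(h1),
                nn.ReLU(),
                nn.Dense(h1, h2, init_rng, l2=spec.l2_lambda),
                nn.BatchNorm(h2),
                nn.ReLU(),
                nn.Dense(h2, N_CLASSES, init_rng, l2=spec.l2_lambda),
            ]
        )


def build_deep_model(
    seq_shape: tuple[int, int] = (48, 4),
    scaleo_shape: tuple[int, int, int] = (16, 48, 4),
    spec: DeepModelSpec | None = None,
) -> DeepClassifier:
    """Untrained dual-branch deep model for the given input shapes."""
    return DeepClassifier(seq_shape, scaleo_shape, spec)


def build_ffnn(input_dim: int = 4, spec: FFNNSpec | None = None) -> FFNNClassifier:
    """Untrained feed-forward baseline network."""
    return FFNNClassifier(input_dim, spec)


def train_nn(model: _NNClassifier, inputs, labels, class_weight=None) -> _NNClassifier:
    """Train a network classifier; returns the fitted model.

    Equivalent to ``model.fit`` — provided as the symmetric counterpart of
    the build functions.
    """
    return model.fit(inputs, labels, class_weight=class_weight)


class SklearnClassifier:
    """Adapter giving scikit-learn estimators the package's fit signature."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, inputs, labels, class_weight: dict[int, float] | None = None):
        if class_weight is not None:
            self.estimator.set_params(class_weight=class_weight)
        self.estimator.fit(inputs, labels)
        return self

    def predict(self, inputs) -> np.ndarray:
        return np.asarray(self.estimator.predict(inputs), dtype=int)

    def predict_proba(self, inputs) -> np.ndarray:
        return self.estimator.predict_proba(inputs)


def make_baseline(name: str, seed: int = 0) -> SklearnClassifier:
    """Shallow baselines: ``svm`` (one-vs-one SVC, C=1.0) or ``random_forest``
    (max tree depth 4)."""
    if name == "svm":
        return SklearnClassifier(SVC(C=1.0, decision_function_shape="ovo", random_state=seed))
    if name == "random_forest":
        return SklearnClassifier(RandomForestClassifier(max_depth=4, random_state=seed))
    raise ValueError(f"unknown baseline {name!r}; expected 'svm' or 'random_forest'")
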