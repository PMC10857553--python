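"""Forecaster architectures and the repeat-training/evaluation protocol.

Two model families are registered: a fully connected network (reference
configuration 128/64/32 ReLU hidden layers) and a single-layer GRU. Inputs
are standardized column-wise (the scaler's mean/std travel with the model
into the deployment bundle); the target stays in saturation units, with the
output bias initialized at the training-target mean so optimization starts
from the climatological constant predictor.

The evaluation protocol: split rows at random into 70/15/15
train/validation/test, train until validation MSE stops improving, score on
the held-out test split; repeat with re-randomized partitions and report
the per-metric mean and standard deviation over the repeats, keeping the
weights of the best (lowest-fitness) repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._nn import GRUNet, MLPNet, TrainResult, train_network
from .metrics import FitnessParams, MetricsReport, compute_metrics, fitness
from .windowing import SupervisedDataset, WindowSpec

__all__ = [
    "ModelArchitecture",
    "TrainingProtocol",
    "Scaler",
    "TrainedModel",
    "DEFAULT_ARCHITECTURES",
    "fit_scaler",
    "split_dataset",
    "train_model",
    "evaluate_repeats",
    "persistence_metrics",
]


@dataclass(frozen=True)
class ModelArchitecture:
    """One registered network configuration.

    family: "fcnn" (hidden_spec = dense layer widths) or "gru"
    (hidden_spec = (recurrent units,)).
    """

    family: str
    hidden_spec: tuple[int, ...] = (128, 64, 32)
    activation: str = "relu"
    id: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("fcnn", "gru"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.hidden_spec:
            raise ValueError("hidden_spec must be non-empty")
        if not self.id:
            object.__setattr__(
                self,
                "id",
                f"{self.family}-" + "-".join(str(h) for h in self.hidden_spec),
            )


#: The registered architecture set, one configuration per family.
DEFAULT_ARCHITECTURES: dict[str, tuple[ModelArchitecture, ...]] = {
    "fcnn": (ModelArchitecture("fcnn", (128, 64, 32), "relu"),),
    "gru": (ModelArchitecture("gru", (128,), "tanh"),),
}


@dataclass(frozen=True)
class TrainingProtocol:
    """Split fractions, repeats, early stopping and optimizer settings."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    repeats: int = 10
    early_stop_patience: int = 10
    seed: int = 0
    max_epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class Scaler:
    """Per-input-column standardization (x - mean) / std."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std <= 0):
            raise ValueError("std must be strictly positive")

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.std + self.mean


def fit_scaler(dataset: SupervisedDataset) -> Scaler:
    """Column means/stds of the input columns only (target untouched).

    Zero-variance columns get std 1 (with a warning) so constant signals
    pass through unchanged rather than blowing up.
    """
    if dataset.n_rows < 2:
        raise ValueError("need at least 2 rows to fit a scaler")
    X = dataset.X
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    degenerate = std == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance input column(s); std set to 1",
            stacklevel=2,
        )
        std = np.where(degenerate, 1.0, std)
    return Scaler(mean, std)


def split_dataset(
    dataset: SupervisedDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[SupervisedDataset, SupervisedDataset, SupervisedDataset]:
    """Random disjoint train/validation/test row partition, reproducible."""
    n = dataset.n_rows
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(n * fractions[0])
    n_val = int(n * fractions[1])
    tr, va, te = (
        perm[:n_train],
        perm[n_train : n_train + n_val],
        perm[n_train + n_val :],
    )
    return dataset.subset(tr), dataset.subset(va), dataset.subset(te)


def _reshape_inputs(arch: ModelArchitecture, spec: WindowSpec, X: np.ndarray) -> np.ndarray:
    """fcnn consumes flat rows; gru consumes (n, w, channels).

    Rows store the SpO2 window first, then (optionally) the heart-rate
    window at the same indices; stacking those blocks as channels is a
    lossless reshape of the same data.
    """
    if arch.family == "fcnn":
        return X
    n = X.shape[0]
    c = spec.channel_count
    return X.reshape(n, c, spec.w).transpose(0, 2, 1)


def _make_net(arch: ModelArchitecture, spec: WindowSpec, rng: np.random.Generator):
    if arch.family == "fcnn":
        return MLPNet(spec.input_length, arch.hidden_spec, rng)
    return GRUNet(spec.channel_count, arch.hidden_spec[0], rng)


@dataclass
class TrainedModel:
    """A trained forecaster plus everything needed to run it standalone."""

    architecture: ModelArchitecture
    net: object
    scaler: Scaler
    spec: WindowSpec
    metrics: MetricsReport
    metrics_std: dict[str, float] = field(
        default_factory=lambda: {"mae": 0.0, "mse": 0.0, "mape": 0.0, "max_ae": 0.0}
    )
    train_info: Optional[TrainResult] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict future saturation (original units) from raw input rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = self.scaler.transform(X)
        return self.net.predict(_reshape_inputs(self.architecture, self.spec, Z))

    def evaluate(self, dataset: SupervisedDataset) -> MetricsReport:
        return compute_metrics(dataset.y, self.predict(dataset.X))


def train_model(
    arch: ModelArchitecture,
    dataset: SupervisedDataset,
    protocol: TrainingProtocol = TrainingProtocol(),
) -> TrainedModel:
    """One split / train / test pass; metrics come from the test split."""
    if dataset.spec.input_length != dataset.X.shape[1]:
        raise ValueError("dataset rows incompatible with its window spec")
    ss = np.random.SeedSequence(protocol.seed)
    split_seed, init_seed = ss.generate_state(2)
    train_ds, val_ds, test_ds = split_dataset(dataset, protocol.fractions, int(split_seed))
    scaler = fit_scaler(train_ds)
    rng = np.random.default_rng(int(init_seed))
    net = _make_net(arch, dataset.spec, rng)
    # start from the climatological constant predictor
    net.params[-1][...] = train_ds.y.mean()
    reshape = lambda X: _reshape_inputs(arch, dataset.spec, scaler.transform(X))
    info = train_network(
        net,
        reshape(train_ds.X),
        train_ds.y,
        reshape(val_ds.X),
        val_ds.y,
        rng,
        lr=protocol.learning_rate,
        batch_size=protocol.batch_size,
        max_epochs=protocol.max_epochs,
        patience=protocol.early_stop_patience,
    )
    model = TrainedModel(arch, net, scaler, dataset.spec, None, train_info=info)  # type: ignore[arg-type]
    model.metrics = model.evaluate(test_ds)
    return model


def evaluate_repeats(
    arch: ModelArchitecture,
    dataset: SupervisedDataset,
    protocol: TrainingProtocol = TrainingProtocol(),
    params: FitnessParams = FitnessParams(),
) -> TrainedModel:
    """Repeat train/test with re-randomized partitions; aggregate metrics.

    Returns the weights of the lowest-fitness repeat, carrying the
    per-metric mean over repeats as ``metrics`` and the per-metric standard
    deviation as ``metrics_std``.
    """
    seeds = np.random.SeedSequence(protocol.seed).generate_state(protocol.repeats)
    reports: list[MetricsReport] = []
    best: Optional[TrainedModel] = None
    best_fit = np.inf
    for rep_seed in seeds:
        rep_protocol = TrainingProtocol(
            fractions=protocol.fractions,
            repeats=1,
            early_stop_patience=protocol.early_stop_patience,
            seed=int(rep_seed) % (2**31),
            max_epochs=protocol.max_epochs,
            batch_size=protocol.batch_size,
            learning_rate=protocol.learning_rate,
        )
        model = train_model(arch, dataset, rep_protocol)
        reports.append(model.metrics)
        f = fitness(model.metrics, params)
        if f < best_fit:
            best_fit = f
            best = model
    assert best is not None
    names = ("mae", "mse", "mape", "max_ae")
    values = {k: np.array([getattr(r, k) for r in reports]) for k in names}
    mean_report = MetricsReport(
        mae=float(values["mae"].mean()),
        mse=float(values["mse"].mean()),
        mape=float(values["mape"].mean()),
        max_ae=float(values["max_ae"].mean()),
        n=int(np.mean([r.n for r in reports])),
    )
    best.metrics = mean_report
    best.metrics_std = {k: float(values[k].std()) for k in names}
    return best


def persistence_metrics(dataset: SupervisedDataset) -> MetricsReport:
    """Errors of the naive forecaster that predicts the last window value."""
    last_col = dataset.spec.w - 1  # last SpO2 input column
    return compute_metrics(dataset.y, dataset.X[:, last_col])
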