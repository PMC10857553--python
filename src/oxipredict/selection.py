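"""Grid model selection and edge-deployable bundle export.

Every registered architecture of every learning algorithm is trained on
every candidate dataset (|A|·|D| cells). Within each algorithm the cell
with the lowest composite fitness (mean over training repeats, scored on
held-out data) is kept; the per-algorithm winners are then re-scored on
their *entire* datasets and the overall minimum becomes the deployed
model. Ties break to the earlier cell in iteration order (algorithms, then
architectures, then datasets as listed), matching a strict less-than
comparison.

A deployment bundle is a directory with ``model.json`` (architecture +
weights) and ``config.json`` (window spec, input length, scaler mean/std)
— everything a streaming edge client needs to run the model without the
training environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._nn import GRUNet, MLPNet
from .metrics import FitnessParams, MetricsReport, compute_metrics, fitness
from .modeling import (
    DEFAULT_ARCHITECTURES,
    ModelArchitecture,
    Scaler,
    TrainedModel,
    TrainingProtocol,
    evaluate_repeats,
)
from .windowing import SupervisedDataset, WindowSpec

__all__ = [
    "GridCell",
    "SelectionResult",
    "BundleSchemaError",
    "select_best",
    "finalize",
    "export_bundle",
    "load_bundle",
    "cells_to_frame",
    "write_report",
]


class BundleSchemaError(ValueError):
    """A deployment bundle's config is missing a required field."""


@dataclass
class GridCell:
    """One evaluated (algorithm, architecture, dataset) grid cell."""

    algorithm: str
    arch_id: str
    spec: WindowSpec
    n_rows: int
    metrics: MetricsReport
    fitness: float
    model: TrainedModel


@dataclass
class SelectionResult:
    """Per-algorithm winners and, after finalize, the overall best."""

    per_algorithm: dict[str, GridCell]
    cells: list[GridCell] = field(default_factory=list)
    overall_best: Optional[GridCell] = None
    overall_full_fitness: dict[str, float] = field(default_factory=dict)


def select_best(
    datasets: Sequence[SupervisedDataset],
    algorithms: Sequence[str] = ("fcnn", "gru"),
    architectures: Optional[dict[str, Sequence[ModelArchitecture]]] = None,
    params: FitnessParams = FitnessParams(),
    protocol: TrainingProtocol = TrainingProtocol(),
) -> SelectionResult:
    """Exhaustively evaluate the grid; track the per-algorithm minimum."""
    if not datasets or not algorithms:
        raise ValueError("datasets and algorithms must be non-empty")
    architectures = architectures or DEFAULT_ARCHITECTURES
    result = SelectionResult(per_algorithm={})
    cell_seed = np.random.SeedSequence(protocol.seed)
    cell_index = 0
    for algo in algorithms:
        archs = architectures.get(algo)
        if not archs:
            raise ValueError(f"no architectures registered for algorithm {algo!r}")
        best: Optional[GridCell] = None
        for arch in archs:
            for ds in datasets:
                cell_protocol = TrainingProtocol(
                    fractions=protocol.fractions,
                    repeats=protocol.repeats,
                    early_stop_patience=protocol.early_stop_patience,
                    seed=int(cell_seed.generate_state(cell_index + 1)[-1]) % (2**31),
                    max_epochs=protocol.max_epochs,
                    batch_size=protocol.batch_size,
                    learning_rate=protocol.learning_rate,
                )
                cell_index += 1
                model = evaluate_repeats(arch, ds, cell_protocol, params)
                cell = GridCell(
                    algorithm=algo,
                    arch_id=arch.id,
                    spec=ds.spec,
                    n_rows=ds.n_rows,
                    metrics=model.metrics,
                    fitness=fitness(model.metrics, params),
                    model=model,
                )
                result.cells.append(cell)
                if best is None or cell.fitness < best.fitness:
                    best = cell
        assert best is not None
        result.per_algorithm[algo] = best
    return result


def finalize(
    result: SelectionResult,
    datasets: Sequence[SupervisedDataset],
    params: FitnessParams = FitnessParams(),
) -> GridCell:
    """Re-score each per-algorithm winner on its full dataset; pick the min."""
    by_spec = {ds.spec: ds for ds in datasets}
    best: Optional[GridCell] = None
    for algo, cell in result.per_algorithm.items():
        ds = by_spec[cell.spec]
        full = compute_metrics(ds.y, cell.model.predict(ds.X))
        f = fitness(full, params)
        result.overall_full_fitness[algo] = f
        if best is None or f < best.fitness:
            best = GridCell(
                algorithm=cell.algorithm,
                arch_id=cell.arch_id,
                spec=cell.spec,
                n_rows=ds.n_rows,
                metrics=full,
                fitness=f,
                model=cell.model,
            )
    assert best is not None
    result.overall_best = best
    return best


# --- deployment bundles ----------------------------------------------------

_CONFIG_FIELDS = ("model_id", "algorithm", "w", "s", "f", "channels", "input_length")


def export_bundle(model: TrainedModel, out_dir: Union[str, Path]) -> Path:
    """Write ``model.json`` + ``config.json`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arch = model.architecture
    weights = [p.tolist() for p in model.net.params]
    (out_dir / "model.json").write_text(
        json.dumps(
            {
                "family": arch.family,
                "hidden_spec": list(arch.hidden_spec),
                "activation": arch.activation,
                "weights": weights,
            }
        )
    )
    config = {
        "model_id": arch.id,
        "algorithm": arch.family,
        "w": model.spec.w,
        "s": model.spec.s,
        "f": model.spec.f,
        "channels": model.spec.channels,
        "input_length": model.spec.input_length,
        "scaler": {
            "mean": model.scaler.mean.tolist(),
            "std": model.scaler.std.tolist(),
        },
    }
    (out_dir / "config.json").write_text(json.dumps(config, indent=2))
    return out_dir


def load_bundle(bundle_dir: Union[str, Path]) -> TrainedModel:
    """Load a bundle into a streaming-ready predictor.

    Raises :class:`BundleSchemaError` naming the first missing config field.
    """
    bundle_dir = Path(bundle_dir)
    config = json.loads((bundle_dir / "config.json").read_text())
    for key in _CONFIG_FIELDS:
        if key not in config:
            raise BundleSchemaError(f"config.json missing required field {key!r}")
    if "scaler" not in config:
        raise BundleSchemaError("config.json missing required field 'scaler'")
    for key in ("mean", "std"):
        if key not in config["scaler"]:
            raise BundleSchemaError(f"config.json missing required field {key!r}")
    spec = WindowSpec(config["w"], config["s"], config["f"], config["channels"])
    if config["input_length"] != spec.input_length:
        raise BundleSchemaError(
            f"input_length {config['input_length']} inconsistent with "
            f"w={spec.w} x {spec.channel_count} channel(s)"
        )
    raw = json.loads((bundle_dir / "model.json").read_text())
    arch = ModelArchitecture(
        raw["family"], tuple(raw["hidden_spec"]), raw["activation"], config["model_id"]
    )
    rng = np.random.default_rng(0)
    if arch.family == "fcnn":
        net = MLPNet(spec.input_length, arch.hidden_spec, rng)
    else:
        net = GRUNet(spec.channel_count, arch.hidden_spec[0], rng)
    stored = [np.asarray(w, dtype=float) for w in raw["weights"]]
    if len(stored) != len(net.params) or any(
        s.shape != p.shape for s, p in zip(stored, net.params)
    ):
        raise BundleSchemaError("model.json weights inconsistent with architecture")
    net.params = stored
    scaler = Scaler(
        np.asarray(config["scaler"]["mean"], dtype=float),
        np.asarray(config["scaler"]["std"], dtype=float),
    )
    placeholder = MetricsReport(0.0, 0.0, 0.0, 0.0, 1)
    return TrainedModel(arch, net, scaler, spec, placeholder)


# --- reporting -------------------------------------------------------------


def cells_to_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    """Grid cells as a table shaped like the per-patient result tables."""
    return pd.DataFrame(
        {
            "algorithm": [c.algorithm for c in cells],
            "arch": [c.arch_id for c in cells],
            "w": [c.spec.w for c in cells],
            "s": [c.spec.s for c in cells],
            "f": [c.spec.f for c in cells],
            "Data": [c.n_rows for c in cells],
            "MAE": [round(c.metrics.mae, 2) for c in cells],
            "MSE": [round(c.metrics.mse, 2) for c in cells],
            "MAPE": [round(c.metrics.mape, 2) for c in cells],
            "Max": [round(c.metrics.max_ae, 2) for c in cells],
            "Fit": [round(c.fitness, 2) for c in cells],
        }
    )


def write_report(cells: Sequence[GridCell], path: Union[str, Path]) -> None:
    cells_to_frame(cells).to_csv(path, index=False)
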