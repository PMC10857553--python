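"""Sliding-window supervised dataset construction.

Each continuous run of 1 Hz readings is turned into rows of a regression
dataset: ``w`` past values taken at stride ``s`` form the inputs, and the
saturation ``s*w + f`` points after the window's start index is the target
(one extra stride beyond the last input point, plus the horizon ``f``).
With 1-based position ``i`` inside a run ``x``:

    inputs:  x[i + s*(j-1)]  for j = 1..w
    target:  x[i + s*w + f]

valid for i = 1..(n - s*w - f), so a run of length ``n`` contributes
``max(0, n - s*w - f)`` rows and runs shorter than the window contribute
none. Windows never straddle a gap: rows are built per continuous segment
and concatenated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .vitals_io import (
    DEFAULT_MAX_GAP,
    ContinuousSegment,
    VitalTrace,
    segment_continuous,
)

__all__ = [
    "WindowSpec",
    "SupervisedDataset",
    "DEFAULT_GRID",
    "row_count",
    "build_rows",
    "build_dataset",
    "dataset_grid",
    "save_dataset",
    "load_dataset",
]

CHANNELS = ("spo2", "spo2_hr")


@dataclass(frozen=True)
class WindowSpec:
    """The (w, s, f) tuple characterizing one dataset shape.

    w: window size in data points; s: stride in elements; f: prediction
    horizon in data points (seconds at 1 Hz). ``channels`` selects SpO2-only
    input or SpO2 plus heart rate.
    """

    w: int
    s: int
    f: int
    channels: str = "spo2"

    def __post_init__(self) -> None:
        for name in ("w", "s", "f"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.channels not in CHANNELS:
            raise ValueError(f"channels must be one of {CHANNELS}, got {self.channels!r}")

    @property
    def channel_count(self) -> int:
        return 2 if self.channels == "spo2_hr" else 1

    @property
    def input_length(self) -> int:
        return self.w * self.channel_count

    @property
    def span(self) -> int:
        """Points consumed by one (window, target) pair: s*w + f."""
        return self.s * self.w + self.f

    def label(self) -> str:
        return f"w{self.w}_s{self.s}_f{self.f}_{self.channels}"


#: The five dataset configurations of the default evaluation grid.
DEFAULT_GRID: tuple[WindowSpec, ...] = (
    WindowSpec(20, 10, 20),
    WindowSpec(20, 10, 30),
    WindowSpec(20, 10, 40),
    WindowSpec(20, 5, 20),
    WindowSpec(10, 10, 20),
)


@dataclass
class SupervisedDataset:
    """Rows of ``w * channel_count`` input columns plus one target column.

    For two-channel input the SpO2 window columns come first, then the heart
    rate values at the same indices; the target is always future SpO2.
    """

    rows: np.ndarray
    spec: WindowSpec

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        expected = self.spec.input_length + 1
        if self.rows.ndim != 2 or self.rows.shape[1] != expected:
            raise ValueError(
                f"rows must have {expected} columns for {self.spec}, "
                f"got shape {self.rows.shape}"
            )

    @property
    def n_rows(self) -> int:
        return int(self.rows.shape[0])

    @property
    def X(self) -> np.ndarray:
        return self.rows[:, :-1]

    @property
    def y(self) -> np.ndarray:
        return self.rows[:, -1]

    def subset(self, idx: np.ndarray) -> "SupervisedDataset":
        return SupervisedDataset(self.rows[idx], self.spec)


def row_count(n: int, spec: WindowSpec) -> int:
    """Number of supervised rows a continuous run of ``n`` points yields.

    Depends on the spec only through ``s*w + f``, so e.g. (w=20,s=5,f=20)
    and (w=10,s=10,f=20) always produce identical counts.
    """
    if n < 0:
        raise ValueError("segment length must be non-negative")
    return max(0, n - spec.span)


def build_rows(segment: ContinuousSegment, spec: WindowSpec) -> np.ndarray:
    """Enumerate all supervised rows of one continuous segment (vectorized)."""
    n = len(segment)
    m = row_count(n, spec)
    if m == 0 or n < spec.w:
        return np.empty((0, spec.input_length + 1))
    starts = np.arange(m)[:, None]
    in_idx = starts + spec.s * np.arange(spec.w)[None, :]
    tgt_idx = np.arange(m) + spec.s * spec.w + spec.f
    cols = [segment.spo2[in_idx]]
    if spec.channels == "spo2_hr":
        if segment.hr is None or np.isnan(segment.hr).any():
            raise ValueError("spec requires heart-rate channel but segment lacks hr")
        cols.append(segment.hr[in_idx])
    cols.append(segment.spo2[tgt_idx][:, None])
    return np.hstack(cols)


def build_dataset(
    trace: VitalTrace,
    spec: WindowSpec,
    max_gap: float = DEFAULT_MAX_GAP,
) -> SupervisedDataset:
    """Segment a trace at gaps > ``max_gap`` and window every segment."""
    parts = [build_rows(seg, spec) for seg in segment_continuous(trace, max_gap)]
    if parts:
        rows = np.vstack(parts)
    else:
        rows = np.empty((0, spec.input_length + 1))
    return SupervisedDataset(rows, spec)


def dataset_grid(
    trace: VitalTrace,
    specs: Sequence[WindowSpec] = DEFAULT_GRID,
    max_gap: float = DEFAULT_MAX_GAP,
) -> list[SupervisedDataset]:
    """One dataset per spec, in the given order (the set of <D, w, s, f>)."""
    if not specs:
        raise ValueError("specs must be non-empty")
    return [build_dataset(trace, spec, max_gap) for spec in specs]


def save_dataset(ds: SupervisedDataset, path: Union[str, Path]) -> None:
    """Persist as CSV ``x1..xk,y`` plus a JSON sidecar with the spec."""
    path = Path(path)
    k = ds.spec.input_length
    cols = [f"x{i + 1}" for i in range(k)] + ["y"]
    pd.DataFrame(ds.rows, columns=cols).to_csv(path, index=False)
    meta = {
        "w": ds.spec.w,
        "s": ds.spec.s,
        "f": ds.spec.f,
        "channels": ds.spec.channels,
        "n_rows": ds.n_rows,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_dataset(path: Union[str, Path]) -> SupervisedDataset:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = WindowSpec(meta["w"], meta["s"], meta["f"], meta["channels"])
    df = pd.read_csv(path)
    return SupervisedDataset(df.to_numpy(float), spec)
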