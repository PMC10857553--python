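"""Reading, writing and gap-segmentation of raw pulse-oximetry traces.

A trace is a timestamped sequence of SpO2 (percent) and heart-rate (bpm)
readings sampled nominally at 1 Hz. Consumer pulse oximeters discard readings
whose signal quality is untrusted, so real traces contain timestamp gaps.
Downstream supervised windowing only ever operates on *continuous* runs:
maximal stretches in which consecutive timestamps differ by at most
``max_gap`` seconds (3 s by default — within that interval saturation does
not change appreciably and the run is treated as continuous).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

DEFAULT_MAX_GAP = 3.0

__all__ = [
    "DEFAULT_MAX_GAP",
    "VitalSample",
    "VitalTrace",
    "ContinuousSegment",
    "TraceParseError",
    "TraceValidationError",
    "read_trace",
    "write_trace",
    "write_bundle",
    "segment_continuous",
]


class TraceParseError(ValueError):
    """A row of an on-disk trace could not be parsed."""


class TraceValidationError(ValueError):
    """A trace violates a sample- or sequence-level invariant."""


@dataclass(frozen=True)
class VitalSample:
    """One pulse-oximeter reading.

    Attributes
    ----------
    timestamp : float
        Seconds since epoch (or since recording start); non-negative.
    spo2 : float
        Oxygen saturation in percent, within [0, 100].
    hr : float, optional
        Heart rate in beats per minute, within (0, 300) when present.
    prediction : float, optional
        A forecast saturation attached to this reading (present only in
        uploaded edge bundles).
    """

    timestamp: float
    spo2: float
    hr: Optional[float] = None
    prediction: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.timestamp) or self.timestamp < 0:
            raise TraceValidationError(
                f"timestamp must be finite and non-negative, got {self.timestamp!r}"
            )
        if not math.isfinite(self.spo2) or not (0.0 <= self.spo2 <= 100.0):
            raise TraceValidationError(
                f"spo2 must lie in [0, 100], got {self.spo2!r}"
            )
        if self.hr is not None and not (0.0 < self.hr < 300.0):
            raise TraceValidationError(
                f"hr must lie in (0, 300) when present, got {self.hr!r}"
            )


class _SampleRun:
    """Shared behaviour for ordered sample containers backed by arrays."""

    timestamps: np.ndarray
    spo2: np.ndarray
    hr: Optional[np.ndarray]
    predictions: Optional[np.ndarray]

    def __len__(self) -> int:
        return int(self.timestamps.shape[0])

    def __getitem__(self, i: int) -> VitalSample:
        hr = None if self.hr is None or np.isnan(self.hr[i]) else float(self.hr[i])
        pred = (
            None
            if self.predictions is None or np.isnan(self.predictions[i])
            else float(self.predictions[i])
        )
        return VitalSample(float(self.timestamps[i]), float(self.spo2[i]), hr, pred)

    @property
    def samples(self) -> Iterator[VitalSample]:
        for i in range(len(self)):
            yield self[i]

    @property
    def has_hr(self) -> bool:
        return self.hr is not None and not np.isnan(self.hr).any()


def _as_arrays(
    samples: Sequence[VitalSample],
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray], Optional[np.ndarray]]:
    ts = np.asarray([s.timestamp for s in samples], dtype=float)
    sp = np.asarray([s.spo2 for s in samples], dtype=float)
    hr_vals = [s.hr for s in samples]
    pr_vals = [s.prediction for s in samples]
    hr = (
        np.asarray([np.nan if v is None else v for v in hr_vals], dtype=float)
        if any(v is not None for v in hr_vals)
        else None
    )
    pr = (
        np.asarray([np.nan if v is None else v for v in pr_vals], dtype=float)
        if any(v is not None for v in pr_vals)
        else None
    )
    return ts, sp, hr, pr


@dataclass
class VitalTrace(_SampleRun):
    """An ordered, strictly-increasing-timestamp sequence of readings."""

    timestamps: np.ndarray
    spo2: np.ndarray
    hr: Optional[np.ndarray] = None
    predictions: Optional[np.ndarray] = None
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        if self.hr is not None:
            self.hr = np.asarray(self.hr, dtype=float)
        if self.predictions is not None:
            self.predictions = np.asarray(self.predictions, dtype=float)
        _validate_arrays(self)

    @classmethod
    def from_samples(
        cls, samples: Sequence[VitalSample], patient_id: str = ""
    ) -> "VitalTrace":
        ts, sp, hr, pr = _as_arrays(samples)
        return cls(ts, sp, hr, pr, patient_id)

    def equals(self, other: "VitalTrace") -> bool:
        def _eq(a, b):
            if a is None and b is None:
                return True
            if a is None or b is None:
                return False
            return np.allclose(a, b, equal_nan=True)

        return (
            np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.spo2, other.spo2)
            and _eq(self.hr, other.hr)
            and _eq(self.predictions, other.predictions)
        )


@dataclass
class ContinuousSegment(_SampleRun):
    """A maximal run with consecutive timestamp gaps <= max_gap; non-empty."""

    timestamps: np.ndarray
    spo2: np.ndarray
    hr: Optional[np.ndarray] = None
    predictions: Optional[np.ndarray] = None
    max_gap: float = DEFAULT_MAX_GAP

    def __post_init__(self) -> None:
        if len(self.timestamps) == 0:
            raise TraceValidationError("a continuous segment must be non-empty")
        gaps = np.diff(self.timestamps)
        if gaps.size and gaps.max() > self.max_gap:
            raise TraceValidationError(
                f"segment contains a gap of {gaps.max():g} s > max_gap={self.max_gap:g} s"
            )


def _validate_arrays(trace: VitalTrace) -> None:
    ts, sp = trace.timestamps, trace.spo2
    if ts.shape != sp.shape:
        raise TraceValidationError("timestamp and spo2 arrays differ in length")
    if len(ts) == 0:
        return
    if not np.all(np.isfinite(ts)) or ts[0] < 0:
        raise TraceValidationError("timestamps must be finite and non-negative")
    d = np.diff(ts)
    if d.size and not np.all(d > 0):
        i = int(np.argmax(d <= 0))
        raise TraceValidationError(
            f"timestamps must be strictly increasing; violation after index {i} "
            f"(t={ts[i]:g} followed by t={ts[i + 1]:g})"
        )
    bad = ~((sp >= 0) & (sp <= 100) & np.isfinite(sp))
    if bad.any():
        i = int(np.argmax(bad))
        raise TraceValidationError(
            f"spo2 out of [0, 100] at index {i}: {sp[i]!r}"
        )
    if trace.hr is not None:
        h = trace.hr
        known = ~np.isnan(h)
        if np.any(known & ~((h > 0) & (h < 300))):
            i = int(np.argmax(known & ~((h > 0) & (h < 300))))
            raise TraceValidationError(f"hr out of (0, 300) at index {i}: {h[i]!r}")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jsonl"):
            raise ValueError(f"format must be 'csv' or 'jsonl', got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    return "csv"


def read_trace(
    path: Union[str, Path],
    format: Optional[str] = None,
    patient_id: str = "",
) -> VitalTrace:
    """Read a trace from CSV (``timestamp,spo2[,hr]``) or JSONL.

    Rows must be sorted by strictly increasing timestamp; duplicates are
    rejected. Malformed rows raise :class:`TraceParseError` naming the line.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return VitalTrace(np.empty(0), np.empty(0), patient_id=patient_id)
        for col in ("timestamp", "spo2"):
            if col not in df.columns:
                raise TraceParseError(f"{path}: missing required column {col!r}")
        for col in ("timestamp", "spo2", "hr", "prediction"):
            if col in df.columns:
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    line = int(bad.idxmax()) + 2  # header is line 1
                    raise TraceParseError(
                        f"{path}: malformed value in column {col!r} on line {line}"
                    )
                df[col] = coerced
        hr = df["hr"].to_numpy(float) if "hr" in df.columns else None
        pred = df["prediction"].to_numpy(float) if "prediction" in df.columns else None
        return VitalTrace(
            df["timestamp"].to_numpy(float),
            df["spo2"].to_numpy(float),
            hr,
            pred,
            patient_id,
        )
    # jsonl
    ts, sp, hr_l, pr_l = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TraceParseError(f"{path}: invalid JSON on line {lineno}: {exc}") from exc
            if "timestamp" not in rec or "spo2" not in rec:
                raise TraceParseError(
                    f"{path}: record on line {lineno} lacks timestamp/spo2"
                )
            ts.append(float(rec["timestamp"]))
            sp.append(float(rec["spo2"]))
            hr_l.append(float(rec["hr"]) if rec.get("hr") is not None else np.nan)
            pr_l.append(
                float(rec["prediction"]) if rec.get("prediction") is not None else np.nan
            )
    hr_a = np.asarray(hr_l) if ts and not np.isnan(hr_l).all() else None
    pr_a = np.asarray(pr_l) if ts and not np.isnan(pr_l).all() else None
    return VitalTrace(np.asarray(ts), np.asarray(sp), hr_a, pr_a, patient_id)


def write_trace(trace: VitalTrace, path: Union[str, Path]) -> None:
    """Write a trace as CSV with header ``timestamp,spo2[,hr][,prediction]``."""
    cols = {"timestamp": trace.timestamps, "spo2": trace.spo2}
    if trace.hr is not None:
        cols["hr"] = trace.hr
    if trace.predictions is not None:
        cols["prediction"] = trace.predictions
    pd.DataFrame(cols).to_csv(path, index=False)


def write_bundle(trace: VitalTrace, path: Union[str, Path]) -> None:
    """Write a trace as a JSONL data bundle, one record per reading.

    Each record carries ``timestamp``, ``spo2`` and, when present, ``hr`` and
    the computed ``prediction``; absent fields are omitted rather than null.
    ``read_trace(path, format="jsonl")`` reproduces the trace exactly.
    """
    with open(path, "w") as fh:
        for i in range(len(trace)):
            rec: dict = {
                "timestamp": float(trace.timestamps[i]),
                "spo2": float(trace.spo2[i]),
            }
            if trace.hr is not None and not np.isnan(trace.hr[i]):
                rec["hr"] = float(trace.hr[i])
            if trace.predictions is not None and not np.isnan(trace.predictions[i]):
                rec["prediction"] = float(trace.predictions[i])
            fh.write(json.dumps(rec) + "\n")


def segment_continuous(
    trace: VitalTrace, max_gap: float = DEFAULT_MAX_GAP
) -> list[ContinuousSegment]:
    """Split a trace into maximal continuous runs.

    A boundary is placed exactly where a consecutive timestamp difference
    exceeds ``max_gap``; a difference of exactly ``max_gap`` keeps the run
    continuous. The segments partition the trace in order.
    """
    n = len(trace)
    if n == 0:
        return []
    gaps = np.diff(trace.timestamps)
    cut = np.flatnonzero(gaps > max_gap) + 1
    bounds = np.concatenate(([0], cut, [n]))
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        out.append(
            ContinuousSegment(
                trace.timestamps[a:b],
                trace.spo2[a:b],
                None if trace.hr is None else trace.hr[a:b],
                None if trace.predictions is None else trace.predictions[a:b],
                max_gap,
            )
        )
    return out
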