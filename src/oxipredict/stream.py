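"""Streaming edge inference: one forecast per incoming reading.

Mirrors the on-device loop: a rolling buffer of the current continuous run
feeds the deployed model each time a new reading arrives. The buffer spans
``s*(w-1)+1`` consecutive samples; the model consumes every ``s``-th value
from its oldest end (the same stride-``s`` indices the training windows
used) and forecasts the saturation ``s+f`` seconds after the newest
reading — the training target sits ``s*w+f`` points after the window's
start, i.e. ``s+f`` after its last input. A timestamp gap over 3 s empties
the buffer: no forecast ever mixes samples from both sides of a gap.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from .modeling import TrainedModel
from .vitals_io import DEFAULT_MAX_GAP, VitalSample, VitalTrace

__all__ = ["Prediction", "StreamState", "replay"]


@dataclass(frozen=True)
class Prediction:
    """A forecast saturation and the future timestamp it refers to."""

    value: float
    for_timestamp: float


class StreamState:
    """Rolling-buffer forecaster around a loaded deployment bundle."""

    def __init__(self, bundle: TrainedModel, max_gap: float = DEFAULT_MAX_GAP):
        self.bundle = bundle
        self.max_gap = max_gap
        spec = bundle.spec
        self.buffer_span = spec.s * (spec.w - 1) + 1
        self._spo2: deque[float] = deque(maxlen=self.buffer_span)
        self._hr: deque[float] = deque(maxlen=self.buffer_span)
        self.last_timestamp: float | None = None

    def push(self, sample: VitalSample) -> Prediction | None:
        """Ingest one reading; emit a forecast once the buffer is full."""
        if self.last_timestamp is not None and sample.timestamp <= self.last_timestamp:
            raise ValueError(
                f"non-increasing timestamp {sample.timestamp:g} "
                f"(last seen {self.last_timestamp:g})"
            )
        needs_hr = self.bundle.spec.channels == "spo2_hr"
        if needs_hr and sample.hr is None:
            warnings.warn(
                f"sample at t={sample.timestamp:g} lacks heart rate required by "
                "the model; reading skipped",
                stacklevel=2,
            )
            return None
        if (
            self.last_timestamp is not None
            and sample.timestamp - self.last_timestamp > self.max_gap
        ):
            self._spo2.clear()
            self._hr.clear()
        self.last_timestamp = sample.timestamp
        self._spo2.append(sample.spo2)
        self._hr.append(sample.hr if sample.hr is not None else np.nan)
        if len(self._spo2) < self.buffer_span:
            return None
        spec = self.bundle.spec
        idx = np.arange(0, self.buffer_span, spec.s)
        spo2 = np.asarray(self._spo2)[idx]
        if needs_hr:
            row = np.concatenate([spo2, np.asarray(self._hr)[idx]])
        else:
            row = spo2
        value = float(self.bundle.predict(row[None, :])[0])
        return Prediction(value, sample.timestamp + spec.s + spec.f)


def replay(
    trace: VitalTrace,
    bundle: TrainedModel,
    max_gap: float = DEFAULT_MAX_GAP,
) -> VitalTrace:
    """Offline replay of the streaming loop over a whole trace.

    Returns a copy of the trace whose ``prediction`` field carries, for each
    reading that triggered a forecast, the forecast emitted at that reading
    (NaN elsewhere). Prediction-for-prediction identical to pushing the
    samples one at a time.
    """
    state = StreamState(bundle, max_gap)
    preds = np.full(len(trace), np.nan)
    for i in range(len(trace)):
        p = state.push(trace[i])
        if p is not None:
            preds[i] = p.value
    return VitalTrace(
        trace.timestamps.copy(),
        trace.spo2.copy(),
        None if trace.hr is None else trace.hr.copy(),
        preds,
        trace.patient_id,
    )
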