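"""Seedable simulator of ambulatory SpO2 / heart-rate traces.

Stands in for real pulse-oximetry recordings: a 1 Hz stream around a
patient-specific baseline saturation, punctuated by activity-driven
desaturation episodes (linear onset, exponential recovery — oxygenation
responds with a lag of tens of seconds), with additive sensor noise,
integer quantization as consumer oximeters report, and i.i.d. per-sample
dropout emulating the device's signal-quality check discarding readings
(which is what creates the timestamp gaps the segmentation stage handles).
Heart rate rises as saturation falls.

The generator is hierarchically seeded: any cohort member can be
regenerated in isolation from the master seed and its index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .vitals_io import VitalTrace

__all__ = ["SimConfig", "simulate_trace", "simulate_cohort", "patient_config"]


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters; defaults sketch a moderately unstable patient.

    duration: trace length in seconds (1 Hz grid before dropout).
    baseline_spo2: resting saturation, percent.
    episode_rate: desaturation episodes per hour (Poisson).
    episode_depth: (mean, sd) of episode depth in percent.
    onset_duration: seconds of linear decline into an episode.
    recovery_tau: exponential recovery time constant, seconds.
    dropout_prob: per-sample probability the reading is discarded.
    hr_baseline: resting heart rate, bpm.
    hr_coupling: bpm rise per percent of desaturation.
    noise_sd: additive Gaussian sensor noise on SpO2, percent.
    hr_noise_sd: additive Gaussian noise on heart rate, bpm.
    quantize: round SpO2 (and hr) to integers as consumer devices report.
    """

    duration: float = 7200.0
    baseline_spo2: float = 95.0
    episode_rate: float = 6.0
    episode_depth: tuple[float, float] = (8.0, 2.0)
    onset_duration: float = 15.0
    recovery_tau: float = 30.0
    dropout_prob: float = 0.05
    hr_baseline: float = 75.0
    hr_coupling: float = 1.5
    noise_sd: float = 0.5
    hr_noise_sd: float = 2.0
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be positive")
        if self.episode_rate < 0 or self.noise_sd < 0 or self.hr_noise_sd < 0:
            raise ValueError("rates and noise levels must be non-negative")


def _episode_profile(
    t: np.ndarray, start: float, depth: float, onset: float, tau: float
) -> np.ndarray:
    """Desaturation (positive = percent below baseline) of one episode."""
    rel = t - start
    out = np.zeros_like(t)
    rising = (rel >= 0) & (rel < onset)
    out[rising] = depth * rel[rising] / onset
    recovering = rel >= onset
    out[recovering] = depth * np.exp(-(rel[recovering] - onset) / tau)
    return out


def simulate_trace(config: SimConfig, patient_id: str = "sim") -> VitalTrace:
    """Generate one trace on a 1 Hz grid, then apply quality dropout."""
    rng = np.random.default_rng(config.seed)
    n = int(config.duration)
    t = np.arange(n, dtype=float)

    n_episodes = rng.poisson(config.episode_rate * config.duration / 3600.0)
    desat = np.zeros(n)
    starts = np.sort(rng.uniform(0.0, config.duration, size=n_episodes))
    mean_d, sd_d = config.episode_depth
    for start in starts:
        depth = max(0.0, rng.normal(mean_d, sd_d))
        desat += _episode_profile(
            t, start, depth, config.onset_duration, config.recovery_tau
        )

    spo2 = config.baseline_spo2 - desat
    if config.noise_sd > 0:
        spo2 = spo2 + rng.normal(0.0, config.noise_sd, size=n)
    hr = config.hr_baseline + config.hr_coupling * desat
    if config.hr_noise_sd > 0:
        hr = hr + rng.normal(0.0, config.hr_noise_sd, size=n)

    spo2 = np.clip(spo2, 50.0, 100.0)
    hr = np.clip(hr, 30.0, 220.0)
    if config.quantize:
        spo2 = np.round(spo2)
        hr = np.round(hr)

    keep = rng.random(n) >= config.dropout_prob
    if not keep.any():  # degenerate all-dropped draw; keep first sample
        keep[0] = True
    return VitalTrace(t[keep], spo2[keep], hr[keep], patient_id=patient_id)


def patient_config(
    base: SimConfig, master_seed: int, index: int, n_patients: int
) -> SimConfig:
    """Deterministic per-patient parameter perturbation of ``base``.

    Patient ``index`` of a cohort is fully determined by (master_seed,
    index), independent of whether the rest of the cohort is generated.
    """
    child = np.random.SeedSequence(master_seed).spawn(n_patients)[index]
    rng = np.random.default_rng(child)
    mean_d, sd_d = base.episode_depth
    return replace(
        base,
        baseline_spo2=float(np.clip(base.baseline_spo2 + rng.normal(0.0, 1.5), 88, 99)),
        episode_rate=float(base.episode_rate * rng.uniform(0.4, 2.0)),
        episode_depth=(float(max(1.0, mean_d * rng.uniform(0.5, 1.8))), sd_d),
        recovery_tau=float(base.recovery_tau * rng.uniform(0.5, 2.5)),
        hr_baseline=float(base.hr_baseline + rng.normal(0.0, 8.0)),
        seed=int(child.generate_state(1)[0]) % (2**31),
    )


def simulate_cohort(
    n_patients: int,
    base: SimConfig = SimConfig(),
    master_seed: int = 0,
) -> list[VitalTrace]:
    """Generate a cohort of heterogeneous patients, hierarchically seeded."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    traces = []
    for i in range(n_patients):
        cfg = patient_config(base, master_seed, i, n_patients)
        traces.append(simulate_trace(cfg, patient_id=f"P{i + 1}"))
    return traces
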