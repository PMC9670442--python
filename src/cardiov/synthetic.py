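"""Class-conditional synthetic 12-lead ECG generator.

Emulates 10-second, 500 Hz, 12-lead recordings whose morphology degrades
monotonically with the critical value, so that the ordinal structure the
classifier is meant to exploit is present by construction:

* ST-segment offset grows linearly with severity (0, 0.1, 0.2, 0.3 mV);
* pathological Q-wave depth grows with severity;
* RR-interval jitter is largest for the medium-risk class (emulating
  AF-like irregularity) and wide-QRS beats appear with class-dependent
  probability (emulating ventricular ectopy);
* heart-rate ranges differ per class.

Beats are sums of five Gaussian bumps (P, Q, R, S, T) plus an ST-segment
bump — a deliberately simple, controllable model, not a physiologically
validated simulator. Additive white noise and sinusoidal baseline drift
complete the signal. Everything is deterministic given the seed.

Records receive synthetic patient ids (some patients own two records, so
patient-wise splitting is exercised), ages, sexes, and a PTB-XL-style
``scp_codes`` entry using representative statement codes of each class, so
the full labeling pipeline runs unchanged on fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .wfdb_io import EcgRecord, write_record

__all__ = [
    "BeatParams",
    "SyntheticConfig",
    "beat_template",
    "generate_record",
    "generate_dataset",
    "write_dataset",
    "mean_st_offset",
    "generate_anomaly_dataset",
]

#: fixed per-lead gain/polarity applied to the base trace
LEAD_GAINS = np.array([0.6, 1.0, 0.5, -0.7, 0.35, 0.75,
                       -0.4, 0.9, 1.1, 1.0, 0.85, 0.7])

#: representative statement sets per critical value (used for scp_codes)
CLASS_CODES = {
    0: [{"NORM": 100.0, "SR": 0.0}],
    1: [{"STACH": 100.0}, {"SBRAD": 100.0}, {"PAC": 80.0, "SR": 0.0}],
    2: [{"AF": 100.0}, {"PVC": 100.0, "SR": 0.0}, {"AFLT": 80.0}],
    3: [{"IMI": 100.0, "SR": 0.0}, {"WPW": 100.0}, {"ASMI": 80.0}],
}


@dataclass(frozen=True)
class BeatParams:
    """Gaussian-bump beat: amplitudes (mV), widths (s) and centers (s,
    relative to the R peak) of the P, Q, R, S, T waves, plus an ST bump."""

    amps: tuple[float, ...] = (0.12, -0.04, 1.0, -0.15, 0.30)
    widths: tuple[float, ...] = (0.025, 0.010, 0.012, 0.012, 0.060)
    centers: tuple[float, ...] = (-0.16, -0.035, 0.0, 0.035, 0.30)
    st_offset: float = 0.0          # mV
    st_center: float = 0.12         # s after R
    st_width: float = 0.045         # s

    def widened(self, factor: float = 2.5) -> "BeatParams":
        """Wide-QRS variant: Q/R/S bumps stretched, R slightly damped."""
        w = list(self.widths)
        a = list(self.amps)
        for i in (1, 2, 3):
            w[i] *= factor
        a[2] *= 0.8
        return replace(self, widths=tuple(w), amps=tuple(a))

    def with_q_depth(self, depth: float) -> "BeatParams":
        a = list(self.amps)
        a[1] = -abs(depth)
        return replace(self, amps=tuple(a))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the generator; indexed tuples are per class 0..3."""

    sampling_rate: float = 500.0
    duration: float = 10.0
    heart_rate_range: tuple = ((60, 80), (90, 120), (70, 115), (50, 80))
    rr_jitter_sd: tuple = (0.008, 0.02, 0.10, 0.05)       # seconds
    wide_qrs_prob: tuple = (0.0, 0.05, 0.35, 0.25)
    q_wave_depth: tuple = (0.04, 0.09, 0.15, 0.28)        # mV
    st_offset: tuple = (0.0, 0.10, 0.20, 0.30)            # mV
    noise_sd: float = 0.03                                # mV per lead
    drift_amplitude: float = 0.10                         # mV
    drift_freq: float = 0.25                              # Hz

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def severity(self, cls: int) -> float:
        return cls / 3.0


def beat_template(params: BeatParams, fs: float, rr: float) -> np.ndarray:
    """Render one beat of length ``rr`` seconds at ``fs`` Hz, R peak at
    0.35 s into the window (or the window midpoint for very short RR)."""
    n = max(int(round(rr * fs)), 8)
    t = np.arange(n) / fs
    r_at = min(0.35, rr / 2)
    wave = np.zeros(n)
    for amp, width, center in zip(params.amps, params.widths, params.centers):
        wave += amp * np.exp(-0.5 * ((t - r_at - center) / width) ** 2)
    if params.st_offset:
        wave += params.st_offset * np.exp(
            -0.5 * ((t - r_at - params.st_center) / params.st_width) ** 2)
    return wave


def _base_trace(cls: int, rng: np.random.Generator,
                config: SyntheticConfig) -> np.ndarray:
    fs = config.sampling_rate
    n = config.n_samples
    hr = rng.uniform(*config.heart_rate_range[cls])
    rr_mean = 60.0 / hr
    trace = np.zeros(n)
    t = 0.05  # first beat onset (s)
    base = BeatParams(st_offset=config.st_offset[cls])
    base = base.with_q_depth(config.q_wave_depth[cls])
    while t < config.duration:
        rr = max(0.3, rr_mean + rng.normal(0.0, config.rr_jitter_sd[cls]))
        params = base
        if rng.random() < config.wide_qrs_prob[cls]:
            params = base.widened()
        beat = beat_template(params, fs, rr)
        start = int(round(t * fs))
        stop = min(start + beat.size, n)
        if start >= n:
            break
        trace[start:stop] += beat[:stop - start]
        t += rr
    return trace


def generate_record(cls: int, seed, config: SyntheticConfig | None = None,
                    record_id: str | None = None) -> EcgRecord:
    """One synthetic 12-lead record of the given critical value class.

    ``seed`` may be an int or a ``numpy.random.Generator``; identical
    (class, seed) pairs give identical signals.
    """
    if cls not in (0, 1, 2, 3):
        raise ValueError(f"class must be in 0..3, got {cls}")
    config = config or SyntheticConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    base = _base_trace(cls, rng, config)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    phases = rng.uniform(0, 2 * np.pi, size=12)
    drift = config.drift_amplitude * np.sin(
        2 * np.pi * config.drift_freq * t[None, :] + phases[:, None])
    noise = rng.normal(0.0, config.noise_sd, size=(12, n))
    signal = LEAD_GAINS[:, None] * base[None, :] + drift + noise
    age = float(np.clip(rng.normal(62, 15), 18, 92))
    sex = "male" if rng.random() < 0.52 else "female"
    codes_choices = CLASS_CODES[cls]
    codes = codes_choices[rng.integers(len(codes_choices))]
    rid = record_id or f"syn{rng.integers(10 ** 8):08d}"
    return EcgRecord(signal=signal, sampling_rate=config.sampling_rate,
                     record_id=rid, patient_id="", age=age, sex=sex,
                     codes=set(codes))


def generate_dataset(n_per_class: int, seed: int,
                     config: SyntheticConfig | None = None,
                     multi_record_prob: float = 0.3):
    """Balanced labeled dataset.

    Returns ``(signals, labels, metadata)``: signals (N, 12, samples)
    float32, labels (N,) int, and a PTB-XL-shaped metadata frame indexed by
    ``ecg_id`` with patient_id, age, sex, scp_codes (serialized dict) and
    the critical value. A fraction of patients owns two records so that
    patient-wise splitting is non-trivial.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    classes = np.repeat(np.arange(4), n_per_class)
    rng.shuffle(classes)
    n = classes.size
    signals = np.empty((n, 12, config.n_samples), dtype=np.float32)
    rows = []
    next_patient = 0
    open_patient = None  # a patient waiting for a second record
    for i, cls in enumerate(classes):
        rec = generate_record(int(cls), rng, config, record_id=f"syn{i:05d}")
        signals[i] = rec.signal.astype(np.float32)
        if open_patient is not None:
            patient = open_patient
            open_patient = None
        else:
            patient = f"p{next_patient:05d}"
            next_patient += 1
            if rng.random() < multi_record_prob:
                open_patient = patient
        rows.append({
            "ecg_id": i,
            "patient_id": patient,
            "age": rec.age,
            "sex": rec.sex,
            "scp_codes": repr({k: 100.0 for k in sorted(rec.codes)}),
            "critical_value": int(cls),
            "filename_hr": f"records500/{rec.record_id}",
        })
    metadata = pd.DataFrame(rows).set_index("ecg_id")
    return signals, classes.astype(int), metadata


def write_dataset(directory, n_per_class: int, seed: int,
                  config: SyntheticConfig | None = None) -> Path:
    """Materialize a generated dataset as WFDB records plus a metadata CSV
    (PTB-XL layout), so the file-reading pipeline runs on fixtures."""
    config = config or SyntheticConfig()
    directory = Path(directory)
    records_dir = directory / "records500"
    signals, labels, metadata = generate_dataset(n_per_class, seed, config)
    for i in range(len(signals)):
        rec = EcgRecord(signal=signals[i].astype(np.float64),
                        sampling_rate=config.sampling_rate,
                        record_id=f"syn{i:05d}")
        write_record(rec, records_dir)
    csv_path = directory / "metadata.csv"
    metadata.to_csv(csv_path)
    return csv_path


def mean_st_offset(signal: np.ndarray, fs: float, lead: int = 1) -> float:
    """Estimate the mean ST-segment elevation of one record (mV).

    R peaks are detected on one lead (default lead II); for each beat the
    mean amplitude 80-160 ms after R (ST segment) is referenced to the mean
    240-160 ms before R (PR baseline). The average over beats is a simple
    severity statistic that grows with the generator's class.
    """
    x = np.asarray(signal[lead], dtype=np.float64)
    height = 0.4 * np.max(x) if np.max(x) > 0 else None
    peaks, _ = find_peaks(x, height=height, distance=int(0.3 * fs))
    if peaks.size == 0:
        return 0.0
    offs = []
    for r in peaks:
        st_lo, st_hi = r + int(0.08 * fs), r + int(0.16 * fs)
        pr_lo, pr_hi = r - int(0.24 * fs), r - int(0.16 * fs)
        if pr_lo < 0 or st_hi > x.size:
            continue
        offs.append(x[st_lo:st_hi].mean() - x[pr_lo:pr_hi].mean())
    return float(np.mean(offs)) if offs else 0.0


def generate_anomaly_dataset(n: int, seed: int, window_s: float = 1.0,
                             config: SyntheticConfig | None = None):
    """Binary localization set for saliency checks.

    Half the records are plain class-0 signals; the other half carry a
    high-amplitude 18 Hz oscillation confined to one random ``window_s``-long
    window (labelled class 3). Returns (signals, labels, windows) where
    ``windows[i]`` is the (start, stop) sample pair of record i's anomaly, or
    None for normal records.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    n_samples = config.n_samples
    fs = config.sampling_rate
    signals = np.empty((n, 12, n_samples), dtype=np.float32)
    labels = np.zeros(n, dtype=int)
    windows: list[tuple[int, int] | None] = []
    w = int(window_s * fs)
    for i in range(n):
        rec = generate_record(0, rng, config, record_id=f"anom{i:04d}")
        sig = rec.signal
        if i % 2 == 1:
            start = int(rng.integers(0, n_samples - w))
            t = np.arange(w) / fs
            burst = 1.5 * np.sin(2 * np.pi * 18.0 * t)
            taper = np.hanning(w)
            sig = sig.copy()
            sig[:, start:start + w] += burst * taper
            labels[i] = 3
            windows.append((start, start + w))
        else:
            windows.append(None)
        signals[i] = sig.astype(np.float32)
    return signals, labels, windows
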