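"""Bandpass preprocessing of raw ECG waveforms.

Raw clinical ECG carries baseline wander (respiration, electrode drift,
< 0.5 Hz) and high-frequency noise; the model consumes signals band-limited
to 0.5-50 Hz. Filtering is zero-phase (forward-backward) so fiducial points
(QRS onset, T peak) keep their sample positions for saliency overlays.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = ["bandpass", "bandpass_sos", "preprocess_record"]

DEFAULT_LOW_HZ = 0.5
DEFAULT_HIGH_HZ = 50.0
FILTER_ORDER = 3


def bandpass_sos(fs: float, low: float = DEFAULT_LOW_HZ,
                 high: float = DEFAULT_HIGH_HZ, order: int = FILTER_ORDER):
    """Second-order sections of the Butterworth band-pass used throughout."""
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the upper "
                         f"cutoff {high} Hz")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float, low: float = DEFAULT_LOW_HZ,
             high: float = DEFAULT_HIGH_HZ, order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied independently per lead.

    ``x`` is (leads, samples) or (samples,); output has the same shape.
    Forward-backward application squares the magnitude response, so the
    effective attenuation is twice the single-pass decibels.
    """
    x = np.asarray(x, dtype=np.float64)
    sos = bandpass_sos(fs, low, high, order)
    return sps.sosfiltfilt(sos, x, axis=-1)


def preprocess_record(record, **kwargs):
    """Return a copy of an :class:`~cardiov.wfdb_io.EcgRecord` with the
    band-passed signal."""
    from dataclasses import replace

    return replace(record, signal=bandpass(record.signal,
                                           record.sampling_rate, **kwargs))
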