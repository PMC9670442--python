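"""Generate synthetic 12-lead ECG, write it as WFDB, read it back and
band-pass filter it.

Prints the drift suppression achieved by the 0.5-50 Hz zero-phase filter:
the synthetic records carry sinusoidal baseline wander below the passband.
"""

import tempfile
from pathlib import Path

import numpy as np

from cardiov import bandpass, generate_record, read_record, write_record

rec = generate_record(cls=2, seed=7)  # medium risk: AF-like irregularity
print(f"record {rec.record_id}: {rec.n_leads} leads x {rec.n_samples} samples "
      f"at {rec.sampling_rate:g} Hz; age {rec.age:.0f}, sex {rec.sex}, "
      f"codes {sorted(rec.codes)}")

with tempfile.TemporaryDirectory() as d:
    write_record(rec, d)
    back = read_record(Path(d) / rec.record_id)
print("WFDB round-trip max error:",
      f"{np.abs(back.signal - rec.signal).max() * 1000:.3f} uV")

filtered = bandpass(rec.signal, rec.sampling_rate)
# below-passband power (baseline drift) before and after, lead II
spectrum = np.abs(np.fft.rfft(rec.signal[1])) ** 2
spectrum_f = np.abs(np.fft.rfft(filtered[1])) ** 2
freqs = np.fft.rfftfreq(rec.n_samples, 1 / rec.sampling_rate)
low = freqs < 0.4
print(f"sub-0.4 Hz power: raw {spectrum[low].sum():.2f}, "
      f"filtered {spectrum_f[low].sum():.4f} "
      f"(drift suppressed ~{spectrum[low].sum() / spectrum_f[low].sum():.0f}x)")
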