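"""Minimal WFDB (PhysioNet waveform database) record I/O.

Covers the subset PTB-XL uses: a text header (``.hea``) plus a single
interleaved 16-bit little-endian signal file (``.dat``, WFDB format 16),
12 signals, with per-signal gain and baseline. Physical units are
millivolts: ``physical = (raw - baseline) / gain``.

Record metadata (age, sex, patient id, statement codes) travels in the
PTB-XL-style CSV, not in the header; header comment lines are preserved on
read but not interpreted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EcgRecord", "read_record", "write_record", "load_dataset",
           "STANDARD_LEADS"]

STANDARD_LEADS = ("I", "II", "III", "AVR", "AVL", "AVF",
                  "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class EcgRecord:
    """One 12-lead ECG waveform plus metadata.

    ``signal`` is (leads, samples) in millivolts at ``sampling_rate`` Hz.
    """

    signal: np.ndarray
    sampling_rate: float
    record_id: str
    patient_id: str = ""
    age: float | None = None
    sex: str | None = None            # "male" / "female"
    codes: set[str] = field(default_factory=set)
    lead_names: tuple[str, ...] = STANDARD_LEADS

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


_GAIN_RE = re.compile(r"^([0-9.eE+-]+)(?:\(([-0-9]+)\))?(?:/(\S+))?$")


def read_record(path, require_leads: int = 12) -> EcgRecord:
    """Read a WFDB record (path without extension, or to the ``.hea`` file).

    Only format 16 with a single ``.dat`` file is supported; that is the
    encoding of the 500 Hz PTB-XL records this package consumes.
    """
    path = Path(path)
    if path.suffix == ".hea":
        path = path.with_suffix("")
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"missing WFDB header {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    record_name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else None
    if require_leads is not None and n_sig != require_leads:
        raise IOError(f"record {record_name}: expected {require_leads} leads, "
                      f"header declares {n_sig}")
    if len(lines) < 1 + n_sig:
        raise IOError(f"header {hea} declares {n_sig} signals but lists "
                      f"{len(lines) - 1}")
    dat_names, gains, baselines, fmts, leads = [], [], [], [], []
    for i, ln in enumerate(lines[1:1 + n_sig]):
        tok = ln.split()
        dat_names.append(tok[0])
        fmts.append(tok[1])
        spec = _GAIN_RE.match(tok[2]) if len(tok) > 2 else None
        gains.append(float(spec.group(1)) if spec and spec.group(1) else 200.0)
        baselines.append(int(spec.group(2)) if spec and spec.group(2) else 0)
        leads.append(tok[-1] if len(tok) > 4 else f"S{i}")
    if any(f.split("+")[0] != "16" for f in fmts):
        raise IOError(f"record {record_name}: only WFDB format 16 is supported "
                      f"(found {set(fmts)})")
    if len(set(dat_names)) != 1:
        raise IOError(f"record {record_name}: multi-file records not supported")
    dat = path.parent / dat_names[0]
    if not dat.exists():
        raise IOError(f"missing WFDB signal file {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size % n_sig:
        raise IOError(f"signal file {dat} length {raw.size} not divisible by "
                      f"{n_sig} signals")
    raw = raw.reshape(-1, n_sig).T.astype(np.float64)
    if n_samples is not None and raw.shape[1] != n_samples:
        raise IOError(f"record {record_name}: header declares {n_samples} "
                      f"samples, file holds {raw.shape[1]}")
    gains_arr = np.asarray(gains)[:, None]
    baselines_arr = np.asarray(baselines)[:, None]
    signal = (raw - baselines_arr) / gains_arr
    return EcgRecord(signal=signal, sampling_rate=fs, record_id=record_name,
                     lead_names=tuple(leads))


def write_record(record: EcgRecord, directory, gain: float = 1000.0) -> Path:
    """Write an :class:`EcgRecord` as a WFDB format-16 pair; returns the
    header path. Gain 1000/mV gives 1 uV resolution, PTB-XL's encoding."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    digital = np.round(record.signal * gain)
    if np.abs(digital).max(initial=0) > 32767:
        raise ValueError(f"record {name}: amplitude overflows 16-bit range at "
                         f"gain {gain}")
    digital = digital.astype("<i2")
    (directory / f"{name}.dat").write_bytes(digital.T.tobytes())
    n_leads, n_samples = record.signal.shape
    lines = [f"{name} {n_leads} {record.sampling_rate:g} {n_samples}"]
    for i in range(n_leads):
        lead = record.lead_names[i] if i < len(record.lead_names) else f"S{i}"
        first = int(digital[i, 0])
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} 0 0 {lead}")
    hea = directory / f"{name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


def load_dataset(directory):
    """Load a directory produced by :func:`cardiov.synthetic.write_dataset`
    (or laid out like PTB-XL: ``metadata.csv`` plus per-record WFDB files
    referenced by its ``filename_hr`` column).

    Returns ``(signals, metadata)``: signals (N, 12, samples) float32 in
    metadata row order.
    """
    import pandas as pd

    directory = Path(directory)
    metadata = pd.read_csv(directory / "metadata.csv", index_col=0)
    signals = []
    for _, row in metadata.iterrows():
        rec = read_record(directory / str(row["filename_hr"]))
        signals.append(rec.signal.astype(np.float32))
    return np.stack(signals), metadata
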