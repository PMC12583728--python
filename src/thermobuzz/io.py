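"""Readers and writers for waveforms and result tables.

Waveforms travel as float WAV (sampling rate in the header) or 2-column
tab-delimited text (time in s, acceleration in m s^-2; the rate is
inferred from the time column) — the text form mirrors the conversion the
field acquisition chain produces.  Tables are plain CSV with documented
column names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .extraction import BuzzFeatures, Waveform

PER_BUZZ_COLUMNS = ["bee_id", "buzz_index", "start_s", "end_s",
                    "duration_s", "peak_accel_ms2", "f0_hz"]


def write_wav(path: str | Path, w: Waveform) -> None:
    wavfile.write(str(path), int(round(w.sampling_rate)),
                  w.samples.astype(np.float32))


def write_waveform_txt(path: str | Path, w: Waveform) -> None:
    arr = np.column_stack([w.times, w.samples])
    np.savetxt(str(path), arr, fmt="%.8f\t%.6f", delimiter="\t",
               header="time_s\tacceleration_ms2", comments="")


def read_waveform(path: str | Path) -> Waveform:
    """Dispatch on extension: .wav uses the header rate; text infers the
    rate from the time column."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        rate, samples = wavfile.read(str(path))
        samples = np.asarray(samples, float)
        if samples.ndim > 1:
            samples = samples[:, 0]
        return Waveform(samples, float(rate), source_id=path.stem)
    data = np.loadtxt(str(path), skiprows=_n_header_rows(path))
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (time, acceleration)")
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    rate = 1.0 / float(np.median(dt))
    return Waveform(x, rate, source_id=path.stem)


def _n_header_rows(path: Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        float(first.split()[0])
        return 0
    except ValueError:
        return 1


def features_to_frame(features: list[BuzzFeatures], bee_id: str) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(features):
        rows.append({
            "bee_id": bee_id, "buzz_index": i,
            "start_s": f.start_time, "end_s": f.start_time + f.duration,
            "duration_s": f.duration, "peak_accel_ms2": f.peak_accel,
            "f0_hz": f.f0,
        })
    return pd.DataFrame(rows, columns=PER_BUZZ_COLUMNS)
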