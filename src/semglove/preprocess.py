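"""Acquisition-side filtering: 5-50 Hz band-pass and 50 Hz line notch.

The acquisition chain band-pass filters raw sEMG at 5-50 Hz and notches
out 50 Hz mains interference.  Both filters here are zero-phase
(forward-backward application), so sample labels stay aligned with the
signal: a 4th-order Butterworth band-pass and a second-order IIR notch
with quality factor 30.  The first and last 250 ms are flagged in
metadata as potentially transient-affected.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import InvalidConfigError
from .recording import SemgRecording

#: Edge stretch flagged as affected by filter transients (seconds).
TRANSIENT_S = 0.25


def bandpass(
    rec: SemgRecording, low: float = 5.0, high: float = 50.0, order: int = 4
) -> SemgRecording:
    """Zero-phase Butterworth band-pass; labels and metadata preserved."""
    nyq = rec.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise InvalidConfigError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < {nyq} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=0)
    return rec.copy_with(
        samples=filtered, bandpass_hz=(low, high), transient_s=TRANSIENT_S
    )


def notch(rec: SemgRecording, freq: float = 50.0, quality: float = 30.0) -> SemgRecording:
    """Zero-phase IIR notch at `freq`; labels and metadata preserved."""
    nyq = rec.sample_rate / 2.0
    if not (0 < freq < nyq):
        raise InvalidConfigError(f"notch frequency {freq} Hz must be in (0, {nyq}) Hz")
    b, a = signal.iirnotch(freq, quality, fs=rec.sample_rate)
    filtered = signal.filtfilt(b, a, rec.samples, axis=0)
    return rec.copy_with(samples=filtered, notch_hz=freq, transient_s=TRANSIENT_S)


def preprocess(
    rec: SemgRecording,
    band: tuple[float, float] = (5.0, 50.0),
    notch_hz: float | None = 50.0,
) -> SemgRecording:
    """Standard chain: band-pass, then (optionally) the mains notch."""
    out = bandpass(rec, *band)
    if notch_hz is not None:
        out = notch(out, notch_hz)
    return out


def sinusoid_gain(rec_in: SemgRecording, rec_out: SemgRecording, freq: float) -> float:
    """Amplitude gain at `freq` measured by FFT (diagnostic helper)."""
    f_in = np.abs(np.fft.rfft(rec_in.samples[:, 0]))
    f_out = np.abs(np.fft.rfft(rec_out.samples[:, 0]))
    k = int(round(freq * rec_in.n_samples / rec_in.sample_rate))
    if f_in[k] == 0:
        return 0.0
    return float(f_out[k] / f_in[k])
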