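"""Windowed RMS feature extraction.

The classifier's input representation is the per-channel root mean
square over adjacent, disjoint analysis windows of 500 ms:

    RMS = sqrt( (1/N) * sum_i v_i^2 )

where N is the number of samples in the window (125 at 250 Hz) and v_i
the voltage at sample i.  At 250 Hz this yields two 4-channel RMS
vectors per second of signal.  Windows are contiguous from sample 0; a
trailing partial window is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, MissingLabelsError
from .recording import N_CHANNELS, SemgRecording

DEFAULT_WINDOW_MS = 500.0


def _window_samples(sample_rate: float, window_ms: float) -> int:
    n_float = window_ms * sample_rate / 1000.0
    n = round(n_float)
    if n <= 0 or abs(n_float - n) > 1e-9:
        raise InvalidConfigError(
            f"window of {window_ms} ms at {sample_rate} Hz is not a positive "
            f"integer number of samples ({n_float})"
        )
    return n


@dataclass
class FeatureMatrix:
    """Per-window, per-channel RMS values with optional window labels.

    ``values`` has shape ``(n_windows, 4)`` in microvolts; ``labels`` is
    one motion code per window when the source recording was labeled.
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    window_ms: float = DEFAULT_WINDOW_MS
    samples_per_window: int = 125
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size and self.values.shape[1] != N_CHANNELS:
            raise InvalidConfigError(
                f"feature values must have {N_CHANNELS} columns; got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise InvalidConfigError("RMS values must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype="U1")
            if self.labels.shape[0] != self.n_windows:
                raise InvalidConfigError("one label per window required")

    @property
    def n_windows(self) -> int:
        return 0 if self.values.size == 0 else self.values.shape[0]

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"rms_ch{i + 1}" for i in range(N_CHANNELS)]
        )
        df.insert(0, "window_index", np.arange(self.n_windows))
        if self.labels is not None:
            df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, window_ms: float = DEFAULT_WINDOW_MS,
                   samples_per_window: int = 125) -> "FeatureMatrix":
        cols = [f"rms_ch{i + 1}" for i in range(N_CHANNELS)]
        labels = df["label"].to_numpy(dtype="U1") if "label" in df.columns else None
        return cls(df[cols].to_numpy(), labels, window_ms, samples_per_window)


def rms_features(
    rec: SemgRecording, window_ms: float = DEFAULT_WINDOW_MS
) -> FeatureMatrix:
    """Compute per-channel RMS over adjacent disjoint windows.

    The trailing partial window (if any) is discarded; a recording
    shorter than one window yields an empty FeatureMatrix.
    """
    n = _window_samples(rec.sample_rate, window_ms)
    n_windows = rec.n_samples // n
    if n_windows == 0:
        return FeatureMatrix(
            np.empty((0, N_CHANNELS)), None, window_ms, n, dict(rec.metadata)
        )
    trimmed = rec.samples[: n_windows * n].reshape(n_windows, n, N_CHANNELS)
    values = np.sqrt(np.mean(trimmed**2, axis=1))
    labels = window_labels(rec, window_ms) if rec.is_labeled else None
    return FeatureMatrix(values, labels, window_ms, n, dict(rec.metadata))


def window_labels(
    rec: SemgRecording, window_ms: float = DEFAULT_WINDOW_MS
) -> np.ndarray:
    """One motion code per complete window: the majority label.

    Ties are broken toward the label that starts earlier within the
    window.
    """
    if rec.labels is None:
        raise MissingLabelsError("recording has no per-sample labels")
    n = _window_samples(rec.sample_rate, window_ms)
    n_windows = rec.n_samples // n
    out = np.empty(n_windows, dtype="U1")
    for w in range(n_windows):
        window = rec.labels[w * n : (w + 1) * n]
        codes, first_pos, counts = np.unique(
            window, return_index=True, return_counts=True
        )
        best = max(range(len(codes)), key=lambda i: (counts[i], -first_pos[i]))
        out[w] = codes[best]
    return out
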