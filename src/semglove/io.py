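"""Delimited-text file formats for recordings, features and label streams.

Recordings are comma-separated UTF-8 with a header row
``time_s,ch1,ch2,ch3,ch4[,label]`` (voltages in microvolts, one file
per trial); feature matrices as ``window_index,rms_ch1..rms_ch4[,label]``;
label streams as one single-letter motion code per line.  Values are
printed to 6 significant digits, so a write/read round trip is lossless
at that precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RecordingFormatError
from .features import FeatureMatrix
from .motions import Motion, as_motion
from .recording import N_CHANNELS, SemgRecording

_CHANNEL_COLS = [f"ch{i + 1}" for i in range(N_CHANNELS)]


def write_recording(rec: SemgRecording, path: str | Path) -> None:
    df = pd.DataFrame(rec.samples, columns=_CHANNEL_COLS)
    df.insert(0, "time_s", rec.times)
    if rec.labels is not None:
        df["label"] = rec.labels
    df.to_csv(path, index=False, float_format="%.6g")


def read_recording(path: str | Path) -> SemgRecording:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise RecordingFormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    if "time_s" not in df.columns:
        raise RecordingFormatError(f"{path}: header must start with time_s")
    channel_cols = [c for c in df.columns if c.startswith("ch")]
    if channel_cols != _CHANNEL_COLS:
        raise RecordingFormatError(
            f"{path}: expected channel columns {_CHANNEL_COLS}; got {channel_cols}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(t) > 1:
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            # diff index i flags data row i+1; +1 header, +1 one-based lines
            raise RecordingFormatError(
                f"{path}: time_s not strictly increasing at line {bad[0] + 3}"
            )
        sample_rate = 1.0 / np.median(dt)
    else:
        sample_rate = 250.0
    labels = df["label"].to_numpy(dtype="U1") if "label" in df.columns else None
    return SemgRecording(
        samples=df[_CHANNEL_COLS].to_numpy(dtype=float),
        sample_rate=float(sample_rate),
        labels=labels,
        metadata={"source": str(path)},
    )


def write_features(features: FeatureMatrix, path: str | Path) -> None:
    features.to_frame().to_csv(path, index=False, float_format="%.6g")


def read_features(path: str | Path) -> FeatureMatrix:
    return FeatureMatrix.from_frame(pd.read_csv(path))


def write_labels(labels: Sequence[Motion | str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{as_motion(l).value}\n" for l in labels))


def read_labels(path: str | Path) -> list[Motion]:
    return [as_motion(line) for line in Path(path).read_text().split()]
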