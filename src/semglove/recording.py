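"""In-memory container for multichannel sEMG recordings.

A recording is a matrix of voltages in microvolts (rows = time points,
columns = the 4 forearm electrode channels) sampled at a fixed rate,
optionally with one motion label per sample and free-form metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InvalidConfigError
from .motions import Motion, as_motion

N_CHANNELS = 4
DEFAULT_SAMPLE_RATE = 250.0


@dataclass
class SemgRecording:
    """Timestamped 4-channel voltage series with optional per-sample labels.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, 4)`` in microvolts.
    sample_rate
        Sampling rate in Hz (default 250).
    labels
        Optional array of single-letter motion codes, one per sample.
    metadata
        Free-form key/value information (subject id, seed, protocol, ...).
    """

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    labels: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise InvalidConfigError(
                f"samples must have shape (n, {N_CHANNELS}); got {self.samples.shape}"
            )
        if self.sample_rate <= 0:
            raise InvalidConfigError(f"sample_rate must be > 0; got {self.sample_rate}")
        if self.labels is not None:
            self.labels = np.asarray(
                [as_motion(l).value for l in np.asarray(self.labels).ravel()],
                dtype="U1",
            )
            if self.labels.shape[0] != self.samples.shape[0]:
                raise InvalidConfigError(
                    f"label count {self.labels.shape[0]} != sample count "
                    f"{self.samples.shape[0]}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def label_motions(self) -> list[Motion]:
        if self.labels is None:
            return []
        return [Motion(l) for l in self.labels]

    def copy_with(self, samples: np.ndarray | None = None, **meta: Any) -> "SemgRecording":
        """Copy, optionally replacing samples and extending metadata."""
        return SemgRecording(
            samples=self.samples.copy() if samples is None else samples,
            sample_rate=self.sample_rate,
            labels=None if self.labels is None else self.labels.copy(),
            metadata={**self.metadata, **meta},
        )


def concatenate(recordings: list[SemgRecording]) -> SemgRecording:
    """Concatenate recordings in time; sample rates must agree."""
    if not recordings:
        raise InvalidConfigError("cannot concatenate an empty list of recordings")
    rates = {r.sample_rate for r in recordings}
    if len(rates) != 1:
        raise InvalidConfigError(f"sample rates differ: {sorted(rates)}")
    labeled = all(r.is_labeled for r in recordings)
    return SemgRecording(
        samples=np.vstack([r.samples for r in recordings]),
        sample_rate=recordings[0].sample_rate,
        labels=np.concatenate([r.labels for r in recordings]) if labeled else None,
        metadata={"concatenated": len(recordings)},
    )
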