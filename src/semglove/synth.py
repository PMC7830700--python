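"""Synthetic sEMG generator emulating the study acquisition protocol.

Real surface EMG during a sustained contraction is well approximated, at
the level the downstream pipeline cares about (windowed RMS amplitude),
by amplitude-modulated band-limited Gaussian noise.  Each channel is
generated as zero-mean Gaussian noise whose power is confined to the
acquisition band (5-50 Hz by default) and whose long-run RMS equals a
per-motion, per-channel target amplitude in microvolts.

Two kinds of recordings are produced:

* single-motion *trials* of ~20 s, 30 repetitions per motion (the
  training material: 10 minutes of signal per motion), and
* two-motion *sequences* alternating every 5 s for 5 repetitions (the
  evaluation material), with a linear amplitude cross-fade at each
  switch to mimic gradual muscle onset/offset.

The default per-motion amplitude profiles are invented (no amplitude
statistics exist for the study's recordings, which were not deposited);
they encode distinct channel-dominance patterns — extensor-dominant for
extension, flexor-dominant for fist, intermediate co-contraction for the
spherical grip, low uniform tone at rest — so the four motions are
linearly separable in 4-channel RMS space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidConfigError
from .motions import MOTION_ORDER, Motion, as_motion
from .recording import DEFAULT_SAMPLE_RATE, N_CHANNELS, SemgRecording

#: Default per-motion channel RMS amplitudes in microvolts (synthetic,
#: invented profiles; see module docstring).
DEFAULT_AMPLITUDES: dict[Motion, tuple[float, float, float, float]] = {
    Motion.EXTENSION: (80.0, 15.0, 12.0, 10.0),
    Motion.REST: (8.0, 8.0, 8.0, 8.0),
    Motion.SPHERICAL: (30.0, 60.0, 45.0, 22.0),
    Motion.FIST: (55.0, 95.0, 80.0, 60.0),
}

#: The three alternating-motion test protocols (Rest/Extension,
#: Rest/Spherical, Spherical/Fist) covering all non-trivial allowed
#: transitions.
PROTOCOL_PAIRS: tuple[tuple[Motion, Motion], ...] = (
    (Motion.REST, Motion.EXTENSION),
    (Motion.REST, Motion.SPHERICAL),
    (Motion.SPHERICAL, Motion.FIST),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic signal model and acquisition protocol.

    Attributes
    ----------
    amplitudes
        Per-motion 4-channel target RMS amplitudes (microvolts).
    noise_band
        Low/high cutoff (Hz) of the band-limited Gaussian process.
    ramp_ms
        Linear amplitude cross-fade duration at motion switches (ms).
    trial_s
        Duration of one single-motion trial (seconds).
    trials_per_motion
        Number of trials recorded per motion.
    sample_rate
        Sampling rate (Hz).
    """

    amplitudes: Mapping[Motion, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    noise_band: tuple[float, float] = (5.0, 50.0)
    ramp_ms: float = 200.0
    trial_s: float = 20.0
    trials_per_motion: int = 30
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.trial_s <= 0:
            raise InvalidConfigError(f"trial_s must be > 0; got {self.trial_s}")
        if self.trials_per_motion < 0:
            raise InvalidConfigError("trials_per_motion must be >= 0")
        if self.ramp_ms < 0:
            raise InvalidConfigError("ramp_ms must be >= 0")
        low, high = self.noise_band
        if not (0 < low < high < self.sample_rate / 2):
            raise InvalidConfigError(
                f"noise_band must satisfy 0 < low < high < sample_rate/2; "
                f"got {self.noise_band} at {self.sample_rate} Hz"
            )
        for m in MOTION_ORDER:
            amps = self.amplitude_vector(m)
            if len(amps) != N_CHANNELS or any(a < 0 for a in amps):
                raise InvalidConfigError(
                    f"amplitudes[{m.value}] must be {N_CHANNELS} non-negative values"
                )

    def amplitude_vector(self, motion: Motion) -> tuple[float, ...]:
        amps = {as_motion(k): v for k, v in self.amplitudes.items()}
        if motion not in amps:
            raise InvalidConfigError(f"no amplitude profile for motion {motion.value}")
        return tuple(float(a) for a in amps[motion])


@dataclass(frozen=True)
class SequenceProtocol:
    """A two-motion alternation protocol: A, B, A, B, ... every `interval_s`."""

    pair: tuple[Motion, Motion]
    interval_s: float = 5.0
    repetitions: int = 5

    def __post_init__(self) -> None:
        a, b = (as_motion(self.pair[0]), as_motion(self.pair[1]))
        object.__setattr__(self, "pair", (a, b))
        allowed = set(PROTOCOL_PAIRS) | {(y, x) for x, y in PROTOCOL_PAIRS}
        if (a, b) not in allowed:
            raise InvalidConfigError(
                f"protocol pair {a.value}{b.value} is not an allowed transition; "
                f"use one of RE, RS, SF (either order)"
            )
        if self.interval_s <= 0:
            raise InvalidConfigError("interval_s must be > 0")
        if self.repetitions < 0:
            raise InvalidConfigError("repetitions must be >= 0")

    @property
    def motion_sequence(self) -> list[Motion]:
        """Ground-truth segment labels: 2 x repetitions motions, alternating."""
        a, b = self.pair
        return [a, b] * self.repetitions

    @property
    def name(self) -> str:
        return "".join(m.value for m in self.pair)


def _bandlimited_unit_noise(
    n: int, sample_rate: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian noise with spectrum confined to `band`, unit RMS.

    White Gaussian noise is shaped in the frequency domain (bins outside
    the band zeroed) and rescaled to unit RMS over the whole stretch, so
    multiplying by a target amplitude yields that exact long-run RMS.
    """
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spectrum[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spectrum, n)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        return x
    return x / rms


def generate_trial(
    motion: Motion | str,
    cfg: SyntheticConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> SemgRecording:
    """Generate one single-motion trial (default: 20 s at 250 Hz).

    Every sample carries the trial's motion label.  Each channel is
    band-limited Gaussian noise scaled so its RMS over the trial equals
    the configured per-motion amplitude; a zero amplitude yields a zero
    channel.  Fully reproducible given the seed.
    """
    cfg = cfg or SyntheticConfig()
    motion = as_motion(motion)
    amps = cfg.amplitude_vector(motion)
    n = round(cfg.trial_s * cfg.sample_rate)
    rng = np.random.default_rng(seed)
    samples = np.empty((n, N_CHANNELS))
    for ch, amp in enumerate(amps):
        if amp == 0:
            samples[:, ch] = 0.0
        else:
            samples[:, ch] = amp * _bandlimited_unit_noise(
                n, cfg.sample_rate, cfg.noise_band, rng
            )
    return SemgRecording(
        samples=samples,
        sample_rate=cfg.sample_rate,
        labels=np.full(n, motion.value, dtype="U1"),
        metadata={"kind": "trial", "motion": motion.value},
    )


def generate_sequence(
    protocol: SequenceProtocol,
    cfg: SyntheticConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> SemgRecording:
    """Generate a labeled two-motion alternation recording.

    Segments alternate A, B, A, B, ...; the channel amplitude envelope
    cross-fades linearly over ``cfg.ramp_ms`` centered on each switch,
    while the ground-truth label switches exactly at the segment
    boundary (the ramp midpoint).
    """
    cfg = cfg or SyntheticConfig()
    seg_n = round(protocol.interval_s * cfg.sample_rate)
    motions = protocol.motion_sequence
    total = seg_n * len(motions)
    if total == 0:
        return SemgRecording(
            samples=np.empty((0, N_CHANNELS)),
            sample_rate=cfg.sample_rate,
            labels=np.empty(0, dtype="U1"),
            metadata={"kind": "sequence", "protocol": protocol.name},
        )

    # Per-channel amplitude envelope: step function with linear cross-fades.
    amp_table = np.array([cfg.amplitude_vector(m) for m in motions])  # (nseg, 4)
    envelope = np.repeat(amp_table, seg_n, axis=0)  # (total, 4)
    ramp_n = round(cfg.ramp_ms / 1000.0 * cfg.sample_rate)
    if ramp_n > 1:
        for k in range(1, len(motions)):
            b = k * seg_n  # boundary sample index
            start = max(b - ramp_n // 2, 0)
            stop = min(start + ramp_n, total)
            frac = np.linspace(0.0, 1.0, stop - start, endpoint=False)[:, None]
            prev_amp = amp_table[k - 1][None, :]
            next_amp = amp_table[k][None, :]
            envelope[start:stop] = prev_amp + frac * (next_amp - prev_amp)

    rng = np.random.default_rng(seed)
    samples = np.empty((total, N_CHANNELS))
    for ch in range(N_CHANNELS):
        base = _bandlimited_unit_noise(total, cfg.sample_rate, cfg.noise_band, rng)
        samples[:, ch] = envelope[:, ch] * base

    labels = np.repeat([m.value for m in motions], seg_n).astype("U1")
    return SemgRecording(
        samples=samples,
        sample_rate=cfg.sample_rate,
        labels=labels,
        metadata={
            "kind": "sequence",
            "protocol": protocol.name,
            "interval_s": protocol.interval_s,
            "repetitions": protocol.repetitions,
        },
    )


def generate_dataset(
    cfg: SyntheticConfig | None = None, seed: int = 0
) -> dict[Motion, list[SemgRecording]]:
    """Generate the full single-motion training corpus.

    Returns ``trials_per_motion`` trials for each of the four motions
    (default 30 x 20 s = 10 min of signal per motion).  Trial sub-seeds
    are spawned deterministically from the master seed via
    ``numpy.random.SeedSequence(seed).spawn``, so the corpus is
    reproducible trial-by-trial.
    """
    cfg = cfg or SyntheticConfig()
    children = iter(
        np.random.SeedSequence(seed).spawn(len(MOTION_ORDER) * cfg.trials_per_motion)
    )
    dataset: dict[Motion, list[SemgRecording]] = {}
    for motion in MOTION_ORDER:
        trials = []
        for trial_idx in range(cfg.trials_per_motion):
            rec = generate_trial(motion, cfg, next(children))
            rec.metadata["trial"] = trial_idx
            trials.append(rec)
        dataset[motion] = trials
    return dataset


def default_protocols(
    interval_s: float = 5.0, repetitions: int = 5
) -> list[SequenceProtocol]:
    """The three standard evaluation protocols: RE, RS, SF."""
    return [
        SequenceProtocol(pair=pair, interval_s=interval_s, repetitions=repetitions)
        for pair in PROTOCOL_PAIRS
    ]
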