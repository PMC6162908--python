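"""Synthetic motor-imagery EEG with class-dependent ERD.

Each simulated trial follows the cue-based imagery protocol: rest until the
cue at 2 s, imagery from the cue through 6 s, trial end at 7 s.  Sensors
carry narrowband sensorimotor rhythms (mu 8-12 Hz, beta 18-25 Hz, built by
band-pass filtering white noise so they are realistically non-sinusoidal)
on top of 1/f background noise.  During the imagery interval the rhythm
source assigned to the trial's class is attenuated by ``1 - erd_depth`` —
event-related desynchronization — so that an epoch extracted over [4, 6] s
shows a class-specific band-power drop of (1 - erd_depth)^2 at the
modulated channel.  Sources can be spatially mixed across channels to
emulate volume conduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data import Trial, TrialSet

__all__ = ["SyntheticConfig", "simulate_trialset", "RHYTHM_BANDS_HZ"]

RHYTHM_BANDS_HZ = {"mu": (8.0, 12.0), "beta": (18.0, 25.0)}


def _default_class_spec() -> dict[int, list[tuple[int, str, float]]]:
    # left/right-hand-like pair: mu ERD at the contralateral sensor
    return {1: [(0, "mu", 0.6)], 2: [(2, "mu", 0.6)]}


@dataclass
class SyntheticConfig:
    """Generator settings.

    ``class_spec`` maps each class label to (channel index, rhythm,
    erd_depth) entries; every (channel, rhythm) pair named anywhere is a
    source present in all trials, and attenuated during imagery only in
    trials of the classes that name it.  ``mixing`` is ``"identity"``
    (source k drives its declared channel) or an
    ``n_channels x n_sources`` matrix over the ordered source list.
    """

    n_channels: int = 3
    class_spec: dict[int, list[tuple[int, str, float]]] = field(
        default_factory=_default_class_spec
    )
    trial_length_s: float = 7.0
    sample_rate_hz: float = 250.0
    cue_onset_s: float = 2.0
    imagery_end_s: float = 6.0
    rhythm_amplitude: float = 1.0
    background_noise_sigma: float = 0.5
    mixing: np.ndarray | str = "identity"
    n_trials_per_class: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1 or self.trial_length_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("channel count, length and rate must be positive")
        for cls, entries in self.class_spec.items():
            for ch, rhythm, depth in entries:
                if not 0 <= ch < self.n_channels:
                    raise ValueError(f"class {cls}: channel {ch} out of range")
                if rhythm not in RHYTHM_BANDS_HZ:
                    raise ValueError(f"unknown rhythm {rhythm!r}")
                if not 0.0 <= depth <= 1.0:
                    raise ValueError(f"erd_depth {depth} outside [0, 1]")

    def sources(self) -> list[tuple[int, str]]:
        """Ordered union of (channel, rhythm) pairs across all classes."""
        seen = []
        for entries in self.class_spec.values():
            for ch, rhythm, _ in entries:
                if (ch, rhythm) not in seen:
                    seen.append((ch, rhythm))
        return sorted(seen)


def _narrowband(rng: np.random.Generator, band: tuple[float, float],
                n: int, rate: float) -> np.ndarray:
    """Unit-variance band-limited noise (order-4 zero-phase Butterworth)."""
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * int(rate)))
    x = x[int(rate) : int(rate) + n]
    s = x.std()
    return x / s if s > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance noise with a -1 spectral power slope (1/f)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    return x / s if s > 0 else x


def simulate_trialset(cfg: SyntheticConfig) -> TrialSet:
    """Generate a balanced, labelled, seed-deterministic TrialSet."""
    cfg.validate()
    rate = cfg.sample_rate_hz
    n = int(round(cfg.trial_length_s * rate))
    sources = cfg.sources()
    if isinstance(cfg.mixing, str):
        if cfg.mixing != "identity":
            raise ValueError(f"unknown mixing {cfg.mixing!r}")
        mix = np.zeros((cfg.n_channels, len(sources)))
        for k, (ch, _) in enumerate(sources):
            mix[ch, k] = 1.0
    else:
        mix = np.asarray(cfg.mixing, float)
        if mix.shape != (cfg.n_channels, len(sources)):
            raise ValueError(
                f"mixing must be {cfg.n_channels} x {len(sources)}, got {mix.shape}"
            )
    imagery = slice(int(round(cfg.cue_onset_s * rate)),
                    int(round(cfg.imagery_end_s * rate)))
    classes = sorted(cfg.class_spec)
    depth_of = {
        (cls, ch, rhythm): depth
        for cls, entries in cfg.class_spec.items()
        for ch, rhythm, depth in entries
    }
    trials = []
    trial_idx = 0
    for cls in classes:
        for _ in range(cfg.n_trials_per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, trial_idx])
            )
            src = np.empty((len(sources), n))
            for k, (ch, rhythm) in enumerate(sources):
                wave = cfg.rhythm_amplitude * _narrowband(
                    rng, RHYTHM_BANDS_HZ[rhythm], n, rate
                )
                depth = depth_of.get((cls, ch, rhythm))
                if depth:
                    env = np.ones(n)
                    env[imagery] = 1.0 - depth
                    wave = wave * env
                src[k] = wave
            noise = cfg.background_noise_sigma * np.stack(
                [_pink_noise(rng, n) for _ in range(cfg.n_channels)]
            )
            trials.append(
                Trial(data=mix @ src + noise, label=cls,
                      subject_id="synthetic", session_id="")
            )
            trial_idx += 1
    return TrialSet(trials=trials, class_set=classes, sample_rate_hz=rate)
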