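"""Broadband preprocessing and the multi-band Butterworth filter bank.

Preprocessing applies a 50 Hz notch and a 0.1-100 Hz Butterworth band-pass.
The filter bank divides the 8-30 Hz range (covering the sensorimotor mu and
beta rhythms) into ten 4 Hz-wide bands overlapping their neighbour by 2 Hz:
[8,12], [10,14], ..., [26,30] Hz.  All filters are applied forward-backward
(zero phase) so band-passed samples stay aligned with trial time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data import RawRecording, Trial

__all__ = ["BandSpec", "FilterBank", "default_filter_bank", "preprocess", "apply_filter_bank"]

DEFAULT_BANDS_HZ: list[tuple[float, float]] = [
    (8, 12), (10, 14), (12, 16), (14, 18), (16, 20),
    (18, 22), (20, 24), (22, 26), (24, 28), (26, 30),
]


@dataclass(frozen=True)
class BandSpec:
    """One band-pass filter: pass-band edges in Hz and Butterworth order."""

    low_hz: float
    high_hz: float
    order: int = 4

    def validate(self, sample_rate_hz: float) -> None:
        nyq = sample_rate_hz / 2.0
        if not (0 < self.low_hz < self.high_hz < nyq):
            raise ValueError(
                f"band [{self.low_hz}, {self.high_hz}] Hz invalid for "
                f"sample rate {sample_rate_hz} Hz (Nyquist {nyq} Hz)"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


class FilterBank:
    """An ordered bank of zero-phase Butterworth band-pass filters."""

    def __init__(self, bands: list[BandSpec], sample_rate_hz: float):
        if not bands:
            raise ValueError("filter bank needs at least one band")
        for b in bands:
            b.validate(sample_rate_hz)
        self.bands = list(bands)
        self.sample_rate_hz = float(sample_rate_hz)
        self._sos = [
            sps.butter(
                b.order, [b.low_hz, b.high_hz], btype="bandpass",
                fs=sample_rate_hz, output="sos",
            )
            for b in bands
        ]

    def __len__(self) -> int:
        return len(self.bands)

    def filter_band(self, x: np.ndarray, band_index: int) -> np.ndarray:
        """Zero-phase band-pass of ``x`` (..., samples) through one band."""
        return sps.sosfiltfilt(self._sos[band_index], np.asarray(x, float), axis=-1)


def default_filter_bank(sample_rate_hz: float, order: int = 4) -> FilterBank:
    """The standard ten-band division of 8-30 Hz (4 Hz bands, 2 Hz overlap)."""
    if sample_rate_hz <= 60:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz too low for the 8-30 Hz bank"
        )
    return FilterBank(
        [BandSpec(lo, hi, order) for lo, hi in DEFAULT_BANDS_HZ], sample_rate_hz
    )


def preprocess(
    recording: RawRecording,
    notch_hz: float = 50.0,
    band_hz: tuple[float, float] = (0.1, 100.0),
    notch_q: float = 30.0,
    order: int = 4,
) -> RawRecording:
    """Apply the mains notch and broadband band-pass to a recording.

    The 100 Hz upper edge is clipped just below Nyquist when the sampling
    rate is under 250 Hz.  Both stages are zero-phase.
    """
    rate = recording.sample_rate_hz
    nyq = rate / 2.0
    low, high = band_hz
    high = min(high, 0.95 * nyq)
    if not (0 < low < high):
        raise ValueError(f"invalid broadband edges [{low}, {high}] Hz")
    x = recording.signal
    if 0 < notch_hz < nyq:
        b, a = sps.iirnotch(notch_hz, notch_q, fs=rate)
        x = sps.filtfilt(b, a, x, axis=-1)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1)
    return RawRecording(
        signal=x,
        sample_rate_hz=rate,
        channel_labels=list(recording.channel_labels),
        events=list(recording.events),
    )


def apply_filter_bank(trial: Trial, bank: FilterBank, sample_rate_hz: float | None = None) -> list[Trial]:
    """Band-pass one trial through every band of the bank.

    Returns one Trial per band, same shape and metadata as the input.  When
    ``sample_rate_hz`` is given it must match the rate the bank was built for.
    """
    if sample_rate_hz is not None and not np.isclose(sample_rate_hz, bank.sample_rate_hz):
        raise ValueError(
            f"trial sample rate {sample_rate_hz} Hz does not match filter bank "
            f"design rate {bank.sample_rate_hz} Hz"
        )
    return [trial.with_data(bank.filter_band(trial.data, i)) for i in range(len(bank))]
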