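"""Sequential structure on spatial-frequency features.

Two operations expose the time axis of FB-CSP features to classifiers:

* :func:`smooth` — a causal moving average over the current and previous
  ``omega`` samples, used to probe whether sequential structure carries
  class information (an SVM on smoothed features is the baseline probe);
* :func:`crop_slices` — the sliding-window cropping strategy, turning one
  labelled trial of T samples into T - tau overlapping labelled slices of
  length tau, multiplying the sample count available to a sequence model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csp import FeatureSeries

__all__ = ["TimeSlice", "smooth", "crop_slices"]


@dataclass
class TimeSlice:
    """A tau-length crop of a feature series, inheriting the trial label."""

    values: np.ndarray  # (D, tau)
    label: int
    trial_id: str = ""
    offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("slice must be 2-D with at least one column")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")

    @property
    def length(self) -> int:
        return self.values.shape[1]


def smooth(
    z: FeatureSeries, omega: int, literal_divisor: bool = False
) -> FeatureSeries:
    """Causal moving average over the current and previous ``omega`` samples.

    Each output sample averages ``omega + 1`` terms; near the left edge the
    divisor shrinks to the number of samples actually available, so constant
    rows are fixed points and ``omega = 0`` is the identity.

    ``literal_divisor`` divides the same sum by ``omega`` instead (undefined
    at ``omega = 0``); it is kept only for comparison and not recommended,
    as constants are then scaled by (omega+1)/omega.
    """
    if omega < 0:
        raise ValueError("smoothing window must be non-negative")
    if omega == 0 and not literal_divisor:
        return FeatureSeries(
            values=z.values.copy(), label=z.label,
            trial_id=z.trial_id, layout=list(z.layout),
        )
    if literal_divisor and omega == 0:
        raise ValueError("literal divisor is undefined for omega = 0")
    x = z.values
    t = x.shape[1]
    csum = np.concatenate(
        [np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1
    )
    idx = np.arange(t)
    left = np.maximum(idx - omega, 0)
    sums = csum[:, idx + 1] - csum[:, left]
    div = (idx - left + 1).astype(float) if not literal_divisor else float(omega)
    return FeatureSeries(
        values=sums / div, label=z.label, trial_id=z.trial_id, layout=list(z.layout)
    )


def crop_slices(z: FeatureSeries, tau: int, stride: int = 1) -> list[TimeSlice]:
    """Crop a feature series into overlapping labelled time slices.

    Slices start at offsets 0, stride, 2*stride, ... up to and including
    ``T - tau - 1`` (exclusive of the very last window so that the stride-1
    count is exactly ``T - tau``).  Every slice inherits the trial label.
    """
    t = z.n_samples
    if tau < 1:
        raise ValueError("slice length tau must be >= 1")
    if tau >= t:
        raise ValueError(f"slice length tau = {tau} must be < T = {t}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return [
        TimeSlice(
            values=z.values[:, off : off + tau].copy(),
            label=z.label,
            trial_id=z.trial_id,
            offset=off,
        )
        for off in range(0, t - tau, stride)
    ]
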