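"""Common spatial patterns per frequency band.

CSP finds spatial filters w maximizing the band-power ratio between two
classes,

    argmax_w  (w' C1 w) / (w' C2 w),

solved here as the generalized eigenproblem ``C1 w = lambda (C1 + C2) w``
via whitening of the composite covariance.  Eigenvalues lie in [0, 1]; the
filters kept are the eigenvectors of the m largest and m smallest
eigenvalues (most discriminative in either direction).  With more than two
classes, a one-versus-rest (OVR) filter set is fitted per class and band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data import Trial, TrialSet
from .filterbank import FilterBank, apply_filter_bank

__all__ = [
    "CovarianceEstimate",
    "CSPFilterSet",
    "FeatureSeries",
    "class_covariance",
    "fit_csp",
    "fit_fbcsp",
    "project",
    "project_trialset",
    "logvar_features",
]


@dataclass
class CovarianceEstimate:
    """Average normalized spatial covariance of one class in one band."""

    matrix: np.ndarray
    class_id: int | None = None
    band_index: int | None = None
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance must be square")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("covariance contains non-finite values")


@dataclass
class CSPFilterSet:
    """Spatial filters for one band (and OVR class, if multi-class).

    ``projection`` has shape (M, N): M = 2m rows, each a spatial filter
    normalized so that w' (C1 + C2) w = 1.  ``eigenvalues`` is the full
    descending spectrum of the whitened problem.
    """

    projection: np.ndarray
    eigenvalues: np.ndarray
    m: int
    band_index: int | None = None
    ovr_class: int | None = None

    @property
    def n_filters(self) -> int:
        return self.projection.shape[0]


@dataclass
class FeatureSeries:
    """Stacked spatial-frequency feature time series Z (D x T) for one trial.

    ``layout`` names each row as (band_index, ovr_class, component) so that
    features remain self-describing after stacking across filter sets.
    """

    values: np.ndarray
    label: int
    trial_id: str = ""
    layout: list[tuple[int | None, int | None, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (rows x time)")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _trial_covariance(data: np.ndarray) -> np.ndarray:
    """Channel-centered covariance X X' normalized by its trace."""
    x = data - data.mean(axis=1, keepdims=True)
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        # all-zero trial: return the zero matrix rather than dividing by 0
        return c
    return c / tr


def class_covariance(trials: list[Trial], class_id: int) -> CovarianceEstimate:
    """Average trace-normalized covariance over the trials of one class.

    Each trial is mean-centered per channel; each per-trial covariance is
    normalized by its trace (removing the trial-amplitude confound) before
    averaging.
    """
    members = [t for t in trials if t.label == class_id]
    if not members:
        raise ValueError(f"no trials of class {class_id}")
    covs = np.stack([_trial_covariance(t.data) for t in members])
    return CovarianceEstimate(
        matrix=covs.mean(axis=0), class_id=class_id, n_trials=len(members)
    )


def _shrink(c: np.ndarray, gamma: float) -> np.ndarray:
    n = c.shape[0]
    return (1.0 - gamma) * c + gamma * (np.trace(c) / n) * np.eye(n)


def fit_csp(
    c1: CovarianceEstimate,
    c2: CovarianceEstimate,
    m: int,
    shrinkage: float = 1e-6,
    band_index: int | None = None,
    ovr_class: int | None = None,
) -> CSPFilterSet:
    """Fit CSP filters from two class covariances.

    Solves ``C1 w = lambda (C1 + C2) w`` by whitening the composite
    ``C1 + C2`` and eigendecomposing the whitened C1; eigenvalues therefore
    lie in [0, 1] and are returned sorted descending.  The projection keeps
    the eigenvectors of the ``m`` largest and ``m`` smallest eigenvalues, in
    that order, each scaled so that ``w' (C1 + C2) w = 1`` and signed so its
    largest-magnitude coefficient is positive.
    """
    a = np.asarray(c1.matrix, float)
    b = np.asarray(c2.matrix, float)
    if a.shape != b.shape:
        raise ValueError("covariances must have the same shape")
    n = a.shape[0]
    if 2 * m > n:
        raise ValueError(f"2m = {2 * m} exceeds channel count N = {n}")
    composite = _shrink(a + b, shrinkage)
    try:
        # eigh on the definite pencil (C1, C1+C2) is the whitening solution
        lam, vecs = scipy.linalg.eigh(_shrink(a, shrinkage), composite)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "composite covariance is singular even after regularization"
        ) from exc
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, 1.0)
    vecs = vecs[:, order]  # columns already satisfy v' (C1+C2) v = 1
    keep = list(range(m)) + list(range(n - m, n))
    w = vecs[:, keep].T.copy()
    # deterministic sign: largest-magnitude coefficient positive
    for row in w:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return CSPFilterSet(
        projection=w,
        eigenvalues=lam,
        m=m,
        band_index=band_index,
        ovr_class=ovr_class,
    )


def band_filtered_trials(ts: TrialSet, bank: FilterBank) -> list[list[Trial]]:
    """Per-band lists of band-passed trials: result[band][trial]."""
    per_trial = [apply_filter_bank(t, bank, ts.sample_rate_hz) for t in ts.trials]
    return [[per_trial[i][b] for i in range(len(ts))] for b in range(len(bank))]


def fit_fbcsp(
    ts: TrialSet,
    bank: FilterBank,
    m: int,
    shrinkage: float = 1e-6,
) -> list[CSPFilterSet]:
    """Fit one CSP filter set per band (two classes) or per band and OVR class.

    With two classes a single binary set is fitted per band
    (``ovr_class=None``).  With more, each class is contrasted against the
    trial-count-weighted pool of all other classes.  Ordering is band-major,
    then class order of ``ts.class_set``.
    """
    classes = list(ts.class_set)
    if len(classes) < 2:
        raise ValueError("need at least two classes for CSP")
    by_band = band_filtered_trials(ts, bank)
    sets: list[CSPFilterSet] = []
    for b, trials_b in enumerate(by_band):
        covs = {c: class_covariance(trials_b, c) for c in classes}
        for cov in covs.values():
            cov.band_index = b
        if len(classes) == 2:
            sets.append(
                fit_csp(covs[classes[0]], covs[classes[1]], m,
                        shrinkage=shrinkage, band_index=b, ovr_class=None)
            )
        else:
            counts = {c: covs[c].n_trials for c in classes}
            for c in classes:
                rest = [r for r in classes if r != c]
                wts = np.array([counts[r] for r in rest], float)
                wts /= wts.sum()
                pooled = sum(w * covs[r].matrix for w, r in zip(wts, rest))
                rest_cov = CovarianceEstimate(
                    matrix=pooled, class_id=None, band_index=b,
                    n_trials=int(sum(counts[r] for r in rest)),
                )
                sets.append(
                    fit_csp(covs[c], rest_cov, m, shrinkage=shrinkage,
                            band_index=b, ovr_class=c)
                )
    return sets


def project(
    band_trials: list[Trial],
    filter_sets: list[CSPFilterSet],
    trial_id: str = "",
) -> FeatureSeries:
    """Spatially filter one trial's band-passed versions: Z = w* X per set.

    ``band_trials`` holds the trial once per band, indexed by the filter
    sets' ``band_index``.  Rows of all sets are stacked in filter-set order
    and the layout records (band, ovr_class, component) per row.
    """
    if not filter_sets:
        raise ValueError("no filter sets given")
    blocks, layout = [], []
    label = band_trials[0].label
    for fs in filter_sets:
        b = fs.band_index if fs.band_index is not None else 0
        if b >= len(band_trials):
            raise ValueError(
                f"filter set expects band {b} but only {len(band_trials)} "
                "band-filtered trials were given"
            )
        x = band_trials[b].data
        if x.shape[0] != fs.projection.shape[1]:
            raise ValueError(
                f"channel count {x.shape[0]} does not match filter width "
                f"{fs.projection.shape[1]}"
            )
        x = x - x.mean(axis=1, keepdims=True)
        blocks.append(fs.projection @ x)
        layout.extend(
            (fs.band_index, fs.ovr_class, k) for k in range(fs.n_filters)
        )
    return FeatureSeries(
        values=np.vstack(blocks), label=label, trial_id=trial_id, layout=layout
    )


def project_trialset(
    ts: TrialSet, bank: FilterBank, filter_sets: list[CSPFilterSet]
) -> list[FeatureSeries]:
    """Project every trial of a set through the fitted filter bank + CSP."""
    out = []
    for i, tr in enumerate(ts.trials):
        bt = apply_filter_bank(tr, bank, ts.sample_rate_hz)
        out.append(project(bt, filter_sets, trial_id=str(i)))
    return out


def logvar_features(
    z: FeatureSeries,
    filter_sets: list[CSPFilterSet] | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Log band-power feature vector: log of each row's variance.

    With ``normalize`` (default) each variance is divided by the summed
    variance of its own filter set before the log — the standard CSP
    feature, invariant to per-set amplitude scaling.  Zero variances are
    floored at machine epsilon.
    """
    if z.n_samples < 2:
        raise ValueError("need at least two samples to compute variance")
    v = z.values.var(axis=1, ddof=0)
    if normalize:
        # group rows by (band, ovr_class) from the layout; fall back to one group
        if z.layout and len(z.layout) == len(v):
            groups: dict[tuple, list[int]] = {}
            for i, (band, ovr, _) in enumerate(z.layout):
                groups.setdefault((band, ovr), []).append(i)
        else:
            groups = {(None, None): list(range(len(v)))}
        out = np.empty_like(v)
        for idx in groups.values():
            s = v[idx].sum()
            out[idx] = v[idx] / s if s > 0 else 1.0 / len(idx)
        v = out
    return np.log(np.maximum(v, np.finfo(float).eps))
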