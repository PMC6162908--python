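"""Baselines, error metrics and the paired-comparison protocol.

Per-subject misclassification rates (%) of two methods are compared with a
classical paired Student t-test on the per-subject differences; kernel SVMs
on log-variance CSP band-power features serve as the shallow baselines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "EvalReport",
    "svm_baseline",
    "misclassification_rate",
    "rate_variance",
    "paired_ttest",
]

SVM_KERNELS = ("linear", "polynomial", "rbf")


@dataclass
class EvalReport:
    """Per-subject error rates of one method plus cross-method p-values."""

    method: str
    subject_error_pct: dict[str, float] = field(default_factory=dict)
    subject_variance: dict[str, float] = field(default_factory=dict)
    onhl: int | None = None
    ttest_p_values: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        for v in self.subject_error_pct.values():
            if not 0 <= v <= 100:
                raise ValueError(f"error rate {v} outside [0, 100]")
        for p in self.ttest_p_values.values():
            if not 0 <= p <= 1:
                raise ValueError(f"p-value {p} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        subjects = sorted(self.subject_error_pct)
        return pd.DataFrame(
            {
                "subject": subjects,
                "method": self.method,
                "error_pct": [self.subject_error_pct[s] for s in subjects],
                "variance": [self.subject_variance.get(s, np.nan) for s in subjects],
                "onhl": self.onhl,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        errs = list(self.subject_error_pct.values())
        summary = {
            "method": self.method,
            "onhl": self.onhl,
            "mean_error_pct": float(np.mean(errs)) if errs else None,
            "subjects": self.subject_error_pct,
            "variances": self.subject_variance,
            "ttest_p_values": self.ttest_p_values,
            "params": self.params,
        }
        with open(path, "w") as f:
            json.dump(summary, f, indent=2)


def misclassification_rate(predicted, true) -> float:
    """Percentage of mismatching labels: 100 * (#wrong / n)."""
    p = np.asarray(predicted)
    t = np.asarray(true)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty label arrays")
    return float(100.0 * np.mean(p != t))


def rate_variance(per_fold_rates) -> float:
    """Sample variance of per-fold (or per-session) error rates."""
    r = np.asarray(per_fold_rates, float)
    if r.size < 2:
        return 0.0
    return float(np.var(r, ddof=1))


def svm_baseline(
    features: np.ndarray,
    labels,
    kernel: str = "rbf",
    folds: int = 5,
    C: float = 1.0,
    degree: int = 3,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Cross-validated error (%) of a kernel SVM on band-power features.

    Multi-class problems are handled one-versus-rest, consistent with the
    OVR CSP extension.  gamma follows sklearn's ``"scale"``
    (1 / (D * feature variance)).  Returns the mean error and the per-fold
    error rates (their sample variance is the reported variance).
    """
    if kernel not in SVM_KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {SVM_KERNELS}")
    x = np.asarray(features, float)
    y = np.asarray(labels)
    sk_kernel = {"linear": "linear", "polynomial": "poly", "rbf": "rbf"}[kernel]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_rates = []
    for tr, te in skf.split(x, y):
        clf = SVC(
            kernel=sk_kernel, C=C, degree=degree, gamma="scale",
            decision_function_shape="ovr",
        )
        clf.fit(x[tr], y[tr])
        fold_rates.append(misclassification_rate(clf.predict(x[te]), y[te]))
    fold_rates = np.array(fold_rates)
    return float(fold_rates.mean()), fold_rates


def paired_ttest(rates_a, rates_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject error rates.

    Returns ``(t, p)`` with ``t`` the classical paired statistic on the
    differences and ``p`` the two-sided Student-t tail with n-1 degrees of
    freedom.  Degenerate case (zero-variance differences): p = 1 when the
    mean difference is 0, otherwise p = 0 (the methods differ by an exact
    constant).
    """
    a = np.asarray(rates_a, float)
    b = np.asarray(rates_b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        return (0.0, 1.0) if d.mean() == 0.0 else (np.inf, 0.0)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 1))
    return t, p
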