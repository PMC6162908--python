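"""End-to-end pipeline: filter bank -> CSP -> cropping -> recurrent classifier.

:func:`run_pipeline` wires the four stages together on a labelled TrialSet:
band-pass filtering through the bank, FB-CSP fitting on the training split,
projection to spatial-frequency feature series, optional causal smoothing,
sliding-window cropping, recurrent-network training, and per-trial
prediction on the validation split by averaging slice probabilities.  The
result carries the misclassification rate, the training trace, and a
machine-readable provenance record (config hash, seed, band list, feature
layout).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .csp import CSPFilterSet, fit_fbcsp, project_trialset
from .data import TrialSet
from .filterbank import BandSpec, FilterBank, default_filter_bank
from .rnn import (
    RNNConfig, RNNModel, TrainingTrace, init_model, predict_trial,
    sweep_depth, train,
)
from .sequential import crop_slices, smooth
from .evalstats import misclassification_rate

logger = logging.getLogger("mibci")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "split_trialset",
    "run_pipeline",
    "save_model",
    "load_model",
    "save_filter_sets",
    "load_filter_sets",
]


@dataclass
class PipelineConfig:
    """Everything one run needs; every random stage derives from ``seed``."""

    m: int = 1                       # CSP filter pairs per set
    bands_hz: list | None = None     # None -> the default ten-band bank
    band_order: int = 4
    omega: int = 0                   # smoothing window (0 = off)
    tau: int = 20                    # slice length / unroll depth
    tau_grid: list[int] | None = None  # when set, sweep overrides tau
    train_stride: int = 1
    eval_stride: int = 1
    rnn: RNNConfig = field(default_factory=RNNConfig)
    val_fraction: float = 0.5
    seed: int = 0

    def validate(self, n_samples: int | None = None) -> None:
        if self.m < 1 or self.omega < 0:
            raise ValueError("m must be >= 1 and omega >= 0")
        if self.train_stride < 1 or self.eval_stride < 1:
            raise ValueError("strides must be >= 1")
        taus = self.tau_grid if self.tau_grid else [self.tau]
        for t in taus:
            if t < 1:
                raise ValueError("tau must be >= 1")
            if n_samples is not None and t >= n_samples:
                raise ValueError(
                    f"tau = {t} must be smaller than the trial length "
                    f"T = {n_samples}"
                )

    def provenance(self, layout=None) -> dict:
        cfg = dataclasses.asdict(self)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "bands_hz": self.bands_hz or "default-10-band-8-30Hz",
            "feature_layout": layout,
        }


@dataclass
class PipelineResult:
    error_pct: float
    accuracy: float
    tau: int
    model: RNNModel
    trace: TrainingTrace
    filter_sets: list[CSPFilterSet]
    predictions: list[int]
    true_labels: list[int]
    sweep_records: dict | None
    provenance: dict


def split_trialset(ts: TrialSet, val_fraction: float = 0.5, seed: int = 0):
    """Train/validation split of a TrialSet.

    When trials carry at least two distinct non-empty session ids, the
    first session (sorted order) trains and the rest validate — the
    two-session evaluation protocol.  Otherwise a seeded stratified split
    holds out ``val_fraction`` of each class.
    """
    sessions = sorted({t.session_id for t in ts.trials if t.session_id})
    if len(sessions) >= 2:
        tr = [i for i, t in enumerate(ts.trials) if t.session_id == sessions[0]]
        va = [i for i, t in enumerate(ts.trials) if t.session_id != sessions[0]]
        return ts.subset(tr), ts.subset(va)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    labels = ts.labels()
    tr_idx, va_idx = [], []
    for c in ts.class_set:
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_val = int(round(val_fraction * len(idx)))
        va_idx.extend(idx[:n_val])
        tr_idx.extend(idx[n_val:])
    return ts.subset(sorted(tr_idx)), ts.subset(sorted(va_idx))


def run_pipeline(ts: TrialSet, cfg: PipelineConfig) -> PipelineResult:
    """Run the full classification pipeline on an epoched TrialSet."""
    cfg.validate(n_samples=ts.n_samples)
    if cfg.bands_hz:
        bank = FilterBank(
            [BandSpec(lo, hi, cfg.band_order) for lo, hi in cfg.bands_hz],
            ts.sample_rate_hz,
        )
    else:
        bank = default_filter_bank(ts.sample_rate_hz, cfg.band_order)
    train_ts, val_ts = split_trialset(ts, cfg.val_fraction, cfg.seed)
    logger.info(
        "split: %d training / %d validation trials, %d bands, m=%d",
        len(train_ts), len(val_ts), len(bank), cfg.m,
    )
    filter_sets = fit_fbcsp(train_ts, bank, cfg.m)
    feats_tr = project_trialset(train_ts, bank, filter_sets)
    feats_va = project_trialset(val_ts, bank, filter_sets)
    if cfg.omega > 0:
        feats_tr = [smooth(f, cfg.omega) for f in feats_tr]
        feats_va = [smooth(f, cfg.omega) for f in feats_va]
    rnn_cfg = dataclasses.replace(cfg.rnn, seed=cfg.seed)
    sweep_records = None
    if cfg.tau_grid:
        tau, sweep_records = sweep_depth(
            feats_tr, feats_va, cfg.tau_grid, rnn_cfg,
            train_stride=cfg.train_stride, eval_stride=cfg.eval_stride,
        )
        logger.info("depth sweep chose tau = %d", tau)
    else:
        tau = cfg.tau
    rnn_cfg = dataclasses.replace(rnn_cfg, unroll_len=tau)
    class_order = list(ts.class_set)
    layout = feats_tr[0].layout
    tr_slices = [
        s for f in feats_tr for s in crop_slices(f, tau, cfg.train_stride)
    ]
    va_slices = [
        s for f in feats_va for s in crop_slices(f, tau, cfg.eval_stride)
    ]
    model = init_model(
        rnn_cfg, feats_tr[0].n_rows, n_classes=len(class_order),
        class_order=class_order, layout=layout,
    )
    logger.info(
        "training %s on %d slices (D=%d, tau=%d, H=%d, %d epochs)",
        rnn_cfg.cell, len(tr_slices), feats_tr[0].n_rows, tau,
        rnn_cfg.hidden_width, rnn_cfg.max_iterations,
    )
    model, trace = train(model, tr_slices, va_slices, rnn_cfg)
    preds, truth = [], []
    for f in feats_va:
        agg = predict_trial(model, f, tau, stride=cfg.eval_stride)
        preds.append(agg.final_label)
        truth.append(f.label)
    err = misclassification_rate(preds, truth)
    logger.info("validation error %.2f%% over %d trials", err, len(truth))
    return PipelineResult(
        error_pct=err,
        accuracy=100.0 - err,
        tau=tau,
        model=model,
        trace=trace,
        filter_sets=filter_sets,
        predictions=preds,
        true_labels=truth,
        sweep_records=sweep_records,
        provenance=cfg.provenance(layout=[list(row) for row in layout]),
    )


# -------------------------------------------------------------- serialization

def save_model(model: RNNModel, path) -> None:
    """Persist an RNN model (weights + config + layout) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(dataclasses.asdict(model.cfg))
        f.attrs["n_inputs"] = model.n_inputs
        f.attrs["n_outputs"] = model.n_outputs
        if model.class_order is not None:
            f.attrs["class_order"] = np.asarray(model.class_order, np.int64)
        if model.layout is not None:
            f.attrs["layout"] = json.dumps(
                [list(row) for row in model.layout]
            )
        g = f.create_group("params")
        for k, v in model.params.items():
            g.create_dataset(k, data=v)


def load_model(path) -> RNNModel:
    with h5py.File(path, "r") as f:
        cfg = RNNConfig(**json.loads(f.attrs["config"]))
        params = {k: f["params"][k][()] for k in f["params"]}
        class_order = (
            [int(c) for c in f.attrs["class_order"]]
            if "class_order" in f.attrs else None
        )
        layout = (
            [tuple(row) for row in json.loads(f.attrs["layout"])]
            if "layout" in f.attrs else None
        )
        return RNNModel(
            cfg=cfg, params=params,
            n_inputs=int(f.attrs["n_inputs"]),
            n_outputs=int(f.attrs["n_outputs"]),
            class_order=class_order, layout=layout,
        )


def save_filter_sets(sets: list[CSPFilterSet], path) -> None:
    """Persist fitted CSP filter sets (plus row layout) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        for i, fs in enumerate(sets):
            g = f.create_group(f"set_{i:04d}")
            g.create_dataset("projection", data=fs.projection)
            g.create_dataset("eigenvalues", data=fs.eigenvalues)
            g.attrs["m"] = fs.m
            g.attrs["band_index"] = -1 if fs.band_index is None else fs.band_index
            g.attrs["ovr_class"] = -1 if fs.ovr_class is None else fs.ovr_class


def load_filter_sets(path) -> list[CSPFilterSet]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f):
            g = f[key]
            band = int(g.attrs["band_index"])
            ovr = int(g.attrs["ovr_class"])
            out.append(
                CSPFilterSet(
                    projection=g["projection"][()],
                    eigenvalues=g["eigenvalues"][()],
                    m=int(g.attrs["m"]),
                    band_index=None if band < 0 else band,
                    ovr_class=None if ovr < 0 else ovr,
                )
            )
    return out
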