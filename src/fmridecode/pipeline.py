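"""End-to-end decoding pipeline and session-wise cross-validation.

Ties the stages together the way the decoding study ran them: smooth,
mask, build one linear kernel over the concatenated sessions, detrend it in
kernel space with a per-run DCT residual-forming matrix, slice train/test
blocks, fit KRR or RVR (or evidence-tuned KRR), post-process the prediction
through the HRF pipeline, and score held-out sessions with Fisher-
transformed Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import hrf as hrf_mod
from .kernels import (
    KernelMatrix,
    apply_region_mask,
    detrend_kernel,
    linear_kernel,
    median_heuristic_gamma,
    polynomial_from_linear,
    rbf_from_linear,
)
from .preprocess import (
    MaskVolume,
    TimeSeriesMatrix,
    apply_mask,
    build_dct_basis,
    smooth_volumes,
)
from .regression import fit_krr, fit_rvr, optimize_evidence, predict_kernel_model
from .scoring import ScoreTable, pearson_r
from .synth import SyntheticDataset

__all__ = ["PipelineConfig", "cross_validate", "decode_split"]

_KERNEL_KINDS = ("linear", "rbf", "polynomial")
_METHODS = ("krr", "rvr", "evidence")


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated configuration of the full decoding pipeline."""

    # preprocessing
    fwhm_mm: float = 6.0
    dct_bases: int = 8
    per_run: bool = True
    mask_path: str | None = None
    region_mask_path: str | None = None
    # kernel
    kernel_kind: str = "linear"
    gamma: float | None = None  # None -> median heuristic on the training block
    theta: float = 0.0
    degree: int = 2
    # model
    method: str = "krr"
    lam: float = 1.0
    lam_grid: list[float] | None = None
    include_constant: bool = False
    # post-processing
    deconvolve: bool = True
    fwhm_tr: float = 3.0
    shift: int = 0
    match_filter: bool = False
    match_filter_events: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_kind not in _KERNEL_KINDS:
            raise ValueError(f"kernel_kind must be one of {_KERNEL_KINDS}")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.fwhm_mm < 0 or self.fwhm_tr < 0:
            raise ValueError("FWHM values must be >= 0")
        if self.dct_bases < 0:
            raise ValueError("dct_bases must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys(dict(d), set(cls.__dataclass_fields__), "pipeline")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _nonlinear(
    K_lin_block: KernelMatrix,
    diag_rows: np.ndarray,
    diag_cols: np.ndarray,
    cfg: PipelineConfig,
    gamma: float,
) -> np.ndarray:
    if cfg.kernel_kind == "linear":
        return K_lin_block.values
    if cfg.kernel_kind == "rbf":
        return rbf_from_linear(K_lin_block, gamma, diag_rows, diag_cols).values
    return polynomial_from_linear(K_lin_block, cfg.theta, cfg.degree).values


def _fit_and_predict(
    K_tt: KernelMatrix,
    K_st: KernelMatrix,
    t_train: np.ndarray,
    cfg: PipelineConfig,
    lam: float,
):
    if cfg.method == "rvr":
        model = fit_rvr(K_tt, t_train)
    elif cfg.method == "evidence":
        hp = optimize_evidence(
            K_tt, t_train, include_constant=cfg.include_constant, seed=cfg.seed
        )
        model = fit_krr(K_tt, t_train, hp.ridge_lambda)
    else:
        model = fit_krr(K_tt, t_train, lam)
    return predict_kernel_model(model, K_st), model


def _postprocess(
    pred: np.ndarray,
    cfg: PipelineConfig,
    tr_seconds: float,
    template: np.ndarray | None,
) -> np.ndarray:
    if cfg.shift != 0:
        pred = hrf_mod.inverse_shift(pred, cfg.shift)
    if cfg.deconvolve:
        H = hrf_mod.convolution_matrix(
            hrf_mod.canonical_hrf(tr_seconds), pred.shape[0]
        )
        z = hrf_mod.deconvolve_constrained(pred, H)
        pred = hrf_mod.reconvolve_smooth(z, H, cfg.fwhm_tr)
    if cfg.match_filter:
        if template is None:
            raise ValueError("match filtering requires a training-derived template")
        pred, _ = hrf_mod.match_filter_insert(pred, template, cfg.match_filter_events)
    return pred


def decode_split(
    K: KernelMatrix,
    tsm_diag_linear: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    target: np.ndarray,
    cfg: PipelineConfig,
    tr_seconds: float,
    template: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Fit on the training scans, predict and post-process the held-out scans.

    ``K`` is the full (already detrended) linear kernel over train+test;
    blocks are sliced from it.  Returns the final prediction and its Pearson
    correlation against the held-out target.
    """
    K_tt_lin = K.block(train_idx, train_idx)
    K_st_lin = K.block(test_idx, train_idx)
    gamma = cfg.gamma
    if cfg.kernel_kind == "rbf" and gamma is None:
        gamma = median_heuristic_gamma(K_tt_lin)
    d = tsm_diag_linear
    K_tt = KernelMatrix(
        _nonlinear(K_tt_lin, d[train_idx], d[train_idx], cfg, gamma or 1.0),
        kind=cfg.kernel_kind,
    )
    K_st = KernelMatrix(
        _nonlinear(K_st_lin, d[test_idx], d[train_idx], cfg, gamma or 1.0),
        kind=cfg.kernel_kind,
    )

    t_train = target[train_idx]
    if cfg.shift != 0:
        t_train = hrf_mod.temporal_shift(t_train, cfg.shift)
    t_test = target[test_idx]

    lams = cfg.lam_grid if (cfg.method == "krr" and cfg.lam_grid) else [cfg.lam]
    best = None
    for lam in lams:
        pred, _ = _fit_and_predict(K_tt, K_st, t_train, cfg, lam)
        pred = _postprocess(pred, cfg, tr_seconds, template)
        r = pearson_r(pred, t_test)
        if best is None or r > best[1]:
            best = (pred, r)
    return best


def _split_template(
    dataset: SyntheticDataset, rating_idx: int, train_runs: list[int]
) -> np.ndarray:
    """Average event template from the convolved training-session ratings."""
    t = dataset.convolved_ratings[rating_idx]
    segments = [
        t[start:stop]
        for run, (start, stop) in enumerate(dataset.run_boundaries)
        if run in train_runs
    ]
    peak = max(seg.max() for seg in segments)
    return hrf_mod.build_spike_template(segments, threshold=0.05 * peak)


def cross_validate(dataset: SyntheticDataset, cfg: PipelineConfig) -> ScoreTable:
    """Leave-one-run-out cross-validation over every rating.

    For each held-out run the model is fitted on the remaining runs (with
    2 runs this is exactly train-on-1/test-on-2 and vice versa), predictions
    are post-processed per the config, and scored against the held-out
    convolved rating.
    """
    n_runs = len(dataset.run_boundaries)
    if n_runs < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    cfgd = dataset.config

    volumes = smooth_volumes(dataset.volumes, cfg.fwhm_mm, cfgd.voxel_size_mm)
    tsm = apply_mask(volumes, dataset.gm_mask, dataset.run_boundaries)
    if cfg.region_mask_path is not None:
        from .io import load_mask

        tsm = apply_region_mask(tsm, load_mask(cfg.region_mask_path))

    K_lin = linear_kernel(tsm)
    if cfg.dct_bases > 0:
        drift = build_dct_basis(
            tsm.n_scans,
            cfg.dct_bases,
            dataset.run_boundaries if cfg.per_run else None,
        )
        K = detrend_kernel(K_lin, drift.R)
    else:
        K = K_lin
    diag = np.diag(K.values).copy()

    table = ScoreTable()
    for r_idx, name in enumerate(dataset.rating_names):
        target = dataset.convolved_ratings[r_idx]
        for test_run in range(n_runs):
            train_runs = [r for r in range(n_runs) if r != test_run]
            train_idx = np.concatenate(
                [np.arange(*dataset.run_boundaries[r]) for r in train_runs]
            )
            test_idx = np.arange(*dataset.run_boundaries[test_run])
            template = (
                _split_template(dataset, r_idx, train_runs) if cfg.match_filter else None
            )
            _, r = decode_split(
                K, diag, train_idx, test_idx, target, cfg, cfgd.tr_seconds, template
            )
            table.add(name, "+".join(map(str, train_runs)), test_run, r)
    return table
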