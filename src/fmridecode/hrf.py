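"""Hemodynamic response modeling and HRF-aware post-processing.

The decoding target is a raw rating z_raw in [0,1] convolved with the
canonical double-gamma HRF, t = H z_raw, where H is a lower-triangular
Toeplitz matrix of HRF samples.  Knowing the box constraint on z_raw lets a
prediction t* be refined: deconvolve it as a box-constrained least-squares
problem (a convex QP), re-convolve the feasible solution, and smooth the
result; this projects the prediction onto the manifold of signals an
admissible rating could actually have produced.

Two further refinements mirror common decoding practice: discrete temporal
shifts of the training target (with inverse shifting of predictions) to
absorb non-canonical hemodynamic delays, and match-filter reconstruction of
stereotyped event ratings (cross-correlate with an average event template,
pick the best-fitting lags, and re-insert the template).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage, optimize
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HRFKernel",
    "ConvolutionMatrix",
    "RatingSeries",
    "canonical_hrf",
    "convolution_matrix",
    "deconvolve_constrained",
    "reconvolve_smooth",
    "temporal_shift",
    "inverse_shift",
    "build_spike_template",
    "match_filter_insert",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class HRFKernel:
    """Canonical HRF sampled at the repetition time, peak-normalized to 1."""

    samples: np.ndarray
    tr_seconds: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        peak = np.abs(self.samples).max()
        if abs(self.samples[0]) > 1e-3 * peak:
            raise ValueError("HRF must start at (approximately) zero")


@dataclass
class ConvolutionMatrix:
    """Lower-triangular Toeplitz matrix implementing causal HRF convolution."""

    H: np.ndarray

    @property
    def n_scans(self) -> int:
        return self.H.shape[0]


def canonical_hrf(
    tr_seconds: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration: float = 32.0,
) -> HRFKernel:
    """Canonical double-gamma HRF sampled at the TR.

    Difference of two gamma densities: a positive response peaking near
    ``peak_delay`` seconds minus ``undershoot_ratio`` times an undershoot
    peaking near ``undershoot_delay`` seconds, over ``duration`` seconds of
    support.  The result is normalized so its peak equals 1, preserving the
    amplitude scale of [0,1] ratings under convolution.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be > 0")
    if peak_dispersion <= 0 or undershoot_dispersion <= 0:
        raise ValueError("dispersions must be > 0")
    if duration < peak_delay:
        raise ValueError("duration must cover the response peak")
    t = np.arange(0.0, duration + 0.5 * tr_seconds, tr_seconds)
    h = gamma_dist.pdf(
        t, peak_delay / peak_dispersion, scale=peak_dispersion
    ) - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    h = h / h.max()
    return HRFKernel(
        samples=h,
        tr_seconds=tr_seconds,
        params=dict(
            peak_delay=peak_delay,
            undershoot_delay=undershoot_delay,
            peak_dispersion=peak_dispersion,
            undershoot_dispersion=undershoot_dispersion,
            undershoot_ratio=undershoot_ratio,
            duration=duration,
        ),
    )


def convolution_matrix(hrf: HRFKernel, n_scans: int) -> ConvolutionMatrix:
    """Toeplitz matrix H with H[i, j] = hrf[i - j] for i >= j, else 0."""
    col = np.zeros(n_scans)
    m = min(n_scans, hrf.samples.shape[0])
    col[:m] = hrf.samples[:m]
    row = np.zeros(n_scans)
    row[0] = col[0]
    return ConvolutionMatrix(H=linalg.toeplitz(col, row))


def deconvolve_constrained(
    t_star: np.ndarray,
    conv: ConvolutionMatrix,
    tol: float = 1e-10,
) -> np.ndarray:
    """Recover a feasible raw rating: argmin_z ||Hz - t*||^2 s.t. 0 <= z <= 1.

    A convex bound-constrained least-squares problem, solved by an
    active-set method (BVLS) to KKT tolerance.  The returned z is always
    feasible (clipped against round-off at the 1e-12 level).
    """
    t_star = np.asarray(t_star, dtype=float).ravel()
    if t_star.shape[0] != conv.n_scans:
        raise ValueError("prediction length does not match convolution matrix")
    res = optimize.lsq_linear(
        conv.H, t_star, bounds=(0.0, 1.0), tol=tol, method="bvls", max_iter=3 * conv.n_scans
    )
    if res.status <= 0:
        raise RuntimeError(f"constrained deconvolution failed: {res.message}")
    return np.clip(res.x, 0.0, 1.0)


def smooth_rating(t: np.ndarray, fwhm_tr: float) -> np.ndarray:
    """1-D Gaussian smoothing (FWHM in scans) with renormalized edges."""
    if fwhm_tr < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_tr == 0:
        return np.asarray(t, dtype=float).copy()
    sigma = fwhm_tr * FWHM_TO_SIGMA
    num = ndimage.gaussian_filter1d(t, sigma, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter1d(np.ones_like(t), sigma, mode="constant", cval=0.0)
    return num / den


def reconvolve_smooth(
    z_raw: np.ndarray, conv: ConvolutionMatrix, fwhm_tr: float = 3.0
) -> np.ndarray:
    """Re-convolve a deconvolved rating and smooth it (default 3-scan FWHM)."""
    z_raw = np.asarray(z_raw, dtype=float).ravel()
    if z_raw.shape[0] != conv.n_scans:
        raise ValueError("rating length does not match convolution matrix")
    return smooth_rating(conv.H @ z_raw, fwhm_tr)


def temporal_shift(v: np.ndarray, k: int) -> np.ndarray:
    """Shift a time series by k scans (k < 0 = earlier) with edge replication.

    Output sample i equals v[i - k] clamped to the valid range, so no
    spurious onsets are injected at the edges.
    """
    v = np.asarray(v, dtype=float).ravel()
    n = v.shape[0]
    if abs(k) >= n / 4:
        raise ValueError(f"|shift| {abs(k)} too large for {n} scans (must be < N/4)")
    idx = np.clip(np.arange(n) - k, 0, n - 1)
    return v[idx]


def inverse_shift(pred: np.ndarray, k: int) -> np.ndarray:
    """Undo :func:`temporal_shift`; exact except within |k| samples of the edges."""
    return temporal_shift(pred, -k)


def _spike_segments(rating: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = np.asarray(rating) > threshold
    segs = []
    in_seg = False
    start = 0
    for i, flag in enumerate(above):
        if flag and not in_seg:
            in_seg, start = True, i
        elif not flag and in_seg:
            segs.append((start, i))
            in_seg = False
    if in_seg:
        segs.append((start, len(above)))
    return segs


def build_spike_template(
    ratings: list[np.ndarray], threshold: float = 0.0
) -> np.ndarray:
    """Average event template from spiky ratings, onset-aligned, peak = 1.

    Detects contiguous supra-threshold segments in each rating, extracts a
    window of the longest segment's length from every onset, averages the
    windows, and normalizes the peak to 1.
    """
    windows = []
    seg_lists = [
        _spike_segments(np.asarray(r, dtype=float).ravel(), threshold) for r in ratings
    ]
    if any(not segs for segs in seg_lists):
        raise ValueError("a rating contains no detectable spikes")
    width = max(stop - start for segs in seg_lists for start, stop in segs)
    for r, segs in zip(ratings, seg_lists):
        r = np.asarray(r, dtype=float).ravel()
        for start, _ in segs:
            w = r[start : start + width]
            if w.shape[0] < width:
                w = np.pad(w, (0, width - w.shape[0]))
            windows.append(w)
    template = np.mean(windows, axis=0)
    return template / np.abs(template).max()


def match_filter_insert(
    pred: np.ndarray, template: np.ndarray, k_events: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct a stereotyped event rating by match filtering.

    Cross-correlates the prediction with the template, greedily selects the
    ``k_events`` highest-scoring onset lags subject to a minimum separation
    of one template length (ties broken by the earliest lag), and returns a
    zero-baseline series with the template inserted at the selected lags,
    together with the sorted lags themselves.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    template = np.asarray(template, dtype=float).ravel()
    m = template.shape[0]
    n = pred.shape[0]
    if k_events < 1:
        raise ValueError("k_events must be >= 1")
    if m >= n:
        raise ValueError("template must be shorter than the prediction")
    scores = np.correlate(pred, template, mode="valid")  # score per onset lag
    order = np.lexsort((np.arange(scores.shape[0]), -scores))
    chosen: list[int] = []
    for lag in order:
        if all(abs(lag - c) >= m for c in chosen):
            chosen.append(int(lag))
            if len(chosen) == k_events:
                break
    if len(chosen) < k_events:
        raise ValueError(
            f"only {len(chosen)} admissible lags for {k_events} events"
        )
    out = np.zeros(n)
    lags = np.sort(np.asarray(chosen))
    for lag in lags:
        out[lag : lag + m] = template[: n - lag]
    return out, lags


@dataclass
class RatingSeries:
    """A rating in its raw and HRF-convolved forms, plus a model prediction."""

    z_raw: np.ndarray | None = None
    t: np.ndarray | None = None
    t_star: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.z_raw is not None:
            z = np.asarray(self.z_raw, dtype=float)
            if z.min() < -1e-9 or z.max() > 1 + 1e-9:
                raise ValueError("raw rating must lie in [0, 1]")
            self.z_raw = z
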