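"""Spatial and temporal preprocessing of 4D fMRI volumes.

The pipeline entering the kernel machinery is: smooth each volume with a
Gaussian kernel, restrict to gray-matter voxels, and remove low-frequency
scanner drift by projecting out a discrete-cosine (DCT) basis with the
residual-forming matrix R = I - CC+.  Detrending can equivalently be applied
to the Gram matrix downstream (see :mod:`fmridecode.kernels`), which is the
cheap route when the voxel count far exceeds the scan count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "TimeSeriesMatrix",
    "DriftModel",
    "MaskVolume",
    "build_dct_basis",
    "residual_forming_matrix",
    "detrend_timeseries",
    "smooth_volumes",
    "apply_mask",
    "unmask",
    "threshold_probability_map",
]

#: Conversion factor between FWHM and standard deviation of a Gaussian.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MaskVolume:
    """Binary 3D mask restricting analysis to informative voxels."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3D array")
        uniq = np.unique(self.data)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask values must be binary (0/1)")
        self.data = self.data.astype(bool)
        if not self.data.any():
            raise ValueError("mask contains no voxels")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class TimeSeriesMatrix:
    """N scans x D voxels matrix extracted from masked volumes.

    Rows are scans in acquisition order; columns are in-mask voxels in a
    fixed raster order (x fastest, then y, then z, 0-based) so that weight
    maps can be scattered back bit-exactly.
    """

    X: np.ndarray
    voxel_index: np.ndarray  # (D, 3) integer grid coordinates per column
    grid_dims: tuple[int, int, int]
    run_boundaries: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D (scans x voxels)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.voxel_index.shape != (self.X.shape[1], 3):
            raise ValueError("voxel_index must be (D, 3)")
        if not self.run_boundaries:
            self.run_boundaries = [(0, self.X.shape[0])]

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]


@dataclass
class DriftModel:
    """Drift basis C and its residual-forming matrix R = I - CC+."""

    C: np.ndarray
    R: np.ndarray
    run_boundaries: list[tuple[int, int]] | None = None

    @property
    def n_scans(self) -> int:
        return self.R.shape[0]

    @property
    def n_bases(self) -> int:
        return self.C.shape[1]


def _dct_columns(n: int, n_bases: int) -> np.ndarray:
    """Orthonormal DCT-II basis, columns l = 0..n_bases-1 (constant included).

    Column l has entries sqrt(2/n) * cos(pi/n * (i + 1/2) * l); the l = 0
    column is scaled by 1/sqrt(2) so that G^T G = I.
    """
    i = np.arange(n)
    G = np.empty((n, n_bases))
    for l in range(n_bases):
        G[:, l] = np.cos(np.pi / n * (i + 0.5) * l)
        G[:, l] *= np.sqrt((1.0 if l == 0 else 2.0) / n)
    return G


def dct_cutoff_hz(n_scans: int, n_bases: int, tr_seconds: float) -> float:
    """Highest frequency removed by an n_bases DCT high-pass filter.

    Basis l completes l/2 cycles over the run, i.e. frequency
    l / (2 * N * TR); with the constant included the highest removed index
    is n_bases - 1.
    """
    return (n_bases - 1) / (2.0 * n_scans * tr_seconds)


def build_dct_basis(
    n_scans: int,
    n_bases: int,
    run_boundaries: list[tuple[int, int]] | None = None,
) -> DriftModel:
    """Build a DCT drift basis and its residual-forming matrix.

    Parameters
    ----------
    n_scans : total number of scans N.
    n_bases : number L of low-frequency DCT bases to remove (constant term
        included).  L = 0 yields an empty basis and R = I.
    run_boundaries : optional list of (start, stop) half-open scan ranges.
        When given, the basis is block-diagonal: each run gets its own L
        bases, and R never mixes scans across runs.
    """
    if n_bases < 0:
        raise ValueError("n_bases must be >= 0")
    if run_boundaries is None:
        run_boundaries = [(0, n_scans)]
    spans = [stop - start for start, stop in run_boundaries]
    if sum(spans) != n_scans:
        raise ValueError("run boundaries do not cover the scan range")
    if any(n_bases > span for span in spans):
        raise ValueError(f"n_bases={n_bases} exceeds a run length")

    C = np.zeros((n_scans, n_bases * len(run_boundaries)))
    R = np.zeros((n_scans, n_scans))
    for k, (start, stop) in enumerate(run_boundaries):
        span = stop - start
        G = _dct_columns(span, n_bases)
        C[start:stop, k * n_bases : (k + 1) * n_bases] = G
        R[start:stop, start:stop] = np.eye(span) - G @ G.T
    return DriftModel(C=C, R=R, run_boundaries=list(run_boundaries))


def residual_forming_matrix(C: np.ndarray) -> np.ndarray:
    """R = I - CC+ for an arbitrary drift basis C (pseudo-inverse form).

    Handles rank-deficient bases through the Moore-Penrose pseudo-inverse.
    The result is symmetric and idempotent and annihilates the column space
    of C.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ValueError("C must be 2D")
    if not np.all(np.isfinite(C)):
        raise ValueError("C contains non-finite entries")
    n = C.shape[0]
    if C.shape[1] == 0:
        return np.eye(n)
    R = np.eye(n) - C @ np.linalg.pinv(C)
    # symmetrize against round-off; R is a projector in exact arithmetic
    return 0.5 * (R + R.T)


def detrend_timeseries(tsm: TimeSeriesMatrix, drift: DriftModel) -> TimeSeriesMatrix:
    """Apply the residual-forming matrix to every voxel column: Xbar = RX."""
    if drift.n_scans != tsm.n_scans:
        raise ValueError(
            f"drift model built for {drift.n_scans} scans, data has {tsm.n_scans}"
        )
    if drift.run_boundaries is not None:
        Xbar = np.empty_like(tsm.X)
        for start, stop in drift.run_boundaries:
            Xbar[start:stop] = drift.R[start:stop, start:stop] @ tsm.X[start:stop]
    else:
        Xbar = drift.R @ tsm.X
    return TimeSeriesMatrix(
        X=Xbar,
        voxel_index=tsm.voxel_index,
        grid_dims=tsm.grid_dims,
        run_boundaries=list(tsm.run_boundaries),
    )


def smooth_volumes(
    volumes: np.ndarray,
    fwhm_mm: float | tuple[float, float, float],
    voxel_size_mm: tuple[float, float, float],
) -> np.ndarray:
    """Separable Gaussian smoothing of each volume in a 4D series.

    sigma per axis is fwhm / (voxel_size * 2*sqrt(2 ln 2)).  Boundary
    handling uses a truncated, renormalized kernel (division by the
    smoothed indicator) so interior mass is preserved and edges are not
    darkened.  fwhm = 0 on every axis is the identity.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise ValueError("expected a 4D array (x, y, z, scans)")
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be non-negative")
    if np.all(fwhm == 0):
        return volumes.copy()
    sigma_vox = fwhm * FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
    norm = ndimage.gaussian_filter(
        np.ones(volumes.shape[:3]), sigma=sigma_vox, mode="constant", cval=0.0
    )
    out = np.empty_like(volumes)
    for t in range(volumes.shape[3]):
        out[..., t] = (
            ndimage.gaussian_filter(
                volumes[..., t], sigma=sigma_vox, mode="constant", cval=0.0
            )
            / norm
        )
    return out


def _raster_order(coords: np.ndarray, grid_dims: tuple[int, int, int]) -> np.ndarray:
    """Sort (D, 3) coordinates so x varies fastest, then y, then z."""
    nx, ny, _ = grid_dims
    linear = coords[:, 0] + nx * (coords[:, 1] + ny * coords[:, 2])
    return np.argsort(linear, kind="stable")


def apply_mask(
    volumes: np.ndarray,
    mask: MaskVolume,
    run_boundaries: list[tuple[int, int]] | None = None,
) -> TimeSeriesMatrix:
    """Extract the scans x voxels matrix of in-mask voxel time series."""
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise ValueError("expected a 4D array (x, y, z, scans)")
    if volumes.shape[:3] != mask.grid_dims:
        raise ValueError(
            f"grid mismatch: volumes {volumes.shape[:3]} vs mask {mask.grid_dims}"
        )
    coords = np.argwhere(mask.data)
    if coords.size == 0:
        raise ValueError("empty mask")
    coords = coords[_raster_order(coords, mask.grid_dims)]
    X = volumes[coords[:, 0], coords[:, 1], coords[:, 2], :].T
    return TimeSeriesMatrix(
        X=X,
        voxel_index=coords,
        grid_dims=mask.grid_dims,
        run_boundaries=run_boundaries or [],
    )


def unmask(
    values: np.ndarray,
    voxel_index: np.ndarray,
    grid_dims: tuple[int, int, int],
) -> np.ndarray:
    """Scatter a per-voxel vector back onto its 3D grid (zeros elsewhere)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != voxel_index.shape[0]:
        raise ValueError("value count does not match voxel index")
    out = np.zeros(grid_dims)
    out[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = values
    return out


def threshold_probability_map(
    pmap: np.ndarray,
    threshold: float = 0.3,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> MaskVolume:
    """Binarize a probabilistic (e.g. cytoarchitectonic) map.

    Uses a strict inequality: voxels with probability > threshold are kept.
    The 0.3 default matches the threshold used to turn warped probability
    maps of functional regions into binary masks.
    """
    pmap = np.asarray(pmap, dtype=float)
    if pmap.min() < 0 or pmap.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = pmap > threshold
    if not mask.any():
        raise ValueError(f"threshold {threshold} yields an empty mask")
    return MaskVolume(data=mask.astype(np.uint8), voxel_size_mm=voxel_size_mm)
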