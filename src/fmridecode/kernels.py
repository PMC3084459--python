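"""Kernel construction and kernel-space detrending.

A kernel is a matrix of similarity measures between pairs of scans.  With a
linear kernel K = XX^T, drift removal commutes with the Gram product:
detrending every voxel time series with the residual-forming matrix R and
then forming the kernel equals forming the kernel first and computing
R^T K R.  Since the voxel count D typically dwarfs the scan count N, the
kernel-space route is enormously cheaper.  Non-linear (RBF, polynomial)
kernels are derived from the (detrended) linear kernel entries, so the
nonlinearity is applied after drift removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import MaskVolume, TimeSeriesMatrix

__all__ = [
    "KernelMatrix",
    "KernelParams",
    "linear_kernel",
    "detrend_kernel",
    "rbf_from_linear",
    "polynomial_from_linear",
    "apply_region_mask",
    "median_heuristic_gamma",
]

_PSD_TOL = 1e-8


@dataclass
class KernelParams:
    """Functional parameters of the non-linear kernels."""

    gamma: float = 1.0  # RBF width
    theta: float = 0.0  # polynomial offset
    degree: int = 1  # polynomial degree

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


@dataclass
class KernelMatrix:
    values: np.ndarray
    kind: str = "linear"  # linear | rbf | polynomial
    row_ids: np.ndarray | None = None
    col_ids: np.ndarray | None = None
    detrended: bool = False
    params: KernelParams | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kernel values must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel contains non-finite entries")
        if self.row_ids is None:
            self.row_ids = np.arange(self.values.shape[0])
        if self.col_ids is None:
            self.col_ids = np.arange(self.values.shape[1])

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]

    def check_psd(self, tol: float = _PSD_TOL) -> None:
        """Verify symmetry and positive semidefiniteness of a square kernel."""
        if not self.is_square:
            raise ValueError("PSD check requires a square kernel")
        K = self.values
        if np.abs(K - K.T).max() >= 1e-10 * max(1.0, np.abs(K).max()):
            raise ValueError("square kernel is not symmetric")
        w = np.linalg.eigvalsh(0.5 * (K + K.T))
        floor = -tol * max(w.max(), 1e-30)
        if w.min() < floor:
            raise ValueError(f"kernel not PSD: min eigenvalue {w.min():.3e}")

    def block(self, rows: slice | np.ndarray, cols: slice | np.ndarray) -> "KernelMatrix":
        """Slice a sub-kernel (e.g. train-train or test-train block)."""
        return KernelMatrix(
            values=self.values[rows][:, cols],
            kind=self.kind,
            row_ids=np.asarray(self.row_ids)[rows],
            col_ids=np.asarray(self.col_ids)[cols],
            detrended=self.detrended,
            params=self.params,
        )


def linear_kernel(
    rows: TimeSeriesMatrix, cols: TimeSeriesMatrix | None = None
) -> KernelMatrix:
    """Linear kernel K(x_i, x_j) = x_i^T x_j between two scan sets."""
    if cols is None:
        cols = rows
    if rows.n_voxels != cols.n_voxels or not np.array_equal(
        rows.voxel_index, cols.voxel_index
    ):
        raise ValueError("row and column scan sets use different voxel mappings")
    return KernelMatrix(values=rows.X @ cols.X.T, kind="linear")


def detrend_kernel(K: KernelMatrix, R: np.ndarray) -> KernelMatrix:
    """Detrend a linear kernel directly in kernel space: R^T K R.

    Only valid for linear kernels: for RBF/polynomial kernels the drift
    enters through the nonlinearity and cannot be projected out afterwards.
    """
    if K.kind != "linear":
        raise ValueError("kernel detrending applies to linear kernels only")
    if not K.is_square or K.values.shape[0] != R.shape[0]:
        raise ValueError("R must match a square kernel over the full scan set")
    return KernelMatrix(
        values=R.T @ K.values @ R,
        kind="linear",
        row_ids=K.row_ids,
        col_ids=K.col_ids,
        detrended=True,
    )


def rbf_from_linear(
    K: KernelMatrix,
    gamma: float,
    diag_rows: np.ndarray | None = None,
    diag_cols: np.ndarray | None = None,
) -> KernelMatrix:
    """RBF kernel exp(-gamma ||x_i - x_j||^2) from linear-kernel entries.

    The squared distance is K_ii - 2 K_ij + K_jj, so only linear-kernel
    blocks are needed.  For a square linear kernel the self-similarities
    default to its diagonal; for a rectangular (test x train) block both
    diagonals must be supplied.
    """
    if K.kind != "linear":
        raise ValueError("input must be a linear kernel")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if diag_rows is None or diag_cols is None:
        if not K.is_square:
            raise ValueError("rectangular kernels need explicit self-similarities")
        diag_rows = diag_cols = np.diag(K.values)
    sq = diag_rows[:, None] - 2.0 * K.values + diag_cols[None, :]
    scale = max(np.abs(sq).max(), 1.0)
    if sq.min() < -1e-8 * scale:
        raise ValueError(f"squared distances strongly negative: {sq.min():.3e}")
    if sq.min() < 0:
        warnings.warn("clamping slightly negative squared distances to 0")
        sq = np.clip(sq, 0.0, None)
    return KernelMatrix(
        values=np.exp(-gamma * sq),
        kind="rbf",
        row_ids=K.row_ids,
        col_ids=K.col_ids,
        detrended=K.detrended,
        params=KernelParams(gamma=gamma),
    )


def polynomial_from_linear(
    K: KernelMatrix, theta: float, degree: int
) -> KernelMatrix:
    """Polynomial kernel (theta + K_ij)^d from linear-kernel entries."""
    if K.kind != "linear":
        raise ValueError("input must be a linear kernel")
    params = KernelParams(gamma=1.0, theta=theta, degree=degree)
    return KernelMatrix(
        values=(theta + K.values) ** degree,
        kind="polynomial",
        row_ids=K.row_ids,
        col_ids=K.col_ids,
        detrended=K.detrended,
        params=params,
    )


def apply_region_mask(tsm: TimeSeriesMatrix, region: MaskVolume) -> TimeSeriesMatrix:
    """Restrict the feature matrix to voxels inside a regional mask.

    Used for prior-knowledge feature selection: kernels built from the
    restricted matrix only see, e.g., auditory or visual cortex.
    """
    if region.grid_dims != tsm.grid_dims:
        raise ValueError(
            f"region grid {region.grid_dims} does not match data grid {tsm.grid_dims}"
        )
    keep = region.data[
        tsm.voxel_index[:, 0], tsm.voxel_index[:, 1], tsm.voxel_index[:, 2]
    ]
    if not keep.any():
        raise ValueError("region mask has no overlap with in-mask voxels")
    return TimeSeriesMatrix(
        X=tsm.X[:, keep],
        voxel_index=tsm.voxel_index[keep],
        grid_dims=tsm.grid_dims,
        run_boundaries=list(tsm.run_boundaries),
    )


def median_heuristic_gamma(K_train: KernelMatrix) -> float:
    """Default RBF width: 1 / median pairwise squared distance on training scans."""
    if K_train.kind != "linear" or not K_train.is_square:
        raise ValueError("median heuristic needs a square linear training kernel")
    d = np.diag(K_train.values)
    sq = d[:, None] - 2.0 * K_train.values + d[None, :]
    off = sq[~np.eye(sq.shape[0], dtype=bool)]
    med = np.median(np.clip(off, 0.0, None))
    if med <= 0:
        raise ValueError("degenerate training set: zero median distance")
    return 1.0 / med
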