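"""Kernel regression models: KRR, sparse-Bayesian RVR, and GP evidence tuning.

Kernel ridge regression (KRR) solves the dual ridge system
beta = (K + lambda I)^-1 t and predicts t* = K_*train beta; it is the dual
of primal ridge w = (X^T X + lambda I)^-1 X^T t and, probabilistically, the
MAP estimate under an isotropic Gaussian weight prior with lambda =
alpha * sigma^2.

Relevance vector regression (RVR) places an independent zero-mean Gaussian
prior with its own precision alpha_i on every weight of the design
Phi = [1, K] and maximizes the marginal likelihood (type-II ML) over the
alpha vector and the noise variance sigma^2.  Precisions driven to infinity
prune their columns (automatic relevance determination); the surviving
training scans are the relevance vectors.

The Gaussian-process evidence optimizer fits the two- (or three-)
hyperparameter covariance C = theta1 I + theta2 K (+ theta3 11^T) by
maximizing the marginal Gaussian log-density of the target, giving the
evidence-implied ridge parameter lambda = theta1/theta2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .kernels import KernelMatrix
from .preprocess import TimeSeriesMatrix, unmask

__all__ = [
    "KRRModel",
    "RVRModel",
    "EvidenceHyperparams",
    "fit_krr",
    "fit_rvr",
    "predict_kernel_model",
    "optimize_evidence",
    "weight_map",
    "sparsity",
]

logger = logging.getLogger(__name__)


@dataclass
class KRRModel:
    """Fitted kernel ridge regression: dual weights and regularization."""

    beta: np.ndarray
    lam: float
    train_kernel_ref: str = ""


@dataclass
class RVRModel:
    """Fitted relevance vector regression.

    ``mu`` has length N+1 with index 0 the bias; pruned entries are exactly
    zero and their ``alpha`` is +inf.  ``relevant_idx`` are the surviving
    design columns (bias included when it survives).
    """

    mu: np.ndarray
    alpha: np.ndarray
    sigma2: float
    relevant_idx: np.ndarray
    converged: bool
    log_evidence_path: np.ndarray
    design_ref: str = ""

    @property
    def log_evidence(self) -> float:
        return float(self.log_evidence_path[-1])


@dataclass
class EvidenceHyperparams:
    """Maximum-evidence hyperparameters of C = theta1 I + theta2 K (+ theta3)."""

    theta1: float
    theta2: float
    theta3: float
    converged: bool
    log_evidence: float

    @property
    def ridge_lambda(self) -> float:
        return self.theta1 / self.theta2


def _solve_spd(A: np.ndarray, b: np.ndarray, context: str = "") -> np.ndarray:
    """Symmetric positive-definite solve with a logged jitter fallback."""
    try:
        c, low = linalg.cho_factor(A, lower=True, check_finite=False)
        return linalg.cho_solve((c, low), b, check_finite=False)
    except linalg.LinAlgError:
        jitter = 1e-10 * np.trace(A) / A.shape[0]
        logger.warning("%s: Cholesky failed, retrying with jitter %.3e", context, jitter)
        c, low = linalg.cho_factor(
            A + jitter * np.eye(A.shape[0]), lower=True, check_finite=False
        )
        return linalg.cho_solve((c, low), b, check_finite=False)


def fit_krr(K: KernelMatrix, t: np.ndarray, lam: float) -> KRRModel:
    """Solve (K + lambda I) beta = t by a symmetric factorization."""
    t = np.asarray(t, dtype=float).ravel()
    if not K.is_square or K.values.shape[0] != t.shape[0]:
        raise ValueError("K must be square and match the target length")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    A = K.values + lam * np.eye(t.shape[0])
    if lam == 0:
        try:
            beta = linalg.solve(A, t, assume_a="sym", check_finite=False)
        except linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "kernel is singular at lambda=0; use lambda > 0"
            ) from err
    else:
        beta = _solve_spd(A, t, context="fit_krr")
    return KRRModel(beta=beta, lam=float(lam))


def predict_kernel_model(
    model: KRRModel | RVRModel, K_test_train: KernelMatrix
) -> np.ndarray:
    """Predict targets for test scans from their similarities to training scans.

    KRR: t* = K_*train beta.  RVR: t* = Phi_* mu with Phi_* = [1, K_*train];
    pruned columns contribute nothing so only relevance vectors matter.
    """
    Kv = K_test_train.values
    if isinstance(model, KRRModel):
        if Kv.shape[1] != model.beta.shape[0]:
            raise ValueError("kernel column count does not match training scans")
        return Kv @ model.beta
    if isinstance(model, RVRModel):
        if Kv.shape[1] != model.mu.shape[0] - 1:
            raise ValueError("kernel column count does not match training scans")
        return model.mu[0] + Kv @ model.mu[1:]
    raise TypeError(f"unsupported model type {type(model)!r}")


def _rvr_log_evidence(
    Phi_a: np.ndarray, alpha_a: np.ndarray, sigma2: float, t: np.ndarray
) -> float:
    """Marginal log-likelihood log N(t; 0, sigma^2 I + Phi A^-1 Phi^T).

    Evaluated through the determinant/Woodbury identities in the M x M
    active-weight space, which stays well-conditioned as sigma^2 -> 0:
    log|C| = N log sigma^2 + log|A + sigma^-2 Phi^T Phi| - log|A| and
    t^T C^-1 t = sigma^-2 t^T (t - Phi mu).
    """
    n = t.shape[0]
    sigma2 = max(sigma2, 1e-12)
    B = np.diag(alpha_a) + Phi_a.T @ Phi_a / sigma2
    sign, logdet_B = np.linalg.slogdet(B)
    if sign <= 0:
        raise linalg.LinAlgError("indefinite posterior precision in RVR evidence")
    logdet_C = n * np.log(sigma2) + logdet_B - np.sum(np.log(alpha_a))
    mu = np.linalg.solve(B, Phi_a.T @ t) / sigma2
    quad = t @ (t - Phi_a @ mu) / sigma2
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet_C + quad)


def fit_rvr(
    K: KernelMatrix,
    t: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    prune_rel: float = 1e9,
    prune_abs: float = 1e12,
) -> RVRModel:
    """Type-II ML fit of relevance vector regression on design Phi = [1, K].

    Iterates the standard fixed-point updates: posterior
    Sigma = (sigma^-2 Phi^T Phi + A)^-1, mu = sigma^-2 Sigma Phi^T t,
    gamma_i = 1 - alpha_i Sigma_ii, alpha_i <- gamma_i / mu_i^2,
    sigma^2 <- ||t - Phi mu||^2 / (N - sum gamma_i).  Columns whose alpha
    exceeds prune_rel * mean(active alpha) or prune_abs are removed from the
    active set.  Stops when the log-evidence change drops below ``tol``, when
    an update would decrease the evidence, or at ``max_iter`` (then flagged
    not converged).
    """
    t = np.asarray(t, dtype=float).ravel()
    n = t.shape[0]
    if n < 3:
        raise ValueError("RVR needs at least 3 scans")
    if not K.is_square or K.values.shape[0] != n:
        raise ValueError("K must be square and match the target length")

    Phi = np.column_stack([np.ones(n), K.values])
    m = n + 1
    active = np.arange(m)
    alpha = np.full(m, 1.0 / n**2)
    var_t = float(np.var(t))
    sigma2 = 0.1 * var_t if var_t > 0 else 0.1

    ev_path: list[float] = []
    converged = False
    best_state: tuple[np.ndarray, np.ndarray, np.ndarray, float] | None = None
    prev_ev: float | None = None

    for _ in range(max_iter):
        Phi_a = Phi[:, active]
        alpha_a = alpha[active]
        A = np.diag(alpha_a) + Phi_a.T @ Phi_a / sigma2
        Sigma = _solve_spd(A, np.eye(len(active)), context="fit_rvr")
        mu_a = Sigma @ (Phi_a.T @ t) / sigma2

        # fixed-point updates can dip transiently; iterate through dips but
        # accept (and record) only iterates that improve the evidence, so
        # the recorded path is monotone and the best iterate is returned
        ev = _rvr_log_evidence(Phi_a, alpha_a, sigma2, t)
        if not ev_path or ev > ev_path[-1]:
            ev_path.append(ev)
            best_state = (active.copy(), alpha[active].copy(), mu_a.copy(), sigma2)
        if prev_ev is not None and abs(ev - prev_ev) < tol:
            converged = True
            break
        prev_ev = ev

        gamma = 1.0 - alpha_a * np.diag(Sigma)
        dof = n - gamma.sum()
        if dof <= 0:
            raise FloatingPointError("effective degrees of freedom <= 0 in RVR")
        with np.errstate(divide="ignore"):
            alpha_new = np.where(mu_a**2 > 0, gamma / mu_a**2, np.inf)
        resid = t - Phi_a @ mu_a
        sigma2 = float(resid @ resid / dof)
        if sigma2 <= 0:
            sigma2 = 1e-12
        alpha[active] = alpha_new

        finite = alpha_new[np.isfinite(alpha_new)]
        thresh = min(prune_abs, prune_rel * finite.mean()) if finite.size else prune_abs
        keep = alpha_new <= thresh
        if not keep.all():
            active = active[keep]
            if active.size == 0:
                raise FloatingPointError("all design columns pruned in RVR")

    if best_state is None:
        raise FloatingPointError("RVR produced no valid iterate")
    active, alpha_a, mu_a, sigma2 = best_state
    mu_full = np.zeros(m)
    mu_full[active] = mu_a
    alpha_out = np.full(m, np.inf)
    alpha_out[active] = alpha_a
    if not converged:
        logger.warning("RVR did not converge in %d iterations", max_iter)
    return RVRModel(
        mu=mu_full,
        alpha=alpha_out,
        sigma2=sigma2,
        relevant_idx=active.copy(),
        converged=converged,
        log_evidence_path=np.asarray(ev_path),
    )


def sparsity(model: RVRModel) -> float:
    """Fraction of training scans kept as relevance vectors (bias excluded)."""
    n_train = model.mu.shape[0] - 1
    n_rel = int(np.sum(model.relevant_idx != 0))
    return n_rel / n_train


def _gp_neg_log_evidence_eig(
    log_theta: np.ndarray, eigvals: np.ndarray, z2: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log evidence and gradient in log-theta, via eigenbasis of K."""
    th1, th2 = np.exp(log_theta)
    c = th1 + th2 * eigvals
    nll = 0.5 * np.sum(np.log(2.0 * np.pi * c) + z2 / c)
    # d nll / d theta_k = 0.5 sum (dc/dtheta) * (1/c - z2/c^2); chain rule for log
    common = 0.5 * (1.0 / c - z2 / c**2)
    g1 = np.sum(common) * th1
    g2 = np.sum(common * eigvals) * th2
    return float(nll), np.array([g1, g2])


def _gp_neg_log_evidence_chol(log_theta: np.ndarray, K: np.ndarray, t: np.ndarray) -> float:
    th = np.exp(log_theta)
    n = t.shape[0]
    C = th[0] * np.eye(n) + th[1] * K + th[2]
    try:
        c, low = linalg.cho_factor(C, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e30
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = t @ linalg.cho_solve((c, low), t, check_finite=False)
    return float(0.5 * (n * np.log(2.0 * np.pi) + logdet + quad))


def optimize_evidence(
    K: KernelMatrix,
    t: np.ndarray,
    include_constant: bool = False,
    n_restarts: int = 3,
    seed: int = 0,
) -> EvidenceHyperparams:
    """Maximize the Gaussian-process evidence of C = theta1 I + theta2 K (+ theta3).

    Optimization runs in log-theta with L-BFGS-B from a moment-matched start
    plus ``n_restarts`` seeded random restarts; the best optimum is kept.
    The implied ridge regularization is lambda = theta1/theta2.
    """
    t = np.asarray(t, dtype=float).ravel()
    if not K.is_square or K.values.shape[0] != t.shape[0]:
        raise ValueError("K must be square and match the target length")
    if np.allclose(t, 0):
        raise ValueError("degenerate all-zero target: evidence is unbounded in theta")
    K.check_psd()

    rng = np.random.default_rng(seed)
    var_t = float(np.var(t)) + 1e-12
    mean_k = float(np.trace(K.values)) / K.values.shape[0] + 1e-12
    base = np.log([0.5 * var_t, 0.5 * var_t / mean_k, 0.1 * var_t])

    if include_constant:
        fun = lambda lt: _gp_neg_log_evidence_chol(lt, K.values, t)
        ndim = 3
        jac = None
    else:
        eigvals, Q = np.linalg.eigh(0.5 * (K.values + K.values.T))
        eigvals = np.clip(eigvals, 0.0, None)
        z2 = (Q.T @ t) ** 2
        fun = lambda lt: _gp_neg_log_evidence_eig(lt, eigvals, z2)
        ndim = 2
        jac = True

    starts = [base[:ndim]]
    for _ in range(n_restarts):
        starts.append(base[:ndim] + rng.normal(0.0, 2.0, size=ndim))

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            fun, x0, jac=jac, method="L-BFGS-B",
            bounds=[(-30.0, 30.0)] * ndim,
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    th = np.exp(best.x)
    theta3 = float(th[2]) if include_constant else 0.0
    return EvidenceHyperparams(
        theta1=float(th[0]),
        theta2=float(th[1]),
        theta3=theta3,
        converged=any_success,
        log_evidence=float(-best.fun),
    )


def weight_map(
    tsm: TimeSeriesMatrix,
    beta: np.ndarray,
    R: np.ndarray | None = None,
) -> np.ndarray:
    """Reconstruct the voxel-space weight image w = X^T R beta.

    ``beta`` are the dual weights (for RVR, the posterior mean without the
    bias entry).  When the model was trained on a detrended kernel, pass the
    same residual-forming matrix R; prediction then satisfies
    t*_j = w^T (R x_j).  With R = None the raw scans are combined directly.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != tsm.n_scans:
        raise ValueError("beta length must equal the number of training scans")
    coeff = beta if R is None else R @ beta
    w = tsm.X.T @ coeff
    return unmask(w, tsm.voxel_index, tsm.grid_dims)
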