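"""Location-scale curve fitting of reading time on surprisal.

This module estimates two curves from a long-format RT table: the mean
reading time mu(s) and the log standard deviation of reading time l(s),
both as smooth functions of surprisal s.  The estimator is a deliberately
transparent two-stage penalized-spline scheme:

1. *Mean stage.*  Penalized weighted least squares of RT on a cubic
   B-spline basis (default 6 basis functions, knots at surprisal
   quantiles, second-order difference penalty), with optional subject
   fixed intercepts and a linear previous-word (spillover) term in the
   design.  Observation weights are exp(-2 l(s)) from the current scale
   estimate.  The smoothing penalty is chosen by generalized
   cross-validation.
2. *Scale stage.*  Penalized least squares of log|residual| on the same
   spline basis (reusing the mean stage's penalty), corrected by the
   Gaussian bias constant E[ln|Z|] = (ln 2 + psi(1/2))/2 so that the
   fitted curve estimates ln sigma(s).

The stages are iterated to a relative-change tolerance.  A linear-control
analog replaces both smooth curves with straight lines and reports slopes
with normal-approximation standard errors, mirroring the common practice of
fitting a linear surprisal effect on mean and on log-SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import digamma

from .synthetic import RTDataset

__all__ = [
    "CurveFit",
    "LinearControlFit",
    "fit_location_scale",
    "fit_linear_control",
    "GAUSSIAN_LOG_ABS_MEAN",
]

# E[ln|Z|] for standard normal Z; used to de-bias log|residual| regressions.
GAUSSIAN_LOG_ABS_MEAN = float((math.log(2.0) + digamma(0.5)) / 2.0)

_LAMBDA_GRID = np.logspace(-4.0, 6.0, 21)
GRID_SIZE = 101


@dataclass(frozen=True)
class CurveFit:
    """Fitted mean and log-SD curves on a uniform surprisal grid."""

    grid: np.ndarray
    mu: np.ndarray
    log_sd: np.ndarray
    basis_dim: int
    lambda_mean: float
    lambda_scale: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if not (np.all(np.diff(self.grid) > 0)):
            raise ValueError("grid must be strictly increasing")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.log_sd))):
            raise ValueError("fitted curves must be finite on the grid")


@dataclass(frozen=True)
class LinearControlFit:
    """Linear surprisal effects on mean RT and on log-SD of RT."""

    beta_mean: float
    beta_logsd: float
    se_beta_mean: float
    se_beta_logsd: float
    intercept_mean: float
    intercept_logsd: float


def _spline_basis(x: np.ndarray, basis_dim: int, knot_source: np.ndarray):
    """Cubic B-spline design matrix with quantile-placed interior knots."""
    degree = 3
    n_interior = basis_dim - degree - 1
    if n_interior < 0:
        raise ValueError(f"basis_dim must be at least {degree + 1}")
    lo, hi = float(knot_source.min()), float(knot_source.max())
    if hi <= lo:
        raise ValueError("degenerate surprisal range: spline basis undefined")
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(knot_source, qs)
        interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    else:
        interior = np.array([])
    t = np.concatenate((np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)))
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray()


def _difference_penalty(p: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(p), n=order, axis=0)
    return d.T @ d


def _penalized_wls(X, y, w, penalty, lam):
    """Solve the penalized weighted normal equations; returns (coef, edf, rss)."""
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    A = xtx + lam * penalty
    coef = np.linalg.solve(A, Xw.T @ y)
    # effective degrees of freedom tr(H) = tr(A^{-1} X'WX)
    edf = float(np.trace(np.linalg.solve(A, xtx)))
    resid = y - X @ coef
    rss = float(w @ (resid * resid))
    return coef, edf, rss


def _gcv_lambda(X, y, w, penalty):
    """Pick the penalty by generalized cross-validation on a fixed grid."""
    n = y.size
    best_lam, best_score = _LAMBDA_GRID[0], np.inf
    for lam in _LAMBDA_GRID:
        _, edf, rss = _penalized_wls(X, y, w, penalty, lam)
        denom = max(n - edf, 1.0)
        score = n * rss / denom**2
        if score < best_score:
            best_lam, best_score = lam, score
    return float(best_lam)


def _cluster_cov(X, w, resid, xtx_inv, clusters):
    """CR1 cluster-robust covariance for a (weighted) least-squares fit.

    Subjects are the clusters; with by-subject intercept/slope variation the
    classical errors would be far too small for repeated-measures reading
    data.  Falls back to the classical estimator when fewer than 2 clusters.
    """
    n, p = X.shape
    groups = np.unique(clusters)
    if groups.size < 2:
        sigma2 = float(w @ (resid * resid)) / max(n - p, 1)
        return xtx_inv * sigma2
    score = X * (w * resid)[:, None]
    meat = np.zeros((p, p))
    for g in groups:
        sg = score[clusters == g].sum(axis=0)
        meat += np.outer(sg, sg)
    g = groups.size
    correction = (g / (g - 1)) * ((n - 1) / max(n - p, 1))
    return correction * xtx_inv @ meat @ xtx_inv


def _mean_design(data: RTDataset, basis_dim: int, adjust_subjects: bool, adjust_spillover: bool):
    df = data.frame
    s = df["surprisal"].to_numpy(dtype=float)
    B = _spline_basis(s, basis_dim, s)
    blocks = [B]
    if adjust_subjects:
        subj = pd.get_dummies(df["subject_id"], drop_first=True, dtype=float)
        blocks.append(subj.to_numpy())
    if adjust_spillover:
        blocks.append(df["prev_surprisal"].to_numpy(dtype=float)[:, None])
    X = np.hstack(blocks)
    penalty = np.zeros((X.shape[1], X.shape[1]))
    penalty[:basis_dim, :basis_dim] = _difference_penalty(basis_dim)
    return X, penalty, B, s


def fit_location_scale(
    data: RTDataset,
    basis_dim: int = 6,
    adjust_subjects: bool = True,
    adjust_spillover: bool = True,
    fit_scale: bool = True,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> CurveFit:
    """Two-stage penalized-spline fit of mean RT and log-SD of RT.

    ``fit_scale=False`` disables the scale stage (constant-variance
    control): the log-SD curve is then the constant ln of the pooled
    residual SD and the mean stage runs unweighted.

    Non-convergence within ``max_iter`` iterations is flagged on the
    result, not raised.
    """
    df = data.frame
    if len(df) < 20 * basis_dim:
        raise ValueError(f"need at least {20 * basis_dim} rows for basis_dim={basis_dim}")
    y = df["rt"].to_numpy(dtype=float)
    X, penalty, B, s = _mean_design(data, basis_dim, adjust_subjects, adjust_spillover)

    grid = np.linspace(s.min(), s.max(), GRID_SIZE)
    Bg = _spline_basis(grid, basis_dim, s)
    scale_penalty = _difference_penalty(basis_dim)

    log_sd_obs = np.zeros_like(y)
    mu_grid = np.zeros(GRID_SIZE)
    log_sd_grid = np.zeros(GRID_SIZE)
    lam_mean = np.nan
    lam_scale = np.nan
    converged = False
    iterations = 0

    for iteration in range(1, max_iter + 1):
        iterations = iteration
        w = np.exp(-2.0 * log_sd_obs)
        w = w / w.mean()  # keep the penalty on the same scale as X'WX
        if iteration == 1:
            lam_mean = _gcv_lambda(X, y, w, penalty)
        coef, _, _ = _penalized_wls(X, y, w, penalty, lam_mean)
        resid = y - X @ coef

        offset = float(np.mean(X[:, basis_dim:] @ coef[basis_dim:])) if X.shape[1] > basis_dim else 0.0
        new_mu_grid = Bg @ coef[:basis_dim] + offset

        if fit_scale:
            z = np.log(np.maximum(np.abs(resid), 1e-8))
            if iteration == 1:
                lam_scale = lam_mean  # reuse the mean penalty: one fewer knob
            scoef, _, _ = _penalized_wls(B, z, np.ones_like(z), scale_penalty, lam_scale)
            new_log_sd_obs = B @ scoef - GAUSSIAN_LOG_ABS_MEAN
            new_log_sd_grid = Bg @ scoef - GAUSSIAN_LOG_ABS_MEAN
        else:
            pooled = math.log(max(float(np.std(resid)), 1e-8))
            new_log_sd_obs = np.full_like(y, pooled)
            new_log_sd_grid = np.full(GRID_SIZE, pooled)

        denom = max(float(np.max(np.abs(mu_grid))), 1.0)
        change = max(
            float(np.max(np.abs(new_mu_grid - mu_grid))) / denom,
            float(np.max(np.abs(new_log_sd_grid - log_sd_grid))),
        )
        mu_grid, log_sd_grid, log_sd_obs = new_mu_grid, new_log_sd_grid, new_log_sd_obs
        if not fit_scale and iteration >= 2:
            converged = True
            break
        if iteration >= 2 and change < tol:
            converged = True
            break

    return CurveFit(
        grid=grid,
        mu=mu_grid,
        log_sd=log_sd_grid,
        basis_dim=basis_dim,
        lambda_mean=float(lam_mean),
        lambda_scale=float(lam_scale) if fit_scale else 0.0,
        iterations=iterations,
        converged=converged,
    )


def fit_linear_control(
    data: RTDataset,
    adjust_subjects: bool = True,
    adjust_spillover: bool = True,
    n_iter: int = 3,
) -> LinearControlFit:
    """Linear surprisal effects on mean RT and on log-SD of RT.

    Stage 1 regresses RT on surprisal (plus optional subject fixed
    intercepts and the spillover term) by weighted least squares; stage 2
    regresses the de-biased log absolute residual on surprisal.  The two
    stages are iterated a fixed small number of times with weights
    exp(-2 l(s)).  Standard errors are the usual normal-approximation WLS
    errors from the final iteration.
    """
    df = data.frame
    if len(df) < 10:
        raise ValueError("need at least 10 rows")
    s = df["surprisal"].to_numpy(dtype=float)
    if np.ptp(s) <= 0:
        raise ValueError("constant surprisal: slope unidentifiable")
    y = df["rt"].to_numpy(dtype=float)

    blocks = [np.ones_like(s)[:, None], s[:, None]]
    if adjust_subjects:
        blocks.append(pd.get_dummies(df["subject_id"], drop_first=True, dtype=float).to_numpy())
    if adjust_spillover:
        blocks.append(df["prev_surprisal"].to_numpy(dtype=float)[:, None])
    X = np.hstack(blocks)
    Z = np.column_stack([np.ones_like(s), s])

    clusters = pd.factorize(df["subject_id"])[0]

    log_sd_obs = np.zeros_like(y)
    beta = np.zeros(X.shape[1])
    gamma = np.zeros(2)
    cov_beta = np.eye(X.shape[1])
    cov_gamma = np.eye(2)
    for _ in range(n_iter):
        w = np.exp(-2.0 * log_sd_obs)
        w = w / w.mean()
        Xw = X * w[:, None]
        xtx_inv = np.linalg.inv(X.T @ Xw)
        beta = xtx_inv @ (Xw.T @ y)
        resid = y - X @ beta
        cov_beta = _cluster_cov(X, w, resid, xtx_inv, clusters)

        z = np.log(np.maximum(np.abs(resid), 1e-8)) - GAUSSIAN_LOG_ABS_MEAN
        ztz_inv = np.linalg.inv(Z.T @ Z)
        gamma = ztz_inv @ (Z.T @ z)
        zr = z - Z @ gamma
        cov_gamma = _cluster_cov(Z, np.ones_like(z), zr, ztz_inv, clusters)
        log_sd_obs = Z @ gamma

    return LinearControlFit(
        beta_mean=float(beta[1]),
        beta_logsd=float(gamma[1]),
        se_beta_mean=float(math.sqrt(cov_beta[1, 1])),
        se_beta_logsd=float(math.sqrt(cov_gamma[1, 1])),
        intercept_mean=float(beta[0]),
        intercept_logsd=float(gamma[0]),
    )
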