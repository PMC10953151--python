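"""Cyclic coordinate-descent solver for GLMs with per-coefficient L1 penalties.

This is the workhorse behind both the adaptive-penalty M-step of the
spike-and-slab EM and the plain (non-negative) lasso fits used elsewhere
in the package.  The penalized objective is

    Q(w0, w) = l(w0, w) - sum_j lambda_j |w_j|

where ``l`` is the log-likelihood summed over observations (Gaussian with
unit dispersion, or binomial), ``lambda_j >= 0`` are per-coefficient
penalty factors, and the intercept ``w0`` is never penalized.  Optionally
every (or individual) coefficient is constrained to be non-negative, in
which case the soft-threshold update is clipped below at zero.

Binomial fits use an IRLS outer loop: each outer iteration builds the
weighted least-squares approximation at the current linear predictor
(working weights floored to avoid divergence) and solves it by cyclic
coordinate descent.

Columns are NOT standardized internally; callers that want standardized
inputs pass ``standardize=True`` (off by default, because the stacking
super learner feeds probabilities that live on a common [0, 1] scale and
the fitted weights should stay interpretable on that scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from ._cd import cd_weighted_gaussian, irls_cd_binomial

__all__ = [
    "PenalizedProblem",
    "GlmFit",
    "soft_threshold",
    "fit_weighted_l1_glm",
    "penalized_objective",
    "log_likelihood",
    "lasso_cv",
]

_WEIGHT_FLOOR = 1e-5  # IRLS working-weight floor
_PROB_CLIP = 1e-8


def soft_threshold(z: float, t: float, nonneg: bool = False) -> float:
    """Soft-thresholding operator ``sign(z) * max(|z| - t, 0)``.

    With ``nonneg=True`` the result is additionally clipped below at 0,
    which is the coordinate update under a non-negativity constraint.
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    out = np.sign(z) * max(abs(z) - t, 0.0)
    if nonneg and out < 0.0:
        out = 0.0
    return float(out)


@dataclass
class PenalizedProblem:
    """A GLM with per-coefficient L1 penalties and optional sign constraints.

    Parameters
    ----------
    design
        N x P design matrix (finite entries).
    response
        Length-N response; for ``family='binomial'`` entries must be 0/1.
    family
        ``'gaussian'`` or ``'binomial'``.
    penalty_factors
        Length-P non-negative penalties (the adaptive lambda_j), on the
        same scale as the summed log-likelihood.  A scalar broadcasts.
    nonneg
        Boolean (global) or length-P boolean vector of non-negativity
        constraints on the coefficients.
    intercept
        Fit an (always unpenalized) intercept.
    """

    design: np.ndarray
    response: np.ndarray
    family: str = "binomial"
    penalty_factors: np.ndarray | float = 0.0
    nonneg: np.ndarray | bool = False
    intercept: bool = True
    standardize: bool = False

    def __post_init__(self) -> None:
        self.design = np.ascontiguousarray(self.design, dtype=np.float64)
        self.response = np.asarray(self.response, dtype=np.float64).ravel()
        if self.design.ndim != 2:
            raise ValueError("design must be 2-D")
        n, p = self.design.shape
        if self.response.shape[0] != n:
            raise ValueError("design and response lengths differ")
        if not np.all(np.isfinite(self.design)):
            raise ValueError("design contains non-finite entries")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response contains non-finite entries")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not np.all(np.isin(self.response, (0.0, 1.0))):
            raise ValueError("binomial response must be coded 0/1")
        self.penalty_factors = np.broadcast_to(
            np.asarray(self.penalty_factors, dtype=np.float64), (p,)
        ).copy()
        if np.any(self.penalty_factors < 0):
            raise ValueError("penalty_factors must be non-negative")
        self.nonneg = np.broadcast_to(np.asarray(self.nonneg, dtype=np.bool_), (p,)).copy()

    @property
    def n_obs(self) -> int:
        return self.design.shape[0]

    @property
    def n_var(self) -> int:
        return self.design.shape[1]


@dataclass
class GlmFit:
    """Result of a penalized GLM fit."""

    intercept: float
    coefficients: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    family: str = "binomial"

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=np.float64) @ self.coefficients

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean response: probabilities for binomial, identity for gaussian."""
        eta = self.linear_predictor(X)
        if self.family == "binomial":
            return _sigmoid(eta)
        return eta


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=np.float64)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def log_likelihood(y: np.ndarray, eta: np.ndarray, family: str) -> float:
    """Log-likelihood summed over observations (unit dispersion for gaussian)."""
    y = np.asarray(y, dtype=np.float64)
    eta = np.asarray(eta, dtype=np.float64)
    if family == "gaussian":
        return float(-0.5 * np.sum((y - eta) ** 2))
    if family == "binomial":
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    raise ValueError(f"unknown family {family!r}")


def penalized_objective(
    problem: PenalizedProblem, intercept: float, coefficients: np.ndarray
) -> float:
    """l(w) - sum_j lambda_j |w_j| for a candidate solution."""
    eta = intercept + problem.design @ coefficients
    return log_likelihood(problem.response, eta, problem.family) - float(
        np.sum(problem.penalty_factors * np.abs(coefficients))
    )


def fit_weighted_l1_glm(
    problem: PenalizedProblem,
    tol: float = 1e-5,
    max_iter: int = 500,
    w_init: np.ndarray | None = None,
    w0_init: float | None = None,
) -> GlmFit:
    """Maximize the per-coefficient L1-penalized GLM log-likelihood.

    Gaussian problems are solved by cyclic coordinate descent directly;
    binomial problems wrap the same quadratic solver in an IRLS loop.
    Convergence is declared when no coefficient (intercept included)
    moves by more than ``tol`` across a full update; non-convergence
    after ``max_iter`` is flagged on the returned fit, not fatal.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    X = problem.design
    y = problem.response
    n, p = X.shape
    scale = np.ones(p)
    offset = np.zeros(p)
    if problem.standardize:
        offset = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = np.ascontiguousarray((X - offset) / scale)

    w = np.zeros(p) if w_init is None else np.asarray(w_init, dtype=np.float64).copy()
    if problem.standardize and w_init is not None:
        w = w * scale
    lam = problem.penalty_factors
    nonneg = problem.nonneg

    if w0_init is not None:
        w0 = float(w0_init)
    elif problem.family == "binomial":
        ybar = np.clip(y.mean(), _PROB_CLIP, 1 - _PROB_CLIP)
        w0 = float(np.log(ybar / (1 - ybar))) if problem.intercept else 0.0
    else:
        w0 = float(y.mean()) if problem.intercept else 0.0

    XT = np.ascontiguousarray(X.T)
    if problem.family == "gaussian":
        v = np.ones(n)
        w0, sweeps, delta = cd_weighted_gaussian(
            XT, y, v, w0, w, lam, nonneg, problem.intercept, tol, max_iter
        )
        n_iter, converged = sweeps, bool(delta < tol)
    else:
        w0, n_iter, converged = irls_cd_binomial(
            XT, y, w0, w, lam, nonneg, problem.intercept, tol,
            max_iter, 0.1 * tol, 200,
        )
        converged = bool(converged)

    if problem.standardize:
        w = w / scale
        w0 = w0 - float(offset @ w)
    obj = penalized_objective(problem, w0, w)
    return GlmFit(
        intercept=w0,
        coefficients=w,
        objective=obj,
        n_iter=n_iter,
        converged=converged,
        family=problem.family,
    )


def _lambda_max(X: np.ndarray, y: np.ndarray, nonneg: bool) -> float:
    # smallest uniform penalty at which all coefficients are zero
    # (score at the intercept-only fit)
    g = X.T @ (y - y.mean())
    m = float(np.max(g)) if nonneg else float(np.max(np.abs(g)))
    if m <= 0:
        m = float(np.max(np.abs(g)))
    return max(m, 1e-10)


def _deviance(y: np.ndarray, mu: np.ndarray, family: str) -> float:
    if family == "binomial":
        mu = np.clip(mu, _PROB_CLIP, 1 - _PROB_CLIP)
        return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return float(np.sum((y - mu) ** 2))


def lasso_cv(
    X: np.ndarray,
    y: np.ndarray,
    family: str = "binomial",
    nonneg: bool = False,
    n_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-5,
    max_iter: int = 500,
    cv_tol: float = 1e-4,
) -> tuple[GlmFit, float, np.ndarray, np.ndarray]:
    """(Non-negative) lasso GLM with the uniform penalty chosen by K-fold CV.

    The penalty grid is ``n_lambda`` log-spaced values descending from the
    smallest all-zero penalty; fold fits are warm-started along the path
    and scored by held-out deviance; the final model is refit on all rows
    at the penalty minimizing mean CV deviance.  Fold fits use the looser
    ``cv_tol`` (they only feed the deviance curve); the refit uses ``tol``.

    Returns ``(fit, best_lambda, lambda_grid, mean_cv_deviance)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = X.shape[0]
    lam_max = _lambda_max(X, y, nonneg)
    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    if family == "binomial" and 2 <= np.sum(y) <= n - 2 and n_folds <= min(
        np.sum(y == 1), np.sum(y == 0)
    ):
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X)

    p = X.shape[1]
    nonneg_vec = np.full(p, bool(nonneg))

    def _init_w0(yy):
        if family == "binomial":
            ybar = np.clip(yy.mean(), _PROB_CLIP, 1 - _PROB_CLIP)
            return float(np.log(ybar / (1 - ybar)))
        return float(yy.mean())

    def _path(XT, yy, lam_value, w, w0, path_tol):
        lam_vec = np.full(p, lam_value)
        if family == "binomial":
            w0, _, _ = irls_cd_binomial(
                XT, yy, w0, w, lam_vec, nonneg_vec, True, path_tol,
                max_iter, 0.1 * path_tol, 200,
            )
        else:
            w0, _, _ = cd_weighted_gaussian(
                XT, yy, np.ones(yy.shape[0]), w0, w, lam_vec, nonneg_vec,
                True, path_tol, max_iter,
            )
        return w0

    cv_dev = np.zeros((n_folds, n_lambda))
    for k, (tr, va) in enumerate(splits):
        XT_tr = np.ascontiguousarray(X[tr].T)
        Xva = X[va]
        y_tr = y[tr]
        w = np.zeros(p)
        w0 = _init_w0(y_tr)
        for i, lam in enumerate(grid):
            w0 = _path(XT_tr, y_tr, lam, w, w0, cv_tol)
            eta = w0 + Xva @ w
            mu = _sigmoid(eta) if family == "binomial" else eta
            cv_dev[k, i] = _deviance(y[va], mu, family)
    mean_dev = cv_dev.mean(axis=0)
    best = int(np.argmin(mean_dev))

    XT_full = np.ascontiguousarray(X.T)
    w = np.zeros(p)
    w0 = _init_w0(y)
    for lam in grid[: best + 1]:
        w0 = _path(XT_full, y, lam, w, w0, tol)
    prob = PenalizedProblem(X, y, family=family,
                            penalty_factors=grid[best], nonneg=nonneg)
    obj = penalized_objective(prob, w0, w)
    fit = GlmFit(intercept=w0, coefficients=w, objective=obj,
                 n_iter=0, converged=True, family=family)
    return fit, float(grid[best]), grid, mean_dev
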