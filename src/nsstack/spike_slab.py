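"""The non-negative spike-and-slab lasso (nsslasso) GLM, fitted by EM.

Each coefficient w_j carries a two-component truncated double-exponential
(Laplace) mixture prior: a sharp "spike" of scale ``s0`` that shrinks
weak effects to zero and a diffuse "slab" of scale ``s1`` (default 1)
that leaves strong effects lightly penalized.  A latent indicator
gamma_j ~ Bernoulli(theta_j) picks the component, theta_j ~ Beta(a, b),
so the effective scale is S_j = (1 - gamma_j) s0 + gamma_j s1.

The EM algorithm treats gamma as missing data:

* E-step: posterior inclusion probability
  p_j = theta_j psi(w_j | s1) / [(1 - theta_j) psi(w_j | s0)
                                 + theta_j psi(w_j | s1)]
  and the conditional expectation of the inverse scale
  lambda_j = (1 - p_j) / s0 + p_j / s1.
* M-step: w maximizes the adaptive-L1 objective
  Q1(w) = l(w) - sum_j lambda_j w_j by cyclic coordinate descent
  (non-negativity enforced when requested); theta_j is set to the
  posterior mode (p_j + a - 1) / (a + b - 1), which for the uniform
  default a = b = 1 is simply theta_j = p_j.

With s0 = s1 the mixture collapses, every lambda_j equals 1/s1, and the
fit reduces to a (non-negative) lasso with uniform penalty 1/s1.

The spike scale ``s0`` is the one tuning parameter that matters; it is
selected from a grid by K-fold cross-validated deviance
(:func:`select_s0_cv`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import beta as beta_dist
from sklearn.model_selection import KFold, StratifiedKFold

from .penalized_glm import (
    GlmFit,
    PenalizedProblem,
    _deviance,
    fit_weighted_l1_glm,
    log_likelihood,
)

__all__ = [
    "SpikeSlabPrior",
    "EMState",
    "NsslassoModel",
    "de_density",
    "e_step_inclusion",
    "e_step_scale",
    "m_step_theta",
    "fit_nsslasso",
    "select_s0_cv",
    "default_s0_grid",
]

_EPS = 1e-8  # clipping for theta and probabilities


@dataclass(frozen=True)
class SpikeSlabPrior:
    """Hyperparameters of the (non-negative) spike-and-slab DE mixture prior."""

    s0: float = 0.05
    s1: float = 1.0
    a: float = 1.0
    b: float = 1.0
    nonneg: bool = True
    shared_theta: bool = False

    def __post_init__(self) -> None:
        if not (self.s1 >= self.s0 > 0):
            raise ValueError("prior scales must satisfy s1 >= s0 > 0")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta hyperparameters must be positive")

    def with_s0(self, s0: float) -> "SpikeSlabPrior":
        return SpikeSlabPrior(s0, self.s1, self.a, self.b, self.nonneg, self.shared_theta)


@dataclass
class EMState:
    """State of the EM iteration at convergence (or at the iteration cap)."""

    w0: float
    w: np.ndarray
    p: np.ndarray
    lam: np.ndarray
    theta: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass
class NsslassoModel:
    """A fitted nsslasso GLM (the stacking super learner)."""

    prior: SpikeSlabPrior
    state: EMState
    family: str
    column_names: list[str] | None = None

    @property
    def intercept(self) -> float:
        return self.state.w0

    @property
    def weights(self) -> np.ndarray:
        return self.state.w

    def predict(self, Z: np.ndarray) -> np.ndarray:
        fit = GlmFit(
            intercept=self.state.w0,
            coefficients=self.state.w,
            objective=np.nan,
            n_iter=self.state.n_iter,
            converged=self.state.converged,
            family=self.family,
        )
        return fit.predict(np.asarray(Z, dtype=np.float64))

    def to_dict(self) -> dict:
        return {
            "prior": {
                "s0": self.prior.s0,
                "s1": self.prior.s1,
                "a": self.prior.a,
                "b": self.prior.b,
                "nonneg": self.prior.nonneg,
                "shared_theta": self.prior.shared_theta,
            },
            "family": self.family,
            "column_names": self.column_names,
            "w0": self.state.w0,
            "w": self.state.w.tolist(),
            "p": self.state.p.tolist(),
            "theta": self.state.theta.tolist(),
            "n_iter": self.state.n_iter,
            "converged": self.state.converged,
            "warnings": self.state.warnings,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NsslassoModel":
        prior = SpikeSlabPrior(**d["prior"])
        w = np.asarray(d["w"], dtype=np.float64)
        p = np.asarray(d["p"], dtype=np.float64)
        theta = np.asarray(d["theta"], dtype=np.float64)
        lam = e_step_scale(p, prior)
        state = EMState(
            w0=float(d["w0"]), w=w, p=p, lam=lam, theta=theta,
            n_iter=int(d["n_iter"]), converged=bool(d["converged"]),
            warnings=list(d.get("warnings", [])),
        )
        return cls(prior=prior, state=state, family=d["family"],
                   column_names=d.get("column_names"))


def de_density(w, scale):
    """Density of the double-exponential distribution restricted to w >= 0,
    written as (1 / (2 * scale)) * exp(-|w| / scale).

    The leading 1/2 means the truncated form integrates to 1/2 over
    [0, inf); the constant cancels between the spike and slab components
    in the posterior inclusion probability, so it is kept as is.
    """
    scale = np.asarray(scale, dtype=np.float64)
    if np.any(scale <= 0):
        raise ValueError("scale must be positive")
    return 1.0 / (2.0 * scale) * np.exp(-np.abs(w) / scale)


def e_step_inclusion(w, theta, prior: SpikeSlabPrior):
    """Posterior inclusion probability p_j = P(gamma_j = 1 | w_j, theta_j).

    Computed in log space so that large |w| / small s0 cannot underflow:
    p = sigmoid(log theta - log(1 - theta) + log psi_1 - log psi_0).
    """
    w = np.abs(np.asarray(w, dtype=np.float64))
    theta = np.clip(np.asarray(theta, dtype=np.float64), 0.0, 1.0)
    # log density ratio slab/spike
    log_ratio = (np.log(prior.s0) - np.log(prior.s1)) + w * (1.0 / prior.s0 - 1.0 / prior.s1)
    with np.errstate(divide="ignore"):
        logit_theta = np.log(theta) - np.log1p(-theta)
    p = expit(logit_theta + log_ratio)
    p = np.where(theta <= 0.0, 0.0, p)
    p = np.where(theta >= 1.0, 1.0, p)
    if np.isscalar(w) or p.ndim == 0:
        return float(p)
    return p


def e_step_scale(p, prior: SpikeSlabPrior):
    """Conditional posterior expectation of 1/S_j:
    lambda_j = (1 - p_j)/s0 + p_j/s1 — the adaptive L1 penalty factor."""
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    out = (1.0 - p) / prior.s0 + p / prior.s1
    return float(out) if out.ndim == 0 else out


def m_step_theta(p, a: float = 1.0, b: float = 1.0):
    """M-step update of theta_j: mode of the Beta(p_j + a, 1 - p_j + b)
    complete-data posterior, (p_j + a - 1)/(a + b - 1), clipped to
    [eps, 1 - eps].  For a = b = 1 this is theta_j = p_j, the same
    optimum a numerical maximizer of the theta-part of the expected log
    posterior would find.  If a + b <= 1 the mode formula is invalid and
    a bounded numerical maximization is used instead.
    """
    scalar_in = np.ndim(p) == 0
    p = np.atleast_1d(np.asarray(p, dtype=np.float64))
    if a <= 0 or b <= 0:
        raise ValueError("Beta hyperparameters must be positive")
    if a + b > 1:
        theta = (p + a - 1.0) / (a + b - 1.0)
    else:
        def _obj(t, pj):
            return -(pj * np.log(t) + (1 - pj) * np.log(1 - t)
                     + beta_dist.logpdf(t, a, b))
        theta = np.array([
            minimize_scalar(_obj, bounds=(_EPS, 1 - _EPS), args=(pj,),
                            method="bounded").x
            for pj in p
        ])
    theta = np.clip(theta, _EPS, 1 - _EPS)
    return float(theta[0]) if scalar_in else theta


def _expected_log_posterior(
    y: np.ndarray, eta: np.ndarray, w: np.ndarray, p: np.ndarray,
    theta: np.ndarray, lam: np.ndarray, prior: SpikeSlabPrior, family: str,
) -> float:
    """Expected log joint posterior with gamma_j replaced by p_j:
    l(w) - sum_j w_j lambda_j + sum_j [p_j log theta_j
    + (1 - p_j) log(1 - theta_j) + log Beta(theta_j | a, b)]."""
    ll = log_likelihood(y, eta, family)
    pen = float(np.sum(np.abs(w) * lam))
    th = np.clip(theta, _EPS, 1 - _EPS)
    mix = float(np.sum(p * np.log(th) + (1 - p) * np.log(1 - th)))
    prior_term = float(np.sum(beta_dist.logpdf(th, prior.a, prior.b)))
    return ll - pen + mix + prior_term


def fit_nsslasso(
    Z: np.ndarray,
    y: np.ndarray,
    prior: SpikeSlabPrior | None = None,
    family: str = "binomial",
    tol: float = 1e-5,
    max_iter: int = 200,
    column_names: list[str] | None = None,
) -> NsslassoModel:
    """Fit the (non-negative) spike-and-slab lasso GLM by EM.

    Initialization is deterministic: w from a slab-only fit (uniform
    penalty 1/s1), theta_j = 0.5, p from one E-step.  Each iteration
    runs the E-step (p, lambda), the coordinate-descent M-step for w
    with penalty factors lambda, and the closed-form theta update,
    until max |delta w| < tol or ``max_iter``.
    """
    prior = prior or SpikeSlabPrior()
    Z = np.ascontiguousarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, J = Z.shape

    def _m_step_w(lam, w_init, w0_init):
        prob = PenalizedProblem(
            Z, y, family=family, penalty_factors=lam, nonneg=prior.nonneg
        )
        return fit_weighted_l1_glm(prob, tol=tol, max_iter=500,
                                   w_init=w_init, w0_init=w0_init)

    # slab-only initialization: lambda_j = 1/s1 for all j
    fit = _m_step_w(np.full(J, 1.0 / prior.s1), None, None)
    w, w0 = fit.coefficients, fit.intercept
    theta = np.full(J, 0.5)
    p = np.atleast_1d(e_step_inclusion(w, theta, prior))

    state = EMState(w0=w0, w=w, p=p, lam=e_step_scale(p, prior), theta=theta)
    prev_obj = -np.inf
    for it in range(max_iter):
        p = np.atleast_1d(e_step_inclusion(w, theta, prior))
        lam = e_step_scale(p, prior)
        fit = _m_step_w(lam, w, w0)
        w_new, w0_new = fit.coefficients, fit.intercept
        theta = np.atleast_1d(m_step_theta(p, prior.a, prior.b))
        if prior.shared_theta:
            theta = np.full(J, float(np.mean(p)))
        delta = max(float(np.max(np.abs(w_new - w), initial=0.0)), abs(w0_new - w0))
        w, w0 = w_new, w0_new
        obj = _expected_log_posterior(
            y, w0 + Z @ w, w, p, theta, lam, prior, family
        )
        state.objective_trace.append(obj)
        if obj < prev_obj - 1e-6:
            state.warnings.append(
                f"objective decreased by {prev_obj - obj:.3g} at iteration {it + 1}"
            )
        prev_obj = obj
        state.n_iter = it + 1
        if delta < tol:
            state.converged = True
            break
    state.w0, state.w, state.p, state.theta = w0, w, p, theta
    state.lam = e_step_scale(p, prior)
    if not state.converged:
        state.warnings.append(f"EM did not converge in {max_iter} iterations")
        warnings.warn("nsslasso EM did not converge", RuntimeWarning, stacklevel=2)
    return NsslassoModel(prior=prior, state=state, family=family,
                         column_names=list(column_names) if column_names else None)


def default_s0_grid(low: float = 0.01, high: float = 0.5, num: int = 8) -> np.ndarray:
    """Default candidate spike scales: log-spaced in [0.01, 0.5]."""
    return np.geomspace(low, high, num)


def select_s0_cv(
    Z: np.ndarray,
    y: np.ndarray,
    s0_grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
    prior: SpikeSlabPrior | None = None,
    family: str = "binomial",
    tol: float = 1e-5,
    max_iter: int = 200,
) -> tuple[float, pd.DataFrame]:
    """Choose the spike scale s0 by K-fold cross-validated deviance.

    Every candidate s0 is fit on each training fold and scored by
    held-out deviance; the s0 with the smallest mean CV deviance wins.
    Returns ``(best_s0, cv_table)`` where the table has one row per
    candidate with per-fold and mean deviances.
    """
    template = prior or SpikeSlabPrior()
    if s0_grid is None:
        s0_grid = default_s0_grid(high=min(0.5, template.s1 * 0.5))
    s0_grid = np.asarray(s0_grid, dtype=np.float64)
    if s0_grid.size == 0:
        raise ValueError("s0 grid is empty")
    if np.any((s0_grid <= 0) | (s0_grid > template.s1)):
        raise ValueError("s0 candidates must lie in (0, s1]")

    Z = np.ascontiguousarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if family == "binomial" and n_folds <= min(np.sum(y == 1), np.sum(y == 0)):
        splits = list(
            StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed).split(Z, y)
        )
    else:
        splits = list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(Z))

    dev = np.zeros((s0_grid.size, n_folds))
    for i, s0 in enumerate(s0_grid):
        pr = template.with_s0(float(s0))
        for k, (tr, va) in enumerate(splits):
            model = fit_nsslasso(Z[tr], y[tr], prior=pr, family=family,
                                 tol=tol, max_iter=max_iter)
            dev[i, k] = _deviance(y[va], model.predict(Z[va]), family)
    table = pd.DataFrame({
        "s0": s0_grid,
        "mean_cv_deviance": dev.mean(axis=1),
        "sd_cv_deviance": dev.std(axis=1, ddof=1) if n_folds > 1 else np.nan,
    })
    best_s0 = float(s0_grid[int(np.argmin(table["mean_cv_deviance"].to_numpy()))])
    return best_s0, table
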