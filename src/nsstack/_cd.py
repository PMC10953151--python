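"""Numba kernels for weighted-L1 coordinate descent.

These are the inner loops of the penalized GLM solver.  The design is
passed TRANSPOSED (P x N, C-contiguous) so each coordinate's data is a
contiguous row and the per-coordinate dot products vectorize.  ``w`` is
mutated in place.

Sweeps follow the usual active-set scheme: a full pass over all
coordinates, then repeated passes over the current non-zero set until
they stabilize, then another full pass to verify optimality.  The
binomial solver runs the whole IRLS loop (working response, floored
working weights, inner quadratic solve) inside one jitted function.
"""

import numpy as np
from numba import njit

_WEIGHT_FLOOR = 1e-5  # IRLS working-weight floor


@njit(cache=True, fastmath=True)
def _soft(z, t, nonneg):
    if z > t:
        out = z - t
    elif z < -t:
        out = z + t
    else:
        out = 0.0
    if nonneg and out < 0.0:
        out = 0.0
    return out


@njit(cache=True, fastmath=True)
def _sweep(XT, r, u, v, w, lam, nonneg, den, active_only):
    """One coordinate pass over u = v * r; returns the largest change."""
    n_var, n_obs = XT.shape
    delta_max = 0.0
    for j in range(n_var):
        if active_only and w[j] == 0.0:
            continue
        if den[j] <= 0.0:
            if w[j] != 0.0:
                for n in range(n_obs):
                    r[n] += XT[j, n] * w[j]
                    u[n] = v[n] * r[n]
                w[j] = 0.0
            continue
        num = den[j] * w[j]
        for n in range(n_obs):
            num += XT[j, n] * u[n]
        wj = _soft(num, lam[j], nonneg[j]) / den[j]
        d = wj - w[j]
        if d != 0.0:
            for n in range(n_obs):
                r[n] -= XT[j, n] * d
                u[n] -= v[n] * XT[j, n] * d
            w[j] = wj
        if abs(d) > delta_max:
            delta_max = abs(d)
    return delta_max


@njit(cache=True, fastmath=True)
def _intercept_step(r, u, v, vsum, w0):
    d = 0.0
    for n in range(r.shape[0]):
        d += u[n]
    d /= vsum
    for n in range(r.shape[0]):
        r[n] -= d
        u[n] -= v[n] * d
    return w0 + d, d


@njit(cache=True, fastmath=True)
def cd_weighted_gaussian(XT, z, v, w0, w, lam, nonneg, fit_intercept, tol, max_sweeps):
    """Cyclic coordinate descent on the weighted penalized least squares

        maximize  -1/2 * sum_n v_n (z_n - w0 - x_n.w)^2  -  sum_j lam_j |w_j|

    Coordinates are visited in fixed index order; the (unpenalized)
    intercept is refreshed before each pass.  Returns
    ``(w0, n_sweeps, last_max_delta)``.
    """
    n_var, n_obs = XT.shape
    r = z - w0 - XT.T @ w
    u = v * r
    vsum = v.sum()
    den = np.empty(n_var)
    for j in range(n_var):
        s = 0.0
        for n in range(n_obs):
            s += v[n] * XT[j, n] * XT[j, n]
        den[j] = s
    sweeps = 0
    delta_max = 0.0
    while sweeps < max_sweeps:
        delta_max = 0.0
        if fit_intercept and vsum > 0.0:
            w0, d = _intercept_step(r, u, v, vsum, w0)
            if abs(d) > delta_max:
                delta_max = abs(d)
        d_full = _sweep(XT, r, u, v, w, lam, nonneg, den, False)
        if d_full > delta_max:
            delta_max = d_full
        sweeps += 1
        if delta_max < tol:
            break
        while sweeps < max_sweeps:
            d_act = _sweep(XT, r, u, v, w, lam, nonneg, den, True)
            if fit_intercept and vsum > 0.0:
                w0, d = _intercept_step(r, u, v, vsum, w0)
                if abs(d) > d_act:
                    d_act = abs(d)
            sweeps += 1
            if d_act < tol:
                break
    return w0, sweeps, delta_max


@njit(cache=True, fastmath=True)
def irls_cd_binomial(XT, y, w0, w, lam, nonneg, fit_intercept, tol,
                     max_outer, inner_tol, max_inner):
    """Full IRLS loop for the L1-penalized logistic likelihood.

    Each outer iteration forms the working response at the current
    linear predictor (working weights floored at 1e-5) and solves the
    weighted quadratic by ``cd_weighted_gaussian``.  Converges when no
    coefficient (intercept included) moves more than ``tol`` across an
    outer iteration.  Returns ``(w0, n_outer, converged)``.
    """
    n_var, n_obs = XT.shape
    v = np.empty(n_obs)
    z = np.empty(n_obs)
    w_prev = np.empty(n_var)
    converged = False
    outer = 0
    for outer in range(1, max_outer + 1):
        eta = w0 + XT.T @ w
        delta = 0.0
        for n in range(n_obs):
            e = eta[n]
            if e >= 0.0:
                mu = 1.0 / (1.0 + np.exp(-e))
            else:
                ex = np.exp(e)
                mu = ex / (1.0 + ex)
            vv = mu * (1.0 - mu)
            if vv < _WEIGHT_FLOOR:
                vv = _WEIGHT_FLOOR
            v[n] = vv
            z[n] = e + (y[n] - mu) / vv
        for j in range(n_var):
            w_prev[j] = w[j]
        w0_prev = w0
        w0, _, _ = cd_weighted_gaussian(
            XT, z, v, w0, w, lam, nonneg, fit_intercept, inner_tol, max_inner
        )
        delta = abs(w0 - w0_prev)
        for j in range(n_var):
            if abs(w[j] - w_prev[j]) > delta:
                delta = abs(w[j] - w_prev[j])
        if delta < tol:
            converged = True
            break
    return w0, outer, converged
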