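"""Compiled inner loops for the layer integrators.

The Prandtl layer uses a backward-Euler elastic-predictor / plastic-corrector
(return mapping) step; the discrete consistency residual is solved with a
bisection-safeguarded Newton iteration.  The Maxwell layer uses the exact
exponential step for piecewise-linear strain.  Both loops are strictly
sequential, hence the numba compilation.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# hardening codes (kept in sync with params._HARDENING_CODES)
HARD_VOCE = 0
HARD_LINEAR = 1
HARD_PERFECT = 2

RETMAP_MAXITER = 100


@njit(cache=True)
def _yield_limit(alpha, sigma_Y, sigma_u, p, hard, H):
    if hard == HARD_VOCE:
        return sigma_Y + (sigma_u - sigma_Y) * (1.0 - np.exp(-alpha * p))
    elif hard == HARD_LINEAR:
        return sigma_Y + H * alpha
    else:
        return sigma_Y


@njit(cache=True)
def prandtl_loop(
    eps,
    E_pr,
    sigma_Y,
    sigma_u,
    p,
    hard,
    H,
    eps_p0,
    alpha0,
    tol,
):
    """Return-mapping integration of the Prandtl layer.

    Returns (sigma_pr, eps_p, alpha, err_step); err_step is -1 on success and
    the offending sample index if the consistency root-find fails.
    """
    n = eps.size
    sigma = np.empty(n)
    eps_p = np.empty(n)
    alpha = np.empty(n)
    ep = eps_p0
    a = alpha0
    for i in range(n):
        trial = E_pr * (eps[i] - ep)
        f = abs(trial) - _yield_limit(a, sigma_Y, sigma_u, p, hard, H)
        if f > 0.0:
            if hard == HARD_PERFECT:
                dg = f / E_pr
            elif hard == HARD_LINEAR:
                dg = f / (E_pr + H)
            else:
                # Solve g(dg) = |trial| - E_pr*dg - k(a + dg) = 0 on (0, f/E_pr].
                # g is strictly decreasing; g(0) = f > 0 and g(f/E_pr) <= 0.
                # Newton with bisection safeguard (rtsafe): bisect whenever the
                # Newton step leaves the bracket or fails to halve the error.
                lo = 0.0
                hi = f / E_pr
                xacc = 4e-16 * hi + 1e-20
                dg = f / (E_pr + (sigma_u - sigma_Y) * p * np.exp(-p * a))
                if dg <= lo or dg >= hi:
                    dg = 0.5 * hi
                dx_old = hi - lo
                dx = dx_old
                converged = False
                for _ in range(RETMAP_MAXITER):
                    g = (
                        abs(trial)
                        - E_pr * dg
                        - _yield_limit(a + dg, sigma_Y, sigma_u, p, hard, H)
                    )
                    if abs(g) <= tol:
                        converged = True
                        break
                    if g > 0.0:
                        lo = dg
                    else:
                        hi = dg
                    if hi - lo <= xacc:
                        converged = True
                        break
                    gp = -E_pr - (sigma_u - sigma_Y) * p * np.exp(-p * (a + dg))
                    newton = ((dg - hi) * gp - g) * ((dg - lo) * gp - g) < 0.0 and abs(
                        2.0 * g
                    ) <= abs(dx_old * gp)
                    dx_old = dx
                    if newton:
                        dx = g / gp
                        cand = dg - dx
                    else:
                        dx = 0.5 * (hi - lo)
                        cand = lo + dx
                    if cand <= lo or cand >= hi:
                        cand = 0.5 * (lo + hi)
                    dg = cand
                if not converged:
                    return sigma, eps_p, alpha, i
            s = 1.0 if trial >= 0.0 else -1.0
            ep += dg * s
            a += dg
            trial = E_pr * (eps[i] - ep)
        sigma[i] = trial
        eps_p[i] = ep
        alpha[i] = a
    return sigma, eps_p, alpha, -1


@njit(cache=True)
def maxwell_loop(t, eps, E_mx, eta, sigma0):
    """Exact exponential stepping of the Maxwell layer for piecewise-linear strain."""
    n = t.size
    sigma = np.empty(n)
    sigma[0] = sigma0
    tau = eta / E_mx
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        rate = (eps[i] - eps[i - 1]) / dt
        decay = np.exp(-dt / tau)
        sigma[i] = sigma[i - 1] * decay + eta * rate * (1.0 - decay)
    return sigma
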