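"""Independent fine-step reference integrators used only by the tests.

These are deliberately naive integrations of the continuous-time rate
equations (explicit stepping of the closed-form slip rate for the plastic
layer; a generic adaptive ODE solver for the viscous layer), written without
any code shared with the package's return-mapping / exponential-step
integrators.
"""
import numpy as np
from scipy.integrate import solve_ivp


def refine_signal(t, eps, factor):
    """Insert ``factor``-fold linear subdivisions into each interval."""
    ts, es = [t[0]], [eps[0]]
    for i in range(1, len(t)):
        sub_t = np.linspace(t[i - 1], t[i], factor + 1)[1:]
        sub_e = np.linspace(eps[i - 1], eps[i], factor + 1)[1:]
        ts.extend(sub_t)
        es.extend(sub_e)
    return np.array(ts), np.array(es)


def prandtl_explicit(t, eps, E_pr, sigma_Y, sigma_u, p):
    """Explicit integration of the Voce slip-rate form of the Prandtl layer.

    On the yield surface, the slip rate is
    ``gamma = sign(sigma) E eps_dot / (E + (sigma_u - sigma_Y) p e^{-p a})``
    whenever it is nonnegative (flow directed outward); otherwise the step is
    elastic.  Plastic strain evolves as ``eps_p_dot = gamma sign(sigma)`` and
    the equivalent plastic strain as ``alpha_dot = gamma``.

    Returns the full (sigma, alpha) histories on the supplied grid.
    """
    ep = 0.0
    a = 0.0
    n = len(t)
    sigma = np.empty(n)
    alpha = np.empty(n)
    sigma[0] = E_pr * (eps[0] - ep)
    alpha[0] = a
    for i in range(1, n):
        de = eps[i] - eps[i - 1]
        s = E_pr * (eps[i - 1] - ep)
        k = sigma_Y + (sigma_u - sigma_Y) * (1.0 - np.exp(-a * p))
        if abs(s) >= k * (1.0 - 1e-12) and s * de > 0:
            hard = (sigma_u - sigma_Y) * p * np.exp(-p * a)
            gamma_dt = np.sign(s) * E_pr * de / (E_pr + hard)  # >= 0 here
            ep += gamma_dt * np.sign(s)
            a += gamma_dt
        sigma[i] = E_pr * (eps[i] - ep)
        alpha[i] = a
    return sigma, alpha


def maxwell_ode(t, eps, E_mx, eta):
    """Generic adaptive ODE solution of the Maxwell governing equation.

    Integrates ``sigma_dot = E_mx eps_dot - (E_mx/eta) sigma`` segment by
    segment (the strain rate is constant between samples) with tight
    tolerances; returns sigma on the input grid.
    """
    sigma = np.empty(len(t))
    sigma[0] = 0.0
    for i in range(1, len(t)):
        rate = (eps[i] - eps[i - 1]) / (t[i] - t[i - 1])
        sol = solve_ivp(
            lambda tt, y: [E_mx * rate - (E_mx / eta) * y[0]],
            (t[i - 1], t[i]),
            [sigma[i - 1]],
            rtol=1e-12,
            atol=1e-14,
        )
        sigma[i] = sol.y[0, -1]
    return sigma
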