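"""Strain-driven time integration of the two-layer elasto-visco-plastic model.

The model superposes a rate-independent Prandtl layer (elastic spring +
hardening frictional slider) and a viscoelastic Maxwell layer (spring +
dashpot) loaded in parallel by a common strain history:

    sigma_mod(t) = sigma_pr(t) + sigma_mx(t)

The Prandtl layer is integrated by backward-Euler return mapping (elastic
predictor, plastic corrector on the discrete consistency condition); the
Maxwell layer by the exact exponential step for piecewise-linear strain.
Both layers are decoupled and integrated independently.

Sign convention: tension positive; the yield condition uses ``|sigma_pr|``
so the model is symmetric in compression.
"""
from __future__ import annotations

import numpy as np

from . import _kernels
from .exceptions import IntegrationError, ParameterError
from .params import MaterialParams, ModelVariant
from .signals import ModelTrajectory, StrainSignal

__all__ = [
    "yield_function",
    "integrate_prandtl",
    "integrate_maxwell",
    "simulate",
    "TwoLayerModel",
]

#: Relative tolerance (times sigma_Y) of the return-mapping consistency solve.
RETMAP_RTOL = 1e-10


def yield_function(
    sigma_pr,
    alpha,
    params: MaterialParams,
    variant: ModelVariant = ModelVariant(),
):
    """Yield condition ``f = |sigma_pr| - k(alpha)`` [MPa].

    ``k`` is the current yield limit: Voce exponential saturation
    ``sigma_Y + (sigma_u - sigma_Y)(1 - exp(-alpha p))``, linear
    ``sigma_Y + H alpha``, or constant ``sigma_Y`` for perfect plasticity.
    Stress states with ``f < 0`` are elastic; ``f = 0`` permits plastic flow;
    ``f > 0`` is inadmissible.
    """
    sigma_pr = np.asarray(sigma_pr, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0):
        raise ParameterError("equivalent plastic strain alpha must be >= 0")
    H = variant.linear_coeff if variant.hardening == "linear" else 0.0
    if variant.hardening == "voce":
        limit = params.sigma_Y + (params.sigma_u - params.sigma_Y) * (
            1.0 - np.exp(-alpha * params.p)
        )
    elif variant.hardening == "linear":
        limit = params.sigma_Y + H * alpha
    else:
        limit = params.sigma_Y + 0.0 * alpha
    out = np.abs(sigma_pr) - limit
    return out.item() if out.ndim == 0 else out


def integrate_prandtl(
    signal: StrainSignal,
    params: MaterialParams,
    variant: ModelVariant = ModelVariant(),
    eps_p0: float = 0.0,
    alpha0: float = 0.0,
):
    """Integrate the Prandtl layer; returns ``(sigma_pr, eps_p, alpha)`` arrays.

    Per step the elastic predictor is ``sigma_trial = E_pr (eps - eps_p)``;
    if it is admissible the step is elastic, otherwise the plastic multiplier
    increment ``dgamma > 0`` solving the discrete consistency condition
    ``f(sigma, alpha + dgamma) = 0`` is found (closed form for linear/perfect
    hardening, safeguarded Newton for Voce) and the internal variables are
    updated ``eps_p += dgamma sign(sigma_trial)``, ``alpha += dgamma``.
    """
    if not variant.plasticity_enabled:
        sigma = params.E_pr * signal.eps
        zeros = np.zeros_like(sigma)
        return sigma, zeros + eps_p0, zeros + alpha0
    H = variant.linear_coeff if variant.hardening == "linear" else 0.0
    sigma, eps_p, alpha, err = _kernels.prandtl_loop(
        signal.eps,
        params.E_pr,
        params.sigma_Y,
        params.sigma_u,
        params.p,
        variant.hardening_code,
        float(H),
        float(eps_p0),
        float(alpha0),
        RETMAP_RTOL * params.sigma_Y,
    )
    if err >= 0:
        raise IntegrationError(
            f"return-mapping consistency solve failed at step {err}", step=int(err)
        )
    return sigma, eps_p, alpha


def integrate_maxwell(
    signal: StrainSignal,
    params: MaterialParams,
    variant: ModelVariant = ModelVariant(),
    sigma0: float = 0.0,
):
    """Integrate the Maxwell layer; returns the ``sigma_mx`` array.

    Solves ``d(sigma)/dt + (E_mx/eta) sigma = E_mx d(eps)/dt`` exactly per
    step under piecewise-linear strain: with relaxation time ``tau = eta/E_mx``
    and step rate ``r``, ``sigma_{n+1} = sigma_n exp(-dt/tau)
    + eta r (1 - exp(-dt/tau))``.  A disabled layer (or ``E_mx = eta = 0``)
    yields identically zero stress.
    """
    if not variant.maxwell_enabled or (params.E_mx == 0.0 and params.eta == 0.0):
        return np.zeros_like(signal.eps)
    if params.E_mx <= 0.0 or params.eta <= 0.0:
        raise ParameterError(
            "Maxwell layer requires E_mx > 0 and eta > 0 "
            "(disable the layer via ModelVariant for ablations)"
        )
    return _kernels.maxwell_loop(
        signal.t, signal.eps, params.E_mx, params.eta, float(sigma0)
    )


def simulate(
    signal: StrainSignal,
    params: MaterialParams,
    variant: ModelVariant = ModelVariant(),
    *,
    eps_p0: float = 0.0,
    alpha0: float = 0.0,
    sigma_mx0: float = 0.0,
) -> ModelTrajectory:
    """Run both layers over ``signal`` and superpose them into a trajectory.

    The damper strain is recovered as ``eps_v = eps - sigma_mx / E_mx``
    (zero when the Maxwell layer is disabled).  Initial internal state
    defaults to zero but may be overridden for chained simulations.
    """
    sigma_pr, eps_p, alpha = integrate_prandtl(
        signal, params, variant, eps_p0=eps_p0, alpha0=alpha0
    )
    sigma_mx = integrate_maxwell(signal, params, variant, sigma0=sigma_mx0)
    maxwell_active = variant.maxwell_enabled and params.E_mx > 0 and params.eta > 0
    if maxwell_active:
        eps_v = signal.eps - sigma_mx / params.E_mx
    else:
        eps_v = np.zeros_like(signal.eps)
    return ModelTrajectory(
        t=signal.t,
        eps=signal.eps,
        sigma_mod=sigma_pr + sigma_mx,
        sigma_pr=sigma_pr,
        sigma_mx=sigma_mx,
        eps_p=eps_p,
        eps_v=eps_v,
        alpha=alpha,
    )


class TwoLayerModel:
    """Convenience wrapper binding a parameter set and variant to the simulator.

    >>> model = TwoLayerModel(MaterialParams(3640, 16.89, 63.99, 172.2, 1970, 3710))
    >>> traj = model.simulate(signal)          # doctest: +SKIP
    """

    def __init__(self, params: MaterialParams, variant: ModelVariant = ModelVariant()):
        self.params = params
        self.variant = variant

    def simulate(self, signal: StrainSignal, **state) -> ModelTrajectory:
        return simulate(signal, self.params, self.variant, **state)

    def stress(self, signal: StrainSignal) -> np.ndarray:
        """Total model stress response [MPa] for a strain excitation."""
        return self.simulate(signal).sigma_mod
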