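"""Closed-form viscoelastic (DMA) characterization of the model's elastic range.

Below the yield stress the two-layer model reduces to a Zener model
(standard linear solid): the Prandtl spring ``E_pr`` in parallel with the
Maxwell element ``(E_mx, eta)``.  Its governing equation

    sigma + a dsigma/dt = b eps + c deps/dt

has constants ``a = eta/E_mx`` [s], ``b = E_pr`` [MPa] and
``c = eta (E_pr + E_mx)/E_mx`` [MPa s].  Evaluating the transfer function at
``i omega`` gives the complex modulus, whose real/imaginary parts are the
storage and loss moduli; their ratio is the loss tangent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .params import MaterialParams

__all__ = [
    "ZenerCoefficients",
    "DMAResult",
    "zener_coefficients",
    "complex_modulus",
    "loss_tangent",
    "modulus_bounds",
]


@dataclass(frozen=True)
class ZenerCoefficients:
    """Constants of the Zener governing equation: a [s], b [MPa], c [MPa·s]."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class DMAResult:
    """Storage/loss modulus [MPa] and loss tangent at angular frequency omega [rad/s]."""

    omega: np.ndarray | float
    E_storage: np.ndarray | float
    E_loss: np.ndarray | float
    tan_delta: np.ndarray | float


def zener_coefficients(params: MaterialParams) -> ZenerCoefficients:
    """Zener coefficients (a, b, c) of the elastic-range equivalent model.

    Raises
    ------
    ParameterError
        If ``E_mx`` or ``eta`` is zero (degenerate Zener model: the
        coefficients divide by ``E_mx`` and the layer carries no state).
    """
    if params.E_mx <= 0 or params.eta <= 0:
        raise ParameterError(
            "Zener coefficients are undefined for E_mx = 0 or eta = 0"
        )
    a = params.eta / params.E_mx
    b = params.E_pr
    c = params.eta * (params.E_pr + params.E_mx) / params.E_mx
    return ZenerCoefficients(a=a, b=b, c=c)


def complex_modulus(params: MaterialParams, omega) -> DMAResult:
    """Storage and loss modulus at angular frequency ``omega`` [rad/s].

    ``E' = (a c w^2 + b) / (a^2 w^2 + 1)``,
    ``E'' = (c w - a b w) / (a^2 w^2 + 1)``.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ParameterError("omega must be >= 0")
    z = zener_coefficients(params)
    denom = z.a**2 * omega**2 + 1.0
    e_store = (z.a * z.c * omega**2 + z.b) / denom
    e_loss = (z.c - z.a * z.b) * omega / denom
    with np.errstate(invalid="ignore", divide="ignore"):
        tan_d = np.where(e_store > 0, e_loss / e_store, np.nan)
    if omega.ndim == 0:
        return DMAResult(
            omega=omega.item(),
            E_storage=e_store.item(),
            E_loss=e_loss.item(),
            tan_delta=tan_d.item(),
        )
    return DMAResult(omega=omega, E_storage=e_store, E_loss=e_loss, tan_delta=tan_d)


def complex_modulus_hz(params: MaterialParams, f_hz) -> DMAResult:
    """As :func:`complex_modulus` but for frequency in Hz (``omega = 2 pi f``)."""
    return complex_modulus(params, 2.0 * np.pi * np.asarray(f_hz, dtype=float))


def loss_tangent(params: MaterialParams, omega):
    """Loss tangent ``tan(delta) = E''/E' = (c w - a b w)/(a c w^2 + b)``."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ParameterError("omega must be > 0 for the loss tangent")
    z = zener_coefficients(params)
    out = (z.c - z.a * z.b) * omega / (z.a * z.c * omega**2 + z.b)
    return out.item() if out.ndim == 0 else out


def loss_tangent_hz(params: MaterialParams, f_hz):
    """Loss tangent at frequency ``f_hz`` in Hz."""
    return loss_tangent(params, 2.0 * np.pi * np.asarray(f_hz, dtype=float))


def modulus_bounds(params: MaterialParams) -> tuple[float, float]:
    """(long-term, instantaneous) Young's modulus bounds ``(E_pr, E_pr + E_mx)``.

    Quasi-static loading leaves the Maxwell layer relaxed, so the long-term
    stiffness is ``E_pr``; a step load engages both springs, giving the
    instantaneous stiffness ``E_pr + E_mx``.  Any apparent modulus measured at
    finite strain rate on noise-free model data lies between the two.
    """
    return params.E_pr, params.E_pr + params.E_mx
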