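"""Classical apparent-property extraction and strain-measure utilities.

An apparent Young's modulus measured at finite strain rate mixes the elastic
and viscous response; on noise-free model data it lies between the long-term
modulus ``E_pr`` and the instantaneous modulus ``E_pr + E_mx`` and grows with
strain rate.  The R-squared window method reproduces the classical extraction:
starting from a minimum number of points at the ramp's origin, the fit window
grows until the coefficient of determination peaks; the slope on that window
is the apparent modulus.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import simulate
from .exceptions import SignalError
from .params import MaterialParams, ModelVariant
from .signals import StrainSignal

__all__ = [
    "LinearFitWindow",
    "apparent_modulus_r2",
    "offset_yield_stress",
    "kink_stress",
    "rate_sweep",
    "true_stress_underestimation",
    "logarithmic_strain",
]


@dataclass(frozen=True)
class LinearFitWindow:
    """Selected linear region and its least-squares fit."""

    start_index: int
    end_index: int  # exclusive
    slope: float  # MPa per unit strain
    intercept: float  # MPa
    r_squared: float


def apparent_modulus_r2(
    stress: np.ndarray, strain: np.ndarray, min_window: int = 5
) -> LinearFitWindow:
    """Apparent modulus by the R-squared window method on a loading ramp.

    Windows are anchored at the first sample and grown one point at a time
    from ``min_window`` to the full series; the window with the maximum
    R-squared (largest window on ties) defines the linear region and its
    least-squares slope is the apparent modulus E_app.
    """
    stress = np.asarray(stress, dtype=float)
    strain = np.asarray(strain, dtype=float)
    if stress.shape != strain.shape or stress.ndim != 1:
        raise SignalError("stress and strain must be 1-D arrays of equal length")
    n = stress.size
    if n < min_window or min_window < 2:
        raise SignalError(
            f"need at least min_window={min_window} >= 2 samples, got {n}"
        )
    # cumulative sums allow O(1) regression per window
    cx = np.cumsum(strain)
    cy = np.cumsum(stress)
    cxx = np.cumsum(strain * strain)
    cxy = np.cumsum(strain * stress)
    cyy = np.cumsum(stress * stress)

    best = None  # (k, slope, intercept, r2)
    best_r2 = -np.inf  # running max, kept separate for tie control
    for k in range(min_window, n + 1):
        m = float(k)
        sx, sy = cx[k - 1], cy[k - 1]
        sxx, sxy, syy = cxx[k - 1], cxy[k - 1], cyy[k - 1]
        var_x = sxx - sx * sx / m
        var_y = syy - sy * sy / m
        cov = sxy - sx * sy / m
        if var_x <= 0:
            continue
        slope = cov / var_x
        intercept = (sy - slope * sx) / m
        if var_y <= 0:
            r2 = 1.0
        else:
            ss_res = var_y - slope * cov
            r2 = 1.0 - max(ss_res, 0.0) / var_y
        # prefer the largest window among R^2 ties (to rounding noise)
        if r2 >= best_r2 - 1e-12:
            best = (k, slope, intercept, r2)
            best_r2 = max(best_r2, r2)
    if best is None:
        raise SignalError("strain has no variation; cannot fit a modulus")
    k, slope, intercept, r2 = best
    return LinearFitWindow(
        start_index=0, end_index=k, slope=slope, intercept=intercept, r_squared=r2
    )


def offset_yield_stress(strain, stress, slope, offset=0.002):
    """Stress at the intersection with the ``slope``-line offset by 0.2 % strain.

    Classical offset-yield construction; returns NaN if the curve never
    crosses the offset line.  Note that with a rate-dependent slope this
    metric is not monotone in strain rate (see :func:`kink_stress`).
    """
    line = slope * (np.asarray(strain) - offset)
    diff = np.asarray(stress) - line
    sign_change = np.where(np.diff(np.sign(diff)) < 0)[0]
    if sign_change.size == 0:
        return float("nan")
    i = sign_change[0]
    # linear interpolation of the crossing
    frac = diff[i] / (diff[i] - diff[i + 1])
    return float(stress[i] + frac * (stress[i + 1] - stress[i]))


def kink_stress(strain, stress):
    """Stress at the yield kink: the point of maximum curvature of the curve.

    On noise-free model ramps this locates the elastic-to-plastic transition;
    its quasi-static limit is the yield stress and, because stress-strain
    curves at different rates are pointwise ordered, it grows monotonically
    with strain rate.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain.size < 11:
        raise SignalError("kink detection needs at least 11 samples")
    d2 = np.gradient(np.gradient(stress, strain), strain)
    i = int(np.argmax(np.abs(d2[5:-5]))) + 5
    return float(stress[i])


def rate_sweep(
    params: MaterialParams,
    variant: ModelVariant = ModelVariant(),
    rates=(1e-4, 1e-3, 1e-2, 1e-1, 1.0),
    eps_max: float = 0.05,
    n_steps: int = 2000,
) -> tuple[dict, pd.DataFrame]:
    """Constant-rate ramps to ``eps_max`` at each strain rate [1/s].

    Returns ``(curves, table)``: ``curves`` maps rate -> trajectory, and
    ``table`` lists per rate the apparent initial slope (R-squared window on
    the pre-yield portion) and the apparent yield stress at the curve's kink
    (maximum-curvature point; NaN if the ramp never yields).  Both grow with
    strain rate for the two-layer model; the slope is bounded by
    ``[E_pr, E_pr + E_mx]``.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise SignalError("strain rates must be positive")
    curves = {}
    rows = []
    eps = np.linspace(0.0, eps_max, n_steps + 1)
    for rate in rates:
        signal = StrainSignal(t=eps / rate, eps=eps)
        traj = simulate(signal, params, variant)
        curves[float(rate)] = traj
        pre_yield = traj.alpha <= 0.0
        n_pre = max(int(np.sum(pre_yield)), 6)
        fit = apparent_modulus_r2(
            traj.sigma_mod[:n_pre], traj.eps[:n_pre], min_window=5
        )
        if traj.alpha[-1] > 0:
            sigma_yield = kink_stress(traj.eps, traj.sigma_mod)
        else:
            sigma_yield = float("nan")
        rows.append(
            {
                "rate": float(rate),
                "apparent_slope_MPa": fit.slope,
                "apparent_yield_MPa": sigma_yield,
            }
        )
    return curves, pd.DataFrame(rows)


def true_stress_underestimation(eps_eng: float, nu: float) -> float:
    """Percent underestimation of true stress by engineering stress.

    Under uniaxial tension with lateral contraction ratio ``nu``, the current
    cross-section shrinks by ``(1 - nu eps)^2``, so engineering stress
    understates true stress by ``100 (1 - (1 - nu eps)^2)`` percent.
    """
    x = nu * eps_eng
    if x < 0 or x >= 1:
        raise SignalError("require 0 <= nu*eps < 1")
    return 100.0 * (1.0 - (1.0 - x) ** 2)


def logarithmic_strain(eps_eng):
    """Logarithmic (true) strain ``ln(1 + eps)`` conjugate to true stress."""
    eps_eng = np.asarray(eps_eng, dtype=float)
    if np.any(eps_eng <= -1):
        raise SignalError("engineering strain must exceed -1")
    out = np.log1p(eps_eng)
    return out.item() if out.ndim == 0 else out
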