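"""Inverse material-parameter identification by multi-start downhill simplex.

The goodness of fit between the model stress response and a measured stress
series is the corner-weighted root-mean-square error

    RMSE_w(q) = sqrt( (1/n) sum_i w_i (sigma_mod(q, t_i) - sigma_exp(t_i))^2 )

with n the *total* number of samples (not the weighted count) and binary
weights concentrated at the loading-profile corner points.  The objective is
minimized with Nelder-Mead started from every point of a Cartesian grid over
the parameter search box; the best of all local solutions is kept as the
quasi-global solution q*.  Positivity of all parameters (and sigma_u >=
sigma_Y) is enforced structurally by optimizing over log-transformed internal
coordinates (E_pr, sigma_Y, delta_u, p, E_mx, eta) with delta_u = sigma_u -
sigma_Y.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import dma
from .core import simulate
from .exceptions import ConfigError, IntegrationError, ParameterError, SignalError
from .params import (
    PARAM_NAMES,
    MaterialParams,
    ModelVariant,
    ParamRanges,
    StartGrid,
    build_start_grid,
)
from .signals import StrainSignal

__all__ = [
    "weighted_rmse",
    "build_start_grid",
    "multistart_identify",
    "identify_specimen",
    "fit_linear_hardening",
    "correct_for_prestress",
    "sensitivity_scan",
    "summarize_cohort",
    "OptimizationResult",
    "TwoLayerRegressor",
]


def _wrmse(residual: np.ndarray, w: np.ndarray) -> float:
    return float(np.sqrt(np.mean(w * residual**2)))


def _check_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise SignalError(f"weight vector length {w.size} != signal length {n}")
    if not np.any(w > 0):
        raise SignalError("weight vector must have at least one nonzero entry")
    return w


def weighted_rmse(
    params: MaterialParams,
    variant: ModelVariant,
    signal: StrainSignal,
    sigma_exp: np.ndarray,
    w: np.ndarray,
) -> float:
    """Corner-weighted RMSE [MPa] between model response and measured stress.

    With all weights equal to 1 this reduces to the plain RMSE.
    """
    sigma_exp = np.asarray(sigma_exp, dtype=float)
    if sigma_exp.shape != signal.t.shape:
        raise SignalError("sigma_exp length must match the strain signal")
    w = _check_weights(w, len(signal))
    sigma_mod = simulate(signal, params, variant).sigma_mod
    return _wrmse(sigma_mod - sigma_exp, w)


# ---------------------------------------------------------------------------
# internal log-coordinate transform


def _encode(internal: np.ndarray) -> np.ndarray:
    return np.log(internal)


def _decode(theta: np.ndarray) -> MaterialParams:
    e, sy, du, p, em, et = np.exp(theta)
    return MaterialParams(E_pr=e, sigma_Y=sy, sigma_u=sy + du, p=p, E_mx=em, eta=et)


@dataclass(frozen=True)
class StartRecord:
    """Outcome of one Nelder-Mead run of the multi-start sweep."""

    index: int
    start: tuple
    objective: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class OptimizationResult:
    """Best-of-all-starts identification result.

    ``rmse_w`` is the weighted objective at ``q_star``; ``rmse`` is the
    unweighted RMSE evaluated at the same point for interpretability.
    """

    q_star: MaterialParams
    rmse_w: float
    rmse: float
    n_starts: int
    per_start: tuple = field(repr=False, default=())
    best_start_index: int = -1

    def to_dict(self) -> dict:
        return {
            "q_star": self.q_star.to_dict(),
            "rmse_w_MPa": self.rmse_w,
            "rmse_MPa": self.rmse,
            "n_starts": self.n_starts,
            "best_start_index": self.best_start_index,
        }


def multistart_identify(
    signal: StrainSignal,
    sigma_exp: np.ndarray,
    w: np.ndarray,
    ranges: ParamRanges | None = None,
    grid: StartGrid | None = None,
    variant: ModelVariant = ModelVariant(),
    *,
    points_per_param: int = 4,
    xatol: float = 1e-3,
    fatol: float = 1e-3,
    maxiter: int = 2000,
    n_polish: int = 3,
) -> OptimizationResult:
    """Identify material parameters for one specimen by multi-start Nelder-Mead.

    Runs a downhill-simplex minimization of the weighted RMSE from every point
    of ``grid`` (built from ``ranges`` with ``points_per_param`` points per
    parameter when not supplied) and keeps the solution with the lowest
    objective; ties break to the lowest start index, so the result is
    independent of execution order.  The winning point is polished by
    restarting Nelder-Mead from it up to ``n_polish`` times (a fresh simplex
    escapes the collapsed one).  Individual start failures are recorded, not
    fatal; only all starts failing raises.

    Parameters are optimized in log space, so the positivity constraint and
    ``sigma_u >= sigma_Y`` hold at every evaluated point.
    """
    sigma_exp = np.asarray(sigma_exp, dtype=float)
    if sigma_exp.shape != signal.t.shape:
        raise SignalError("sigma_exp length must match the strain signal")
    w = _check_weights(w, len(signal))
    if grid is None:
        grid = build_start_grid(ranges, points_per_param)

    def objective(theta: np.ndarray) -> float:
        try:
            with np.errstate(over="ignore"):
                params = _decode(theta)
            sigma_mod = simulate(signal, params, variant).sigma_mod
        except (ParameterError, IntegrationError, FloatingPointError, OverflowError):
            return np.inf
        resid = sigma_mod - sigma_exp
        if not np.all(np.isfinite(resid)):
            return np.inf
        return _wrmse(resid, w)

    options = {"xatol": xatol, "fatol": fatol, "maxiter": maxiter}
    records = []
    best = None  # (objective, index, theta, nit)
    for i in range(len(grid)):
        theta0 = _encode(grid.points[i])
        try:
            res = minimize(objective, theta0, method="Nelder-Mead", options=options)
            obj, theta, nit, ok = float(res.fun), res.x, int(res.nit), bool(res.success)
        except Exception:
            obj, theta, nit, ok = np.inf, theta0, 0, False
        records.append(
            StartRecord(
                index=i,
                start=tuple(grid.points[i]),
                objective=obj,
                iterations=nit,
                converged=ok,
            )
        )
        if np.isfinite(obj) and (best is None or obj < best[0]):
            best = (obj, i, theta, nit)
    if best is None:
        raise ConfigError("all multi-start optimizations failed")

    obj_best, idx_best, theta_best = best[0], best[1], best[2]
    for _ in range(n_polish):
        res = minimize(objective, theta_best, method="Nelder-Mead", options=options)
        if float(res.fun) < obj_best - 1e-12:
            obj_best, theta_best = float(res.fun), res.x
        else:
            break

    q_star = _decode(theta_best)
    rmse = weighted_rmse(q_star, variant, signal, sigma_exp, np.ones_like(w))
    return OptimizationResult(
        q_star=q_star,
        rmse_w=obj_best,
        rmse=rmse,
        n_starts=len(grid),
        per_start=tuple(records),
        best_start_index=idx_best,
    )


def fit_linear_hardening(
    signal: StrainSignal,
    sigma_exp: np.ndarray,
    w: np.ndarray,
    ranges: ParamRanges | None = None,
    H_range: tuple[float, float] = (100.0, 10_000.0),
    points_per_param: int = 2,
    **nm_options,
) -> tuple[OptimizationResult, float]:
    """Best linear-hardening fit, with the hardening coefficient optimized.

    The ablated model replaces the Voce saturation by a linear yield-limit
    growth ``sigma_Y + H alpha``; the five free constants
    (E_pr, sigma_Y, H, E_mx, eta) are identified by the same multi-start
    log-space Nelder-Mead.  Returns the optimization result (whose ``q_star``
    carries a placeholder ``sigma_u = sigma_Y``, ``p = 1``) and the optimized
    coefficient H [MPa].
    """
    sigma_exp = np.asarray(sigma_exp, dtype=float)
    w = _check_weights(w, len(signal))
    if ranges is None:
        ranges = ParamRanges()
    b = ranges.as_bounds()
    axes = [
        np.linspace(*b[0], points_per_param),  # E_pr
        np.linspace(*b[1], points_per_param),  # sigma_Y
        np.linspace(*H_range, points_per_param),  # H
        np.linspace(*b[4], points_per_param),  # E_mx
        np.linspace(*b[5], points_per_param),  # eta
    ]
    import itertools

    starts = np.array(list(itertools.product(*axes)), dtype=float)

    def decode(theta):
        e, sy, H, em, et = np.exp(theta)
        params = MaterialParams(E_pr=e, sigma_Y=sy, sigma_u=sy, p=1.0, E_mx=em, eta=et)
        return params, ModelVariant(hardening="linear", linear_coeff=H)

    def objective(theta):
        try:
            with np.errstate(over="ignore"):
                params, variant = decode(theta)
            sigma_mod = simulate(signal, params, variant).sigma_mod
        except (ParameterError, IntegrationError, FloatingPointError, OverflowError):
            return np.inf
        resid = sigma_mod - sigma_exp
        if not np.all(np.isfinite(resid)):
            return np.inf
        return _wrmse(resid, w)

    options = {
        "xatol": nm_options.get("xatol", 1e-3),
        "fatol": nm_options.get("fatol", 1e-3),
        "maxiter": nm_options.get("maxiter", 2000),
    }
    records = []
    best = None
    for i, s in enumerate(starts):
        res = minimize(objective, np.log(s), method="Nelder-Mead", options=options)
        records.append(
            StartRecord(
                index=i,
                start=tuple(s),
                objective=float(res.fun),
                iterations=int(res.nit),
                converged=bool(res.success),
            )
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
            best = (float(res.fun), i, res.x)
    if best is None:
        raise ConfigError("all linear-hardening starts failed")
    obj_best, idx_best, theta_best = best
    for _ in range(3):
        res = minimize(objective, theta_best, method="Nelder-Mead", options=options)
        if float(res.fun) < obj_best - 1e-12:
            obj_best, theta_best = float(res.fun), res.x
        else:
            break
    params, variant = decode(theta_best)
    rmse = weighted_rmse(params, variant, signal, sigma_exp, np.ones_like(w))
    result = OptimizationResult(
        q_star=params,
        rmse_w=obj_best,
        rmse=rmse,
        n_starts=len(starts),
        per_start=tuple(records),
        best_start_index=idx_best,
    )
    return result, float(variant.linear_coeff)


def identify_specimen(record, **kwargs) -> OptimizationResult:
    """Run :func:`multistart_identify` on a specimen record.

    ``record`` is any object exposing ``t``, ``eps``, ``sigma_exp`` and
    ``weights`` arrays (e.g. :class:`bonerheo.synthetic.SpecimenRecord`).
    """
    signal = StrainSignal(t=record.t, eps=record.eps)
    return multistart_identify(signal, record.sigma_exp, record.weights, **kwargs)


def correct_for_prestress(q_star: MaterialParams, prestress: float) -> MaterialParams:
    """Add the preload-induced prestress back onto sigma_Y and sigma_u.

    The fit runs on data shifted to zero stress at t = 0, so the identified
    yield and ultimate stress are low by the prestress removed in the shift;
    the other four parameters are unaffected.
    """
    if prestress < 0:
        raise ParameterError("prestress must be >= 0")
    return q_star.replace(
        sigma_Y=q_star.sigma_Y + prestress, sigma_u=q_star.sigma_u + prestress
    )


def sensitivity_scan(
    q_star: MaterialParams,
    signal: StrainSignal,
    sigma_exp: np.ndarray,
    w: np.ndarray,
    factors,
    variant: ModelVariant = ModelVariant(),
) -> pd.DataFrame:
    """Objective landscape around the optimum, one parameter scaled at a time.

    For each of the six parameters and each scale factor, evaluates RMSE_w
    with that parameter multiplied by the factor while the others stay at
    their optimum.  Scaled parameter sets that violate the model's
    admissibility (e.g. ``sigma_u < sigma_Y``) yield NaN.  ``factors`` must
    include 1.0 so each curve passes through RMSE_w(q*).

    Returns a DataFrame indexed by factor with one column per parameter.
    """
    factors = np.asarray(factors, dtype=float)
    if not np.any(np.isclose(factors, 1.0)):
        raise ConfigError("factors must include 1.0")
    out = {}
    for name in PARAM_NAMES:
        curve = np.empty(factors.size)
        for j, fac in enumerate(factors):
            try:
                scaled = q_star.replace(**{name: getattr(q_star, name) * fac})
                curve[j] = weighted_rmse(scaled, variant, signal, sigma_exp, w)
            except (ParameterError, SignalError):
                curve[j] = np.nan
        out[name] = curve
    return pd.DataFrame(out, index=pd.Index(factors, name="factor"))


def summarize_cohort(
    results,
    prestresses=None,
    tan_delta_freq_hz: float = 1.0,
) -> pd.DataFrame:
    """Cohort summary table: mean and SD of each identified quantity.

    Rows are RMSE, the six material parameters (sigma_Y and sigma_u corrected
    for each specimen's prestress when ``prestresses`` is given) and the loss
    tangent at ``tan_delta_freq_hz`` (per-specimen loss tangents averaged).
    """
    results = list(results)
    if not results:
        raise ConfigError("summarize_cohort needs at least one result")
    if prestresses is None:
        prestresses = [0.0] * len(results)
    if len(prestresses) != len(results):
        raise ConfigError("one prestress per result required")
    rows = {name: [] for name in ("RMSE", *PARAM_NAMES, "tan_delta")}
    for res, pre in zip(results, prestresses):
        q = correct_for_prestress(res.q_star, pre)
        rows["RMSE"].append(res.rmse)
        for name in PARAM_NAMES:
            rows[name].append(getattr(q, name))
        try:
            td = dma.loss_tangent_hz(res.q_star, tan_delta_freq_hz)
        except ParameterError:
            td = np.nan
        rows["tan_delta"].append(td)
    table = pd.DataFrame(
        {
            "mean": {k: float(np.mean(v)) for k, v in rows.items()},
            "sd": {k: float(np.std(v, ddof=1)) if len(results) > 1 else 0.0
                   for k, v in rows.items()},
        }
    )
    table.index.name = "quantity"
    return table


class TwoLayerRegressor:
    """Scikit-learn style estimator for the inverse identification.

    ``fit(X, y, sample_weight=...)`` expects ``X`` of shape (n, 2) with
    columns (time [s], engineering strain) and ``y`` the measured stress
    [MPa]; ``sample_weight`` is the binary corner-weight vector (all-ones
    when omitted, i.e. a plain-RMSE fit).  After fitting, ``params_`` holds
    the identified :class:`MaterialParams`, ``rmse_w_``/``rmse_`` the
    objective values and ``result_`` the full :class:`OptimizationResult`.
    ``predict(X)`` returns the fitted model's stress response.
    """

    def __init__(
        self,
        ranges: ParamRanges | None = None,
        points_per_param: int = 4,
        hardening: str = "voce",
        linear_coeff: float | None = None,
        xatol: float = 1e-3,
        fatol: float = 1e-3,
        maxiter: int = 2000,
        n_polish: int = 3,
    ):
        self.ranges = ranges
        self.points_per_param = points_per_param
        self.hardening = hardening
        self.linear_coeff = linear_coeff
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter = maxiter
        self.n_polish = n_polish

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "ranges": self.ranges,
            "points_per_param": self.points_per_param,
            "hardening": self.hardening,
            "linear_coeff": self.linear_coeff,
            "xatol": self.xatol,
            "fatol": self.fatol,
            "maxiter": self.maxiter,
            "n_polish": self.n_polish,
        }

    def set_params(self, **kw):
        valid = self.get_params()
        for k, v in kw.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for TwoLayerRegressor")
            setattr(self, k, v)
        return self

    def _variant(self) -> ModelVariant:
        return ModelVariant(hardening=self.hardening, linear_coeff=self.linear_coeff)

    @staticmethod
    def _signal(X) -> StrainSignal:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise SignalError("X must have shape (n_samples, 2): columns (t, eps)")
        return StrainSignal(t=X[:, 0], eps=X[:, 1])

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        signal = self._signal(X)
        y = np.asarray(y, dtype=float)
        if sample_weight is None:
            sample_weight = np.ones(len(signal))
        result = multistart_identify(
            signal,
            y,
            sample_weight,
            ranges=self.ranges,
            variant=self._variant(),
            points_per_param=self.points_per_param,
            xatol=self.xatol,
            fatol=self.fatol,
            maxiter=self.maxiter,
            n_polish=self.n_polish,
        )
        self.result_ = result
        self.params_ = result.q_star
        self.rmse_w_ = result.rmse_w
        self.rmse_ = result.rmse
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("TwoLayerRegressor is not fitted yet")
        signal = self._signal(X)
        return simulate(signal, self.params_, self._variant()).sigma_mod

    def score(self, X, y, sample_weight=None) -> float:
        """Coefficient of determination of the stress prediction."""
        y = np.asarray(y, dtype=float)
        pred = self.predict(X)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - np.mean(y)) ** 2)
        return float(1.0 - ss_res / ss_tot)
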