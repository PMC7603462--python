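"""Material parameters, model variants and multi-start parameter ranges.

The two-layer model combines a Prandtl layer (spring ``E_pr`` in series with a
frictional slider whose yield limit hardens from the yield stress ``sigma_Y``
toward the ultimate stress ``sigma_u`` with exponent ``p``) and a Maxwell layer
(spring ``E_mx`` in series with a dashpot of viscosity ``eta``).  Stresses and
moduli are in MPa, viscosity in MPa·s, strains dimensionless, time in seconds.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "MaterialParams",
    "ModelVariant",
    "ParamRanges",
    "StartGrid",
    "PARAM_NAMES",
]

#: Canonical ordering of the six identified constants.
PARAM_NAMES = ("E_pr", "sigma_Y", "sigma_u", "p", "E_mx", "eta")


@dataclass(frozen=True)
class MaterialParams:
    """The six material constants of the two-layer model.

    Parameters
    ----------
    E_pr : float
        Elastic modulus of the Prandtl-layer spring [MPa].  Equals the
        long-term (quasi-static) Young's modulus of the model.
    sigma_Y : float
        Yield stress of the plastic slider [MPa].
    sigma_u : float
        Ultimate stress the hardening law saturates toward [MPa];
        ``sigma_u >= sigma_Y``.
    p : float
        Dimensionless exponent shaping the exponential hardening.
    E_mx : float
        Elastic modulus of the Maxwell-layer spring [MPa].
    eta : float
        Viscosity of the Maxwell-layer dashpot [MPa·s].
    """

    E_pr: float
    sigma_Y: float
    sigma_u: float
    p: float
    E_mx: float
    eta: float

    def __post_init__(self):
        if not (self.E_pr > 0):
            raise ParameterError(f"E_pr must be > 0, got {self.E_pr}")
        if not (self.sigma_Y > 0):
            raise ParameterError(f"sigma_Y must be > 0, got {self.sigma_Y}")
        if self.sigma_u < self.sigma_Y:
            raise ParameterError(
                f"sigma_u ({self.sigma_u}) must be >= sigma_Y ({self.sigma_Y})"
            )
        if not (self.p > 0):
            raise ParameterError(f"p must be > 0, got {self.p}")
        if self.E_mx < 0:
            raise ParameterError(f"E_mx must be >= 0, got {self.E_mx}")
        if self.eta < 0:
            raise ParameterError(f"eta must be >= 0, got {self.eta}")
        for name in PARAM_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        """Return the parameters as an array in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, q) -> "MaterialParams":
        q = np.asarray(q, dtype=float)
        if q.shape != (6,):
            raise ParameterError(f"expected 6 parameters, got shape {q.shape}")
        return cls(*q)

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParams":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def replace(self, **kw) -> "MaterialParams":
        return replace(self, **kw)


# Hardening law codes shared with the compiled kernels.
_HARDENING_CODES = {"voce": 0, "linear": 1, "perfect": 2}


@dataclass(frozen=True)
class ModelVariant:
    """Structural ablations of the two-layer model.

    ``hardening`` selects how the yield limit grows with equivalent plastic
    strain: ``"voce"`` (exponential saturation), ``"linear"`` (slope
    ``linear_coeff`` [MPa]) or ``"perfect"`` (constant at ``sigma_Y``).
    Disabling plasticity locks the slider (purely elastic Prandtl layer);
    disabling the Maxwell layer forces its stress to zero.
    """

    hardening: str = "voce"
    linear_coeff: float | None = None
    plasticity_enabled: bool = True
    maxwell_enabled: bool = True

    def __post_init__(self):
        if self.hardening not in _HARDENING_CODES:
            raise ParameterError(
                f"hardening must be one of {sorted(_HARDENING_CODES)}, "
                f"got {self.hardening!r}"
            )
        if self.hardening == "linear":
            if self.linear_coeff is None or self.linear_coeff < 0:
                raise ParameterError(
                    "linear hardening requires a nonnegative linear_coeff [MPa]"
                )

    @property
    def hardening_code(self) -> int:
        return _HARDENING_CODES[self.hardening]


def _check_range(name, lo, hi, positive=True):
    if positive and lo <= 0:
        raise ParameterError(f"{name} lower bound must be > 0, got {lo}")
    if not lo < hi:
        raise ParameterError(f"{name} range requires lower < upper, got ({lo}, {hi})")


@dataclass(frozen=True)
class ParamRanges:
    """Search box for the multi-start identification.

    The ultimate stress is parameterized by its offset above the yield stress,
    ``delta = sigma_u - sigma_Y``, so that ``sigma_u >= sigma_Y`` holds for
    every point of the box.  Defaults are the standard search ranges for
    wet single-trabecula tensile tests.
    """

    E_pr: tuple[float, float] = (500.0, 5000.0)
    sigma_Y: tuple[float, float] = (10.0, 100.0)
    delta_u: tuple[float, float] = (10.0, 100.0)
    p: tuple[float, float] = (10.0, 1000.0)
    E_mx: tuple[float, float] = (500.0, 5000.0)
    eta: tuple[float, float] = (2000.0, 20000.0)

    def __post_init__(self):
        for name in ("E_pr", "sigma_Y", "delta_u", "p", "E_mx", "eta"):
            lo, hi = getattr(self, name)
            _check_range(name, lo, hi)

    @property
    def internal_names(self) -> tuple[str, ...]:
        return ("E_pr", "sigma_Y", "delta_u", "p", "E_mx", "eta")

    def as_bounds(self) -> np.ndarray:
        """(6, 2) array of (lower, upper) in internal ordering."""
        return np.array([getattr(self, n) for n in self.internal_names], float)

    def contains(self, params: MaterialParams) -> bool:
        q = np.array(
            [
                params.E_pr,
                params.sigma_Y,
                params.sigma_u - params.sigma_Y,
                params.p,
                params.E_mx,
                params.eta,
            ]
        )
        b = self.as_bounds()
        return bool(np.all(q >= b[:, 0]) and np.all(q <= b[:, 1]))


@dataclass(frozen=True)
class StartGrid:
    """Cartesian grid of multi-start points.

    ``points`` has shape (n_starts, 6) in internal ordering
    (E_pr, sigma_Y, delta_u, p, E_mx, eta).
    """

    points_per_param: int
    points: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.points.shape[0]

    def start_params(self, i: int) -> MaterialParams:
        e, sy, du, p, em, et = self.points[i]
        return MaterialParams(e, sy, sy + du, p, em, et)


def build_start_grid(
    ranges: ParamRanges | None = None,
    points_per_param: int = 4,
    spacing: str = "linear",
) -> StartGrid:
    """Cartesian multi-start grid over the parameter box.

    Each of the six ranges is subdivided by ``points_per_param`` equally spaced
    points including both endpoints (geometrically spaced if
    ``spacing="log"``); the grid is their Cartesian product, hence
    ``points_per_param ** 6`` start points.  ``sigma_u`` is reconstructed per
    point as ``sigma_Y + delta_u``.
    """
    if ranges is None:
        ranges = ParamRanges()
    if points_per_param < 2:
        raise ParameterError("points_per_param must be >= 2")
    if spacing not in ("linear", "log"):
        raise ParameterError("spacing must be 'linear' or 'log'")
    axes = []
    for lo, hi in ranges.as_bounds():
        if spacing == "linear":
            axes.append(np.linspace(lo, hi, points_per_param))
        else:
            axes.append(np.geomspace(lo, hi, points_per_param))
    pts = np.array(list(itertools.product(*axes)), dtype=float)
    return StartGrid(points_per_param=points_per_param, points=pts)
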