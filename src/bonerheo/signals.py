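"""Excitation signals and simulation trajectories.

Time series are validated on construction: strictly increasing time, equal
lengths, finite values.  Non-monotone or duplicate timestamps are rejected
rather than silently sorted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SignalError

__all__ = ["StrainSignal", "DisplacementSignal", "ModelTrajectory"]


def _validate_series(t: np.ndarray, y: np.ndarray, yname: str) -> None:
    if t.ndim != 1 or y.ndim != 1:
        raise SignalError("time and value series must be one-dimensional")
    if t.shape != y.shape:
        raise SignalError(
            f"t and {yname} must have equal length, got {t.size} vs {y.size}"
        )
    if t.size < 2:
        raise SignalError("signal needs at least 2 samples")
    if not np.all(np.isfinite(t)):
        raise SignalError("non-finite value in time vector")
    if not np.all(np.isfinite(y)):
        raise SignalError(f"non-finite value in {yname}")
    if not np.all(np.diff(t) > 0):
        raise SignalError("time must be strictly increasing (no duplicates)")


@dataclass(frozen=True)
class StrainSignal:
    """Strain-controlled excitation: engineering strain ``eps`` over time ``t`` [s]."""

    t: np.ndarray
    eps: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "eps", np.asarray(self.eps, dtype=float))
        _validate_series(self.t, self.eps, "eps")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "eps": self.eps})

    @classmethod
    def from_csv(cls, path) -> "StrainSignal":
        df = pd.read_csv(path)
        for col in ("t_s", "eps"):
            if col not in df.columns:
                raise SignalError(f"{path}: missing column {col!r}")
        return cls(df["t_s"].to_numpy(), df["eps"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DisplacementSignal:
    """Displacement-controlled excitation: machine displacement ``u`` [mm] over ``t`` [s].

    ``segment_boundaries`` holds the sample indices at which a ramp/hold
    segment ends (the profile's corner points), in increasing order.
    """

    t: np.ndarray
    u: np.ndarray
    segment_boundaries: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        object.__setattr__(
            self,
            "segment_boundaries",
            np.asarray(self.segment_boundaries, dtype=int),
        )
        _validate_series(self.t, self.u, "u")
        b = self.segment_boundaries
        if b.size and (b.min() < 0 or b.max() >= self.t.size):
            raise SignalError("segment boundary index out of range")

    def __len__(self) -> int:
        return self.t.size

    @property
    def corner_times(self) -> np.ndarray:
        return self.t[self.segment_boundaries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "u_mm": self.u})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


#: Column order of the trajectory CSV export.
_TRAJ_COLUMNS = (
    "t_s",
    "eps",
    "sigma_mod_MPa",
    "sigma_pr_MPa",
    "sigma_mx_MPa",
    "eps_p",
    "eps_v",
    "alpha",
)


@dataclass(frozen=True)
class ModelTrajectory:
    """Synchronized result of a strain-driven two-layer simulation.

    Attributes
    ----------
    t, eps : arrays
        The input excitation.
    sigma_mod, sigma_pr, sigma_mx : arrays [MPa]
        Total model stress and its Prandtl/Maxwell layer contributions
        (``sigma_mod = sigma_pr + sigma_mx`` pointwise).
    eps_p, eps_v, alpha : arrays
        Plastic slider strain, viscous damper strain and equivalent plastic
        strain (``alpha`` is non-decreasing).
    """

    t: np.ndarray
    eps: np.ndarray
    sigma_mod: np.ndarray
    sigma_pr: np.ndarray
    sigma_mx: np.ndarray
    eps_p: np.ndarray
    eps_v: np.ndarray
    alpha: np.ndarray

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        data = dict(
            zip(
                _TRAJ_COLUMNS,
                (
                    self.t,
                    self.eps,
                    self.sigma_mod,
                    self.sigma_pr,
                    self.sigma_mx,
                    self.eps_p,
                    self.eps_v,
                    self.alpha,
                ),
            )
        )
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
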