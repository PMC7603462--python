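"""Cyclic tensile loading protocol: profile construction, weights, resampling.

The displacement-controlled profile has two parts, both run at a constant
machine displacement rate (default 0.01 mm/s):

* part 1 (relaxation): ramp to 0.025 mm, hold 60 s, ramp back to 0 mm,
  hold 60 s;
* part 2 (cyclic): repeatedly elongate by +0.05 mm from the previously held
  position, hold 10 s, unload by 0.025 mm, hold 10 s.

Cycle counting treats the part-1 ramp as loading cycle 1 and each part-2
repetition as one further cycle; the profile is truncated at the end of the
hold that follows the ``n_cycles``-th cycle's unloading step.  With the
defaults the held peak positions are 0.025, 0.05, 0.075 and 0.10 mm.

The identification objective is weighted only at the profile's corner points
(every ramp/hold transition); :func:`corner_weights` produces that binary
weight vector, and :func:`resample_signal` snaps corner instants into the
coarser grid so the weights survive the 1 Hz resampling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, SignalError
from .signals import DisplacementSignal, StrainSignal

__all__ = [
    "LoadingProtocol",
    "build_displacement_profile",
    "to_strain_signal",
    "corner_weights",
    "resample_signal",
    "shift_preload",
]


@dataclass(frozen=True)
class LoadingProtocol:
    """Parameters of the displacement-controlled cyclic tensile protocol."""

    rate: float = 0.01  # mm/s
    part1_peak: float = 0.025  # mm
    part1_hold: float = 60.0  # s
    part2_step: float = 0.05  # mm
    part2_unload: float = 0.025  # mm
    part2_hold: float = 10.0  # s
    n_cycles: int = 4

    def __post_init__(self):
        for name in (
            "rate",
            "part1_peak",
            "part1_hold",
            "part2_step",
            "part2_unload",
            "part2_hold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"protocol field {name} must be positive")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.part2_unload >= self.part2_step:
            raise ConfigError(
                "part2_unload must be smaller than part2_step "
                "(each cycle must produce net elongation)"
            )


def _segments(proto: LoadingProtocol) -> list[tuple[float, float]]:
    """(duration [s], end position [mm]) for each ramp/hold segment."""
    segs = []
    pos = 0.0
    # part 1 = loading cycle 1
    segs.append((proto.part1_peak / proto.rate, proto.part1_peak))
    segs.append((proto.part1_hold, proto.part1_peak))
    segs.append((proto.part1_peak / proto.rate, 0.0))
    segs.append((proto.part1_hold, 0.0))
    pos = 0.0
    for _ in range(proto.n_cycles - 1):
        pos += proto.part2_step
        segs.append((proto.part2_step / proto.rate, pos))
        segs.append((proto.part2_hold, pos))
        pos -= proto.part2_unload
        segs.append((proto.part2_unload / proto.rate, pos))
        segs.append((proto.part2_hold, pos))
    return segs


def build_displacement_profile(
    proto: LoadingProtocol = LoadingProtocol(), sample_rate: float = 10.0
) -> DisplacementSignal:
    """Sample the piecewise-linear displacement profile at ``sample_rate`` [Hz].

    Segment-end instants are always included exactly; their sample indices are
    recorded as ``segment_boundaries`` (the profile's corner points).
    """
    if sample_rate <= 0:
        raise ConfigError("sample_rate must be positive")
    dt = 1.0 / sample_rate
    times = [0.0]
    values = [0.0]
    boundaries = []
    t0, u0 = 0.0, 0.0
    for duration, u1 in _segments(proto):
        t1 = t0 + duration
        n_interior = int(np.floor(duration / dt - 1e-9))
        for k in range(1, n_interior + 1):
            tk = t0 + k * dt
            if tk >= t1 - 1e-12:
                break
            times.append(tk)
            values.append(u0 + (u1 - u0) * (tk - t0) / duration)
        times.append(t1)
        values.append(u1)
        boundaries.append(len(times) - 1)
        t0, u0 = t1, u1
    return DisplacementSignal(
        t=np.array(times), u=np.array(values), segment_boundaries=np.array(boundaries)
    )


def to_strain_signal(disp: DisplacementSignal, gauge_factor: float) -> StrainSignal:
    """Map machine displacement [mm] to gauge strain via ``eps = u * gauge_factor``.

    ``gauge_factor`` [1/mm] lumps the specimen-specific relation between
    machine displacement and the strain of the optically tracked gauge length;
    it sets the realized strain rate of the first ramp.
    """
    if gauge_factor <= 0:
        raise ConfigError("gauge_factor must be positive")
    return StrainSignal(t=disp.t, eps=disp.u * gauge_factor)


def corner_weights(disp: DisplacementSignal) -> np.ndarray:
    """Binary weight vector: 1.0 at each ramp/hold corner sample, 0.0 elsewhere.

    The sample at t = 0 is never weighted.  Raises if the signal records no
    segment boundaries (an all-hold signal has no corners).
    """
    if disp.segment_boundaries.size == 0:
        raise SignalError("signal has no corner points to weight")
    w = np.zeros(len(disp))
    w[disp.segment_boundaries] = 1.0
    w[0] = 0.0
    if not np.any(w > 0):
        raise SignalError("signal has no corner points to weight")
    return w


def _resample_arrays(t, y, target_rate, preserve_times):
    dt_med = float(np.median(np.diff(t)))
    if target_rate >= 1.0 / dt_med - 1e-9:
        raise SignalError(
            f"resampling target rate {target_rate} Hz does not downsample the "
            f"signal (original ~{1.0 / dt_med:.3g} Hz)"
        )
    step = 1.0 / target_rate
    n = int(np.floor((t[-1] - t[0]) / step + 1e-9)) + 1
    grid = t[0] + step * np.arange(n)
    if t[-1] - grid[-1] > 1e-9:
        grid = np.append(grid, t[-1])
    else:
        grid[-1] = t[-1]
    for tc in preserve_times:
        idx = int(np.argmin(np.abs(grid - tc)))
        grid[idx] = tc
    grid = np.unique(grid)
    return grid, np.interp(grid, t, y)


def resample_signal(signal, target_rate: float):
    """Linearly resample a signal onto a uniform grid at ``target_rate`` [Hz].

    Only downsampling is allowed.  Endpoints are preserved; for displacement
    signals every corner instant is snapped into the new grid (replacing the
    nearest grid point) so corner values survive exactly and the segment
    boundaries are re-identified on the resampled signal.
    """
    if isinstance(signal, DisplacementSignal):
        corner_times = signal.corner_times
        grid, y = _resample_arrays(signal.t, signal.u, target_rate, corner_times)
        boundaries = np.searchsorted(grid, corner_times)
        return DisplacementSignal(t=grid, u=y, segment_boundaries=boundaries)
    if isinstance(signal, StrainSignal):
        grid, y = _resample_arrays(signal.t, signal.eps, target_rate, ())
        return StrainSignal(t=grid, eps=y)
    raise TypeError(f"cannot resample object of type {type(signal).__name__}")


def shift_preload(force: np.ndarray, disp: np.ndarray, A_mean: float):
    """Convert force [N] to stress [MPa], zero both series at t = 0.

    Engineering stress is ``sigma = F / A_mean`` with ``A_mean`` [mm^2] the
    representative cross-section.  Both stress and displacement are offset so
    their first sample is zero (removing the preload step that would otherwise
    excite an unrealistic initial viscous response); the removed stress offset
    is returned as the specimen's prestress [MPa].

    Returns
    -------
    (stress, disp_shifted, prestress)
    """
    if A_mean <= 0:
        raise ConfigError("A_mean must be positive")
    force = np.asarray(force, dtype=float)
    disp = np.asarray(disp, dtype=float)
    stress = force / A_mean
    prestress = float(stress[0])
    return stress - prestress, disp - disp[0], prestress
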