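"""Inspiratory drive waveforms and tidal-volume calibration.

Four clinically standard inspiratory drive profiles are supported:

* CF — constant flow ``Q_aw`` for the whole inspiration;
* DF — decelerating (triangular) flow, ``Q_max * (1 - t/t_i)``, reaching
  exactly zero at end-inspiration;
* SF — half-sinusoidal flow, ``Q_max * sin(pi * t / t_i)``, zero at both
  onset and end of inspiration;
* CP — constant set pressure ``P_set`` at the airway opening (ideal pressure
  source, no rise-time ramp); the flow profile then emerges from the
  resistive network.

A drive can also be specified by a target tidal volume: the flow-profile
amplitudes invert in closed form, while the CP set pressure is found by a
bracketing root search against the periodic-steady-state inspired volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import optimize

from .network import LungNetwork, VentilatorSettings, validate_settings

__all__ = [
    "AirwayDrive",
    "make_drive",
    "vt_of_drive",
    "calibrate_drive_to_vt",
    "ConfigurationError",
    "CalibrationError",
]


class ConfigurationError(ValueError):
    """Invalid or inconsistent drive/settings configuration."""


class CalibrationError(RuntimeError):
    """Target tidal volume unreachable within the search bracket."""


@dataclass(frozen=True)
class AirwayDrive:
    """Airway-opening boundary condition over one inspiration.

    ``kind`` is ``"flow_controlled"`` or ``"pressure_controlled"``.
    ``shape`` is one of ``constant`` / ``triangle`` / ``halfsine`` and
    ``amplitude`` its peak value (l/s for flow, cmH2O for pressure); the
    solver exploits the shape for exact time propagation.
    """

    kind: str
    shape: str
    amplitude: float
    t_i: float

    def __call__(self, t):
        """Evaluate the waveform (Q_aw in l/s, or P_aw in cmH2O) at time t in [0, t_i]."""
        t = np.asarray(t, dtype=float)
        if self.shape == "constant":
            return np.broadcast_to(np.float64(self.amplitude), t.shape).copy() if t.ndim else float(self.amplitude)
        if self.shape == "triangle":
            return self.amplitude * (1.0 - t / self.t_i)
        if self.shape == "halfsine":
            return self.amplitude * np.sin(np.pi * t / self.t_i)
        raise ConfigurationError(f"unknown waveform shape {self.shape!r}")


def make_drive(settings: VentilatorSettings) -> AirwayDrive:
    """Build the airway drive for concrete (already calibrated) settings."""
    problems = validate_settings(settings)
    if problems:
        raise ConfigurationError("; ".join(problems))
    key, val = settings.amplitude()
    if key == "target_vt":
        raise ConfigurationError(
            "settings specify target_vt; calibrate with calibrate_drive_to_vt first"
        )
    mode = settings.mode
    if mode == "CF":
        return AirwayDrive("flow_controlled", "constant", val, settings.t_i)
    if mode == "DF":
        return AirwayDrive("flow_controlled", "triangle", val, settings.t_i)
    if mode == "SF":
        return AirwayDrive("flow_controlled", "halfsine", val, settings.t_i)
    if mode == "CP":
        return AirwayDrive("pressure_controlled", "constant", val, settings.t_i)
    raise ConfigurationError(f"unknown mode {mode!r}")


def vt_of_drive(drive: AirwayDrive) -> float:
    """Inspired volume at the airway opening, ∫ Q_aw dt over inspiration (l).

    Closed forms: constant Q*t_i; triangle Q_max*t_i/2; half-sine
    2*Q_max*t_i/pi.  Pressure-controlled drives have no prescribed flow —
    their tidal volume emerges from the circuit — and are rejected.
    """
    if drive.kind != "flow_controlled":
        raise ConfigurationError("tidal volume of a pressure-controlled drive emerges from the circuit")
    if drive.shape == "constant":
        return drive.amplitude * drive.t_i
    if drive.shape == "triangle":
        return drive.amplitude * drive.t_i / 2.0
    if drive.shape == "halfsine":
        return 2.0 * drive.amplitude * drive.t_i / math.pi
    raise ConfigurationError(f"unknown waveform shape {drive.shape!r}")


def _flow_amplitude_for_vt(mode: str, target_vt: float, t_i: float) -> float:
    if mode == "CF":
        return target_vt / t_i
    if mode == "DF":
        return 2.0 * target_vt / t_i
    if mode == "SF":
        return math.pi * target_vt / (2.0 * t_i)
    raise ConfigurationError(f"mode {mode!r} has no closed-form flow amplitude")


def calibrate_drive_to_vt(
    net: LungNetwork,
    settings: VentilatorSettings,
    vt_tol: float = 1e-4,
) -> VentilatorSettings:
    """Resolve ``target_vt`` into a concrete drive amplitude.

    Flow-controlled modes invert their closed-form tidal volumes exactly.
    For CP the set pressure is found by Brent root search on the periodic
    steady state: the inspired airway volume is monotone (in fact affine)
    in P_set, so a bracket above PEEP always exists for reachable targets.
    """
    key, target = settings.amplitude()
    if key != "target_vt":
        return settings  # already concrete
    if not target > 0:
        raise ConfigurationError(f"target_vt must be > 0 (got {target})")
    base = replace(settings, target_vt=None)
    if settings.mode in ("CF", "DF", "SF"):
        amp = _flow_amplitude_for_vt(settings.mode, target, settings.t_i)
        k = "q_aw" if settings.mode == "CF" else "q_max"
        return replace(base, **{k: amp})

    # CP: root-search P_set against steady-state inspired volume
    from .solver import find_periodic_steady_state  # deferred: avoids import cycle

    def vt_err(p_set: float) -> float:
        s = replace(base, p_set=p_set)
        traj = find_periodic_steady_state(net, s)
        return traj.v_t - target

    lo = settings.peep + 1e-6
    hi = settings.peep + 5.0
    f_lo = vt_err(lo)
    f_hi = vt_err(hi)
    # expand the bracket geometrically, capped at ~1000 cmH2O above PEEP —
    # far outside any physical ventilator setting
    while f_hi < 0 and hi - settings.peep < 1000.0:
        lo, f_lo = hi, f_hi
        hi = settings.peep + 2.0 * (hi - settings.peep)
        f_hi = vt_err(hi)
    if f_lo > 0 or f_hi < 0:
        raise CalibrationError(
            f"target V_T={target} l unreachable for CP: achieved range "
            f"[{f_lo + target:.4g}, {f_hi + target:.4g}] l over P_set in [{lo:.3g}, {hi:.3g}] cmH2O"
        )
    p_set = optimize.brentq(vt_err, lo, hi, xtol=1e-10, rtol=8.9e-16)
    achieved = vt_err(p_set) + target
    if abs(achieved - target) > vt_tol:
        raise CalibrationError(
            f"CP calibration converged to V_T={achieved:.6f} l, outside tolerance {vt_tol} of target {target}"
        )
    return replace(base, p_set=float(p_set))
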