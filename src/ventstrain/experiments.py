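"""Scripted in-silico experiments: mode comparisons and parameter sweeps.

Each experiment is a pure function of (network, settings, grid) returning a
:class:`SweepResult` whose tidy table can be exported bit-identically —
there is no randomness anywhere in the pipeline.

Sweep conventions (documented design choices):

* In the PEEP sweep each mode keeps its *set* control fixed while PEEP
  varies — flow-controlled modes keep their amplitude (hence tidal volume),
  pressure control keeps P_set (so its tidal volume shrinks as PEEP rises) —
  mirroring how each mode is dialled at the bedside.
* In the tidal-volume x peak-flow grid the inspiratory time follows from the
  waveform geometry (CF: t_i = V_T/Q_aw; DF: 2 V_T/Q_max; SF: pi V_T/(2 Q_max));
  cells with t_i >= t_tot are marked infeasible and skipped, and cells where
  auto-PEEP exceeds set PEEP by more than 0.1 cmH2O are flagged.
* Rest volume enters only the strain formulas, never the circuit, so the
  rest-volume sweeps reuse one steady-state solve per mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .drive import calibrate_drive_to_vt, make_drive, vt_of_drive
from .energetics import EnergeticsTrace, compute_energetics, strain_from_volume
from .network import MODES, LungNetwork, Scenario, VentilatorSettings, scenario_hash
from .solver import CycleTrajectory, find_periodic_steady_state

__all__ = [
    "SweepResult",
    "mode_comparison",
    "peep_sweep",
    "vt_qmax_grid",
    "vrest_sweep",
    "heterogeneous_vrest",
    "resolve_modes_at_matched_vt",
    "DEFAULT_PEEP_GRID",
    "DEFAULT_VREST_GRID",
    "HETEROGENEOUS_VREST_PRESET",
]

DEFAULT_PEEP_GRID = np.round(np.arange(0.0, 12.75 + 1e-9, 0.25), 10)
DEFAULT_VREST_GRID = np.round(np.arange(0.2, 1.2 + 1e-9, 0.05), 10)

#: Rest-volume assignment pairing small rest volumes with high-compliance
#: compartments, chosen (and verified in the tests) so that under baseline
#: constant-flow ventilation compartment A develops the highest maximal
#: strain and compartment D the lowest.
HETEROGENEOUS_VREST_PRESET: dict[str, float] = {
    "A": 0.4,
    "B": 0.8,
    "C": 0.9,
    "D": 1.2,
    "E": 1.0,
}


@dataclass
class SweepResult:
    """Tidy long-format result of one sweep experiment."""

    name: str  # swept variable
    grid: np.ndarray
    table: pd.DataFrame  # one row per (grid point, mode, compartment)
    scenario: str  # provenance hash of the base scenario

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _matched_target_vt(net: LungNetwork, settings: VentilatorSettings) -> float:
    """Tidal volume all modes are matched to in a comparison."""
    key, val = settings.amplitude()
    if key == "target_vt":
        return val
    if settings.mode in ("CF", "DF", "SF"):
        return vt_of_drive(make_drive(settings))
    # CP: its steady-state inspired volume defines the match
    return find_periodic_steady_state(net, settings).v_t


def resolve_modes_at_matched_vt(
    net: LungNetwork,
    settings: VentilatorSettings,
    modes: Sequence[str] = MODES,
) -> dict[str, VentilatorSettings]:
    """Concrete per-mode settings sharing the same tidal volume and timing."""
    target = _matched_target_vt(net, settings)
    out = {}
    for mode in modes:
        s = VentilatorSettings(
            mode=mode,
            peep=settings.peep,
            t_i=settings.t_i,
            t_tot=settings.t_tot,
            target_vt=target,
        )
        out[mode] = calibrate_drive_to_vt(net, s)
    return out


def mode_comparison(
    net: LungNetwork,
    settings: VentilatorSettings,
    modes: Sequence[str] = MODES,
    dt: float = 1e-3,
) -> dict[str, tuple[CycleTrajectory, EnergeticsTrace]]:
    """Run all requested modes at matched tidal volume and inspiratory time."""
    resolved = resolve_modes_at_matched_vt(net, settings, modes)
    out = {}
    for mode, s in resolved.items():
        traj = find_periodic_steady_state(net, s, dt=dt)
        out[mode] = (traj, compute_energetics(traj))
    return out


def _records_for(
    traj: CycleTrajectory, trace: EnergeticsTrace, base: dict
) -> list[dict]:
    rows = []
    for lab in traj.labels:
        rows.append(
            {
                **base,
                "compartment": lab,
                "S_max": trace.s_max[lab],
                "max_strain_rate": trace.max_strain_rate[lab],
                "P_ex": traj.p_ex[lab],
                "V_T_comp": traj.vt_comp[lab],
                "V_peak": traj.v_peak[lab],
                "V_T": traj.v_t,
            }
        )
    return rows


def peep_sweep(
    net: LungNetwork,
    settings: VentilatorSettings,
    peep_grid: np.ndarray | None = None,
    modes: Sequence[str] = MODES,
    dt: float = 1e-3,
) -> SweepResult:
    """Maximal strain per compartment across a PEEP range, per mode.

    Amplitudes are resolved once at the base settings (matched V_T at the
    base PEEP) and then held fixed: flow modes keep their waveform amplitude,
    CP keeps its set pressure.
    """
    grid = DEFAULT_PEEP_GRID if peep_grid is None else np.asarray(peep_grid, float)
    resolved = resolve_modes_at_matched_vt(net, settings, modes)
    rows: list[dict] = []
    for peep in grid:
        for mode in modes:
            s = replace(resolved[mode], peep=float(peep))
            traj = find_periodic_steady_state(net, s, dt=dt)
            trace = compute_energetics(traj)
            rows.extend(_records_for(traj, trace, {"mode": mode, "peep": float(peep)}))
    return SweepResult("peep", grid, pd.DataFrame(rows), scenario_hash(Scenario(net, settings)))


def vt_qmax_grid(
    net: LungNetwork,
    settings: VentilatorSettings,
    vt_grid: np.ndarray,
    qmax_grid: np.ndarray,
    modes: Sequence[str] = ("DF", "SF"),
    autopeep_threshold: float = 0.1,
    dt: float = 1e-3,
) -> SweepResult:
    """Maximal strain over a tidal-volume x peak-flow grid.

    The inspiratory time is implied by the waveform: raising V_T at fixed
    peak flow lengthens inspiration, shortens expiration and builds
    auto-PEEP.  Cells with t_i >= t_tot are recorded as infeasible (NaN
    outputs); cells whose auto-PEEP exceeds ``autopeep_threshold`` above set
    PEEP carry ``autopeep_flag = True``.
    """
    vt_grid = np.asarray(vt_grid, float)
    qmax_grid = np.asarray(qmax_grid, float)
    t_i_of = {
        "CF": lambda vt, q: vt / q,
        "DF": lambda vt, q: 2.0 * vt / q,
        "SF": lambda vt, q: np.pi * vt / (2.0 * q),
    }
    rows: list[dict] = []
    for mode in modes:
        if mode not in t_i_of:
            raise ValueError(f"vt_qmax_grid supports flow-controlled modes only, got {mode!r}")
        for vt in vt_grid:
            for qmax in qmax_grid:
                t_i = t_i_of[mode](vt, qmax)
                base = {"mode": mode, "v_t_set": float(vt), "q_max": float(qmax), "t_i": float(t_i)}
                if not t_i < settings.t_tot:
                    for lab in net.labels:
                        rows.append(
                            {
                                **base,
                                "compartment": lab,
                                "feasible": False,
                                "S_max": np.nan,
                                "max_strain_rate": np.nan,
                                "P_ex": np.nan,
                                "V_T_comp": np.nan,
                                "V_T": np.nan,
                                "autopeep_flag": False,
                            }
                        )
                    continue
                amp = {"q_aw" if mode == "CF" else "q_max": float(qmax)}
                s = VentilatorSettings(
                    mode=mode, peep=settings.peep, t_i=float(t_i), t_tot=settings.t_tot, **amp
                )
                traj = find_periodic_steady_state(net, s, dt=dt)
                trace = compute_energetics(traj)
                for lab in net.labels:
                    rows.append(
                        {
                            **base,
                            "compartment": lab,
                            "feasible": True,
                            "S_max": trace.s_max[lab],
                            "max_strain_rate": trace.max_strain_rate[lab],
                            "P_ex": traj.p_ex[lab],
                            "V_T_comp": traj.vt_comp[lab],
                            "V_T": traj.v_t,
                            "autopeep_flag": bool(
                                traj.p_ex[lab] - settings.peep > autopeep_threshold
                            ),
                        }
                    )
    return SweepResult("v_t_set", vt_grid, pd.DataFrame(rows), scenario_hash(Scenario(net, settings)))


def _smax_for_vrest(traj: CycleTrajectory, vrest: Mapping[str, float] | float) -> dict[str, float]:
    """Maximal strain re-evaluated for alternative rest volumes.

    Rest volume never enters the circuit, so the peak of (V + C*P_ex) from a
    single steady-state solve serves every rest-volume assignment.
    """
    out = {}
    for j, lab in enumerate(traj.labels):
        comp = traj.net.compartments[lab]
        vr = vrest if isinstance(vrest, (int, float)) else vrest[lab]
        full = strain_from_volume(traj.V[:, j], comp.C, traj.p_ex[lab], vr)
        out[lab] = float(np.max(full))
    return out


def vrest_sweep(
    net: LungNetwork,
    settings: VentilatorSettings,
    vrest_grid: np.ndarray | None = None,
    modes: Sequence[str] = ("CF", "CP"),
    dt: float = 1e-3,
) -> SweepResult:
    """Maximal strain versus a uniform compartmental rest volume."""
    grid = DEFAULT_VREST_GRID if vrest_grid is None else np.asarray(vrest_grid, float)
    resolved = resolve_modes_at_matched_vt(net, settings, modes)
    rows: list[dict] = []
    for mode in modes:
        traj = find_periodic_steady_state(net, resolved[mode], dt=dt)
        trace = compute_energetics(traj)
        for vr in grid:
            smax = _smax_for_vrest(traj, float(vr))
            for lab in net.labels:
                # strain rate is Q/V_rest: rescale the stored maximum exactly
                base_vr = net.compartments[lab].V_rest
                rows.append(
                    {
                        "mode": mode,
                        "v_rest": float(vr),
                        "compartment": lab,
                        "S_max": smax[lab],
                        "max_strain_rate": trace.max_strain_rate[lab] * base_vr / float(vr),
                        "P_ex": traj.p_ex[lab],
                        "V_T_comp": traj.vt_comp[lab],
                        "V_T": traj.v_t,
                    }
                )
    return SweepResult("v_rest", grid, pd.DataFrame(rows), scenario_hash(Scenario(net, settings)))


def heterogeneous_vrest(
    net: LungNetwork,
    settings: VentilatorSettings,
    vrest_map: Mapping[str, float] | None = None,
    dt: float = 1e-3,
) -> dict[str, float]:
    """Maximal strain per compartment under per-compartment rest volumes.

    Defaults to constant-flow ventilation with
    :data:`HETEROGENEOUS_VREST_PRESET`.
    """
    vrest_map = dict(HETEROGENEOUS_VREST_PRESET if vrest_map is None else vrest_map)
    for lab, vr in vrest_map.items():
        if not vr > 0:
            raise ValueError(f"rest volume for {lab} must be > 0 (got {vr})")
    net2 = net.with_rest_volumes(vrest_map)
    traj = find_periodic_steady_state(net2, settings, dt=dt)
    return _smax_for_vrest(traj, vrest_map)
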