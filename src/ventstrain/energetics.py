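"""Intracycle elastic power, cumulative energy, strain and strain rate.

For each compartment the *total elastic* intracycle power is

    ICP_elastic(t) = Q(t) * (V(t)/C + P_ex),   0 <= t <= t_i,

with ``Q`` the instantaneous inflow, ``V`` the volume above the
end-expiratory residual, ``C`` the compliance and ``P_ex`` the residual
end-expiratory pressure (set PEEP + auto-PEEP).  Its running integral
``A(t)`` is the elastic energy delivered so far, which drives the strain
analog of a uniformly inflating sphere of rest volume ``V_rest``:

    strain(t)  = 1 + sqrt(2*C*A(t) + C^2*P_ex^2) / V_rest
               = 1 + (V(t) + C*P_ex) / V_rest            (identical forms)

Two strain-rate variants are computed side by side.  The quotient form
``ICP / (V_rest * sqrt(2CA + C^2 P_ex^2))`` evaluates to ``Q/(C*V_rest)``,
whereas differentiating the volume-form strain gives ``Q/V_rest``; the two
differ by the constant factor ``C``.  The dimensionally consistent
derivative ``Q/V_rest`` is the default reported strain rate; the quotient
form is preserved unchanged for comparison (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, cumulative_trapezoid

from .solver import CycleTrajectory

__all__ = [
    "icp_elastic",
    "icp_driving",
    "icp_total",
    "cumulative_energy",
    "strain_from_energy",
    "strain_from_volume",
    "strain_rate_printed",
    "strain_rate_consistent",
    "compute_energetics",
    "max_strain",
    "EnergeticsTrace",
    "EnergeticsError",
]


class EnergeticsError(ValueError):
    """Inconsistent energetics inputs (e.g. negative radicand)."""


def icp_elastic(Q, V, C, P_ex):
    """Total elastic intracycle power Q*(V/C + P_ex), cmH2O*l/s."""
    if not C > 0:
        raise EnergeticsError(f"compliance must be > 0 (got {C})")
    return np.asarray(Q) * (np.asarray(V) / C + P_ex)


def icp_driving(Q, V, C):
    """Driving power Q*V/C — the PEEP-free incremental-elastic component."""
    return np.asarray(Q) * np.asarray(V) / C


def icp_total(Q, V, C, P_ex, R_path):
    """Resistive-inclusive power Q*(V/C + P_ex + R_path*Q).

    ``R_path`` is the series resistance from the airway opening to the
    compartment along the tree.
    """
    Q = np.asarray(Q)
    return Q * (np.asarray(V) / C + P_ex + R_path * Q)


def cumulative_energy(icp, t, method: str = "simpson"):
    """Cumulative elastic energy A(t) = ∫0..t ICP ds on a uniform grid, cmH2O*l.

    Composite-Simpson cumulative integral by default (A(0) = 0); the power
    trace right after a constant-pressure step decays fast enough that the
    O(h^2) trapezoid bias is visible against the exact energy-volume
    identity on a 1 ms grid, while Simpson's O(h^4) error is not.  Pass
    ``method="trapezoid"`` for the plain trapezoidal rule.
    """
    icp = np.asarray(icp)
    t = np.asarray(t)
    if method == "simpson":
        return cumulative_simpson(icp, x=t, initial=0.0)
    if method == "trapezoid":
        return cumulative_trapezoid(icp, t, initial=0.0)
    raise ValueError(f"unknown method {method!r}")


def strain_from_energy(A, C, P_ex, V_rest):
    """Strain from delivered elastic energy: 1 + sqrt(2CA + C^2 P_ex^2)/V_rest."""
    rad = 2.0 * C * np.asarray(A) + (C * P_ex) ** 2
    if np.any(rad < 0):
        raise EnergeticsError("negative radicand 2CA + C^2 P_ex^2: inconsistent inputs")
    return 1.0 + np.sqrt(rad) / V_rest


def strain_from_volume(V, C, P_ex, V_rest):
    """Volume-form strain: 1 + (V + C*P_ex)/V_rest."""
    return 1.0 + (np.asarray(V) + C * P_ex) / V_rest


def strain_rate_printed(icp, A, C, P_ex, V_rest):
    """Quotient-form strain rate ICP/(V_rest*sqrt(2CA + C^2 P_ex^2)), 1/s.

    Kept exactly in this form; along a trajectory it equals ``Q/(C*V_rest)``,
    a factor ``1/C`` above the derivative of the volume-form strain.  Raises
    at a zero radicand (t = 0 with P_ex = 0), where the quotient is singular
    and no limit is reported.
    """
    rad = 2.0 * C * np.asarray(A) + (C * P_ex) ** 2
    if np.any(rad <= 0):
        raise EnergeticsError(
            "zero/negative radicand: quotient-form strain rate singular (limit unavailable)"
        )
    return np.asarray(icp) / (V_rest * np.sqrt(rad))


def strain_rate_consistent(Q, V_rest):
    """Time derivative of the volume-form strain: Q/V_rest, 1/s (default)."""
    if not V_rest > 0:
        raise EnergeticsError(f"V_rest must be > 0 (got {V_rest})")
    return np.asarray(Q) / V_rest


@dataclass
class EnergeticsTrace:
    """Per-compartment energetics of one steady-state breath.

    Arrays are sampled on the inspiration grid ``t``; scalars ``S_max`` are
    maxima of the volume-form strain over the *whole* cycle (the volume peak
    normally falls at end-inspiration, but pendelluft can shift it).
    """

    labels: tuple[str, ...]
    t: np.ndarray  # inspiration grid, s
    icp: np.ndarray  # (nt, nc) elastic intracycle power, cmH2O*l/s
    A: np.ndarray  # (nt, nc) cumulative elastic energy, cmH2O*l
    strain: np.ndarray  # (nt, nc), unitless
    strain_rate: np.ndarray  # (nt, nc) default Q/V_rest, 1/s
    strain_rate_printed: np.ndarray | None  # quotient form, None if singular
    s_max: dict[str, float]
    t_peak: dict[str, float]  # time of the strain maximum within the cycle, s
    a_end_insp: dict[str, float]  # A(t_i), cmH2O*l
    max_strain_rate: dict[str, float]  # max of the default strain rate, 1/s

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t": self.t}
        for j, lab in enumerate(self.labels):
            cols[f"ICP_{lab}"] = self.icp[:, j]
            cols[f"A_{lab}"] = self.A[:, j]
            cols[f"strain_{lab}"] = self.strain[:, j]
            cols[f"strainrate_{lab}"] = self.strain_rate[:, j]
            if self.strain_rate_printed is not None:
                cols[f"strainrate_printed_{lab}"] = self.strain_rate_printed[:, j]
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        return {
            "S_max": dict(self.s_max),
            "A_end_insp": dict(self.a_end_insp),
            "max_strain_rate": dict(self.max_strain_rate),
            "t_peak": dict(self.t_peak),
        }


def compute_energetics(traj: CycleTrajectory) -> EnergeticsTrace:
    """Derive the full energetics trace from a steady-state cycle."""
    labels = traj.labels
    net = traj.net
    t = traj.t_insp
    Vi = traj.inspiration(traj.V)
    Qi = traj.inspiration(traj.Q)

    nc = len(labels)
    icp = np.empty_like(Vi)
    A = np.empty_like(Vi)
    strain_i = np.empty_like(Vi)
    rate = np.empty_like(Vi)
    printed = np.empty_like(Vi)
    printed_ok = True
    s_max: dict[str, float] = {}
    t_peak: dict[str, float] = {}
    a_end: dict[str, float] = {}
    max_rate: dict[str, float] = {}

    for j, lab in enumerate(labels):
        comp = net.compartments[lab]
        p_ex = traj.p_ex[lab]
        icp[:, j] = icp_elastic(Qi[:, j], Vi[:, j], comp.C, p_ex)
        A[:, j] = cumulative_energy(icp[:, j], t)
        strain_i[:, j] = strain_from_volume(Vi[:, j], comp.C, p_ex, comp.V_rest)
        rate[:, j] = strain_rate_consistent(Qi[:, j], comp.V_rest)
        try:
            printed[:, j] = strain_rate_printed(icp[:, j], A[:, j], comp.C, p_ex, comp.V_rest)
        except EnergeticsError:
            printed_ok = False
        # strain maximum over the whole cycle (volume form is valid throughout)
        full_strain = strain_from_volume(traj.V[:, j], comp.C, p_ex, comp.V_rest)
        k = int(np.argmax(full_strain))
        s_max[lab] = float(full_strain[k])
        t_peak[lab] = float(traj.t[k])
        a_end[lab] = float(A[-1, j])
        max_rate[lab] = float(np.max(rate[:, j]))

    return EnergeticsTrace(
        labels=labels,
        t=t,
        icp=icp,
        A=A,
        strain=strain_i,
        strain_rate=rate,
        strain_rate_printed=printed if printed_ok else None,
        s_max=s_max,
        t_peak=t_peak,
        a_end_insp=a_end,
        max_strain_rate=max_rate,
    )


def max_strain(traj: CycleTrajectory) -> dict[str, float]:
    """Per-compartment maximal strain over the cycle (volume-form)."""
    return compute_energetics(traj).s_max
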