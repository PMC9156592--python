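"""Linear circuit solver: nodal analysis, phase propagation, periodic steady state.

The airway tree is the direct electrical analog of a resistive network
feeding capacitors: pressure plays voltage, flow plays current, each
compartment is a capacitor of capacitance ``C`` whose charge is the absolute
elastic volume ``v`` (so alveolar pressure is ``v/C``).  Kirchhoff flow
balances at the internal nodes reduce the dynamics to a linear
time-invariant system

    dv/dt = A v + b u(t)

where ``u`` is the airway-opening boundary value (prescribed flow for
CF/DF/SF, prescribed pressure for CP and for passive expiration against the
PEEP valve).  Within a phase the forcing is constant, affine in ``t``
(decelerating flow) or sinusoidal, so the state can be propagated *exactly*
with the matrix exponential of a small augmented generator — no
time-stepping error, and phase end states independent of the output grid.

The breath-to-breath map is therefore affine, ``v_end = M v_0 + c``; the
periodic (cycled) steady state, including auto-PEEP, is its unique fixed
point, solved directly and confirmed by one verification cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .drive import AirwayDrive, calibrate_drive_to_vt, make_drive
from .network import LungNetwork, VentilatorSettings, validate_network, validate_settings

__all__ = [
    "NodalMaps",
    "build_nodal_maps",
    "instantaneous_solve",
    "simulate_phase",
    "find_periodic_steady_state",
    "CycleTrajectory",
    "SolverError",
    "SimulationError",
    "SteadyStateError",
]


class SolverError(RuntimeError):
    """Singular or ill-posed circuit system."""


class SimulationError(RuntimeError):
    """Model violated during integration (e.g. negative absolute volume)."""


class SteadyStateError(RuntimeError):
    """Cycle map not contracting or fixed point not confirmed."""


# ---------------------------------------------------------------------------
# nodal analysis


@dataclass(frozen=True)
class NodalMaps:
    """Precomputed linear maps for one boundary kind on a fixed network.

    All circuit quantities are affine in the compartment volumes ``v`` and
    the boundary value ``u``:

    * compartment inflows     Q  = ``Fv @ v + fu * u``  (== dv/dt)
    * internal node pressures p  = ``Pv @ v + pu * u``
    * airway-opening pressure P_ao = ``av @ v + au * u``
    * airway-opening flow     Q_ao = ``qv @ v + qu * u``
    """

    kind: str  # "flow" or "pressure"
    labels: tuple[str, ...]
    nodes: tuple[str, ...]
    Fv: np.ndarray
    fu: np.ndarray
    Pv: np.ndarray
    pu: np.ndarray
    av: np.ndarray
    au: float
    qv: np.ndarray
    qu: float


def build_nodal_maps(net: LungNetwork, kind: str) -> NodalMaps:
    """Assemble and pre-solve the Kirchhoff system for one boundary kind.

    ``kind="pressure"``: the airway-opening pressure is prescribed; unknowns
    are the internal node pressures.  ``kind="flow"``: the total flow through
    the root resistance is prescribed and the airway-opening pressure is an
    extra unknown closed by the flow constraint.
    """
    if kind not in ("flow", "pressure"):
        raise ValueError(f"kind must be 'flow' or 'pressure', got {kind!r}")
    labels = net.labels
    nodes = tuple(net.topology)
    n_n, n_c = len(nodes), len(labels)
    nidx = {n: i for i, n in enumerate(nodes)}
    cidx = {l: i for i, l in enumerate(labels)}
    root = net.root()
    r_root = net.shared_resistances[net.topology[root][0]]

    nx = n_n + (1 if kind == "flow" else 0)
    # equations are written K x + Lv v + mu u = 0, so x = -Kinv (Lv v + mu u)
    K = np.zeros((nx, nx))
    Lv = np.zeros((nx, n_c))  # LHS coefficients of the known leaf pressures v/C
    mu = np.zeros(nx)  # LHS coefficients of the boundary value u
    iao = n_n  # index of P_ao when unknown

    # per-node flow balance: sum over incident edges of (P_other - P_n)/R = 0
    for parent, child, R in net.edges():
        g = 1.0 / R
        if child in nidx:  # node-node or AO-node edge
            i = nidx[child]
            K[i, i] -= g
            if parent == "AO":
                if kind == "pressure":
                    mu[i] += g  # known P_ao = u
                else:
                    K[i, iao] += g
            else:
                K[i, nidx[parent]] += g
            # reciprocal contribution at the parent's balance (if internal)
            if parent != "AO":
                j = nidx[parent]
                K[j, j] -= g
                K[j, i] += g
        else:  # leaf edge: child pressure is v/C (known)
            j = cidx[child]
            i = nidx[parent]
            K[i, i] -= g
            Lv[i, j] += g / net.compartments[child].C

    if kind == "flow":
        # balance at the airway opening: (P_root - P_ao)/R_root + u = 0
        K[iao, iao] -= 1.0 / r_root
        K[iao, nidx[root]] += 1.0 / r_root
        mu[iao] = 1.0

    try:
        Kinv = np.linalg.inv(K)
    except np.linalg.LinAlgError as e:  # pragma: no cover - valid nets are solvable
        raise SolverError(f"singular circuit system for topology {list(net.topology)}: {e}")

    Xv = Kinv @ (-Lv)
    Xu = Kinv @ (-mu)

    # compartment inflow: Q_j = (P_parent - v_j/C_j)/R_j
    parent_of = {c: n for n, (_, kids) in net.topology.items() for c in kids}
    Fv = np.zeros((n_c, n_c))
    fu = np.zeros(n_c)
    for lab in labels:
        j = cidx[lab]
        comp = net.compartments[lab]
        i = nidx[parent_of[lab]]
        Fv[j, :] = Xv[i, :] / comp.R
        Fv[j, j] -= 1.0 / (comp.C * comp.R)
        fu[j] = Xu[i] / comp.R

    Pv = Xv[:n_n, :]
    pu = Xu[:n_n]
    if kind == "flow":
        av, au = Xv[iao, :], float(Xu[iao])
        qv, qu = np.zeros(n_c), 1.0  # Q_ao is the boundary itself
    else:
        av, au = np.zeros(n_c), 1.0  # P_ao is the boundary itself
        qv = -Pv[nidx[root], :] / r_root
        qu = (1.0 - pu[nidx[root]]) / r_root
    return NodalMaps(kind, labels, nodes, Fv, fu, Pv, pu, av, au, qv, float(qu))


def instantaneous_solve(
    net: LungNetwork,
    v: Mapping[str, float] | np.ndarray,
    q_aw: float | None = None,
    p_aw: float | None = None,
) -> dict:
    """Solve the algebraic circuit at one instant.

    Exactly one of ``q_aw`` (prescribed airway flow, l/s) or ``p_aw``
    (prescribed airway pressure, cmH2O) must be given.  Returns a dict with
    per-compartment inflows ``flows`` (negative values — pendelluft — are
    permitted), internal ``node_pressures``, and the airway-opening ``p_ao``
    and ``q_ao``.
    """
    if (q_aw is None) == (p_aw is None):
        raise ValueError("give exactly one of q_aw or p_aw")
    kind = "flow" if q_aw is not None else "pressure"
    u = q_aw if q_aw is not None else p_aw
    maps = build_nodal_maps(net, kind)
    varr = np.array([v[l] for l in maps.labels]) if isinstance(v, Mapping) else np.asarray(v, float)
    Q = maps.Fv @ varr + maps.fu * u
    p = maps.Pv @ varr + maps.pu * u
    return {
        "flows": dict(zip(maps.labels, Q)),
        "node_pressures": dict(zip(maps.nodes, p)),
        "p_ao": float(maps.av @ varr + maps.au * u),
        "q_ao": float(maps.qv @ varr + maps.qu * u),
    }


# ---------------------------------------------------------------------------
# exact phase propagation


def _phase_generator(net: LungNetwork, boundary: AirwayDrive) -> tuple[np.ndarray, np.ndarray]:
    """Augmented generator G and auxiliary initial tail for one phase.

    The augmented state is (v, aux) with d/dt (v, aux) = G (v, aux); the aux
    block reproduces the forcing exactly: a constant, the pair (t, 1) for a
    ramp, or a rotating (sin, cos) pair for the half-sinusoid.
    """
    kind = "flow" if boundary.kind == "flow_controlled" else "pressure"
    maps = build_nodal_maps(net, kind)
    A, b = maps.Fv, maps.fu
    n = A.shape[0]
    if boundary.shape == "constant":
        G = np.zeros((n + 1, n + 1))
        G[:n, :n] = A
        G[:n, n] = b * boundary.amplitude
        aux0 = np.array([1.0])
    elif boundary.shape == "triangle":
        # u(t) = amp * (1 - t/t_i) = amp + (-amp/t_i) * t
        G = np.zeros((n + 2, n + 2))
        G[:n, :n] = A
        G[:n, n] = b * (-boundary.amplitude / boundary.t_i)  # coefficient of t
        G[:n, n + 1] = b * boundary.amplitude  # constant part
        G[n, n + 1] = 1.0  # dt/dt = 1
        aux0 = np.array([0.0, 1.0])
    elif boundary.shape == "halfsine":
        w = np.pi / boundary.t_i
        G = np.zeros((n + 2, n + 2))
        G[:n, :n] = A
        G[:n, n] = b * boundary.amplitude  # coefficient of sin(w t)
        G[n, n + 1] = w
        G[n + 1, n] = -w
        aux0 = np.array([0.0, 1.0])
    else:
        raise ValueError(f"unknown waveform shape {boundary.shape!r}")
    return G, aux0


def simulate_phase(
    net: LungNetwork,
    boundary: AirwayDrive,
    v0: np.ndarray,
    duration: float,
    dt: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Propagate one phase; return (t_grid, v_samples, v_end).

    ``t_grid`` spans [0, duration] with step ~dt (exactly duration/N);
    ``v_samples`` holds absolute compartment volumes row-wise.  Propagation
    is exact per step (matrix exponential), so refining ``dt`` changes only
    the sampling, not the trajectory or the end state.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")
    n = len(net.compartments)
    v0 = np.asarray(v0, dtype=float)
    G, aux0 = _phase_generator(net, boundary)
    N = max(1, int(round(duration / dt)))
    h = duration / N
    E = expm(G * h)
    z = np.concatenate([v0, aux0])
    vs = np.empty((N + 1, n))
    vs[0] = v0
    for k in range(1, N + 1):
        z = E @ z
        vs[k] = z[:n]
    if vs.min() < -1e-9:
        lab = net.labels[int(np.argmin(vs.min(axis=0)))]
        raise SimulationError(
            f"negative absolute volume in compartment {lab} (min {vs.min():.3e} l): model violated"
        )
    t = np.linspace(0.0, duration, N + 1)
    return t, vs, vs[-1].copy()


# ---------------------------------------------------------------------------
# periodic steady state


@dataclass
class CycleTrajectory:
    """One breath at periodic steady state, sampled on a uniform-by-phase grid.

    Volumes ``V`` are measured above the end-expiratory residual (so
    ``V[:, i][0] == 0``); ``p_ex`` are the per-compartment residual
    end-expiratory pressures (set PEEP + auto-PEEP); ``p_alv = V/C + p_ex``.
    At the phase switch ``t_i`` the grid holds two samples (end-inspiration
    and start-expiration) because flows are discontinuous there.
    """

    net: LungNetwork
    settings: VentilatorSettings
    labels: tuple[str, ...]
    t: np.ndarray
    i_end_insp: int  # index of the end-inspiration sample
    V: np.ndarray  # (nt, nc) volumes above residual, l
    Q: np.ndarray  # (nt, nc) compartment inflows, l/s
    p_alv: np.ndarray  # (nt, nc) alveolar pressures, cmH2O
    q_aw: np.ndarray  # airway-opening flow, l/s
    p_aw: np.ndarray  # airway-opening pressure, cmH2O
    node_p: np.ndarray  # (nt, n_nodes) internal node pressures
    nodes: tuple[str, ...]
    v_star: np.ndarray  # steady-state absolute volumes at cycle start, l
    p_ex: dict[str, float]
    v_t: float  # airway inspired volume, l
    vt_comp: dict[str, float]  # per-compartment end-inspiratory volume, l
    v_peak: dict[str, float]  # per-compartment peak volume over the cycle, l
    dt: float

    @property
    def t_insp(self) -> np.ndarray:
        return self.t[: self.i_end_insp + 1]

    def inspiration(self, arr: np.ndarray) -> np.ndarray:
        """Slice a (nt, ...) sample array to the inspiration grid."""
        return arr[: self.i_end_insp + 1]

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t": self.t, "Q_aw": self.q_aw, "P_aw": self.p_aw}
        for j, lab in enumerate(self.labels):
            cols[f"V_{lab}"] = self.V[:, j]
            cols[f"Q_{lab}"] = self.Q[:, j]
            cols[f"P_{lab}"] = self.p_alv[:, j]
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        return {
            "mode": self.settings.mode,
            "peep": self.settings.peep,
            "v_t": self.v_t,
            "p_ex": dict(self.p_ex),
            "end_inspiratory_volume": dict(self.vt_comp),
        }


def _cycle_propagators(net: LungNetwork, settings: VentilatorSettings):
    """Full-phase propagators (augmented expm) for inspiration and expiration."""
    drive = make_drive(settings)
    Gi, aux_i = _phase_generator(net, drive)
    exp_boundary = AirwayDrive("pressure_controlled", "constant", settings.peep, settings.t_tot - settings.t_i)
    Ge, aux_e = _phase_generator(net, exp_boundary)
    Ei = expm(Gi * settings.t_i)
    Ee = expm(Ge * (settings.t_tot - settings.t_i))
    return drive, exp_boundary, (Ei, aux_i), (Ee, aux_e)


def find_periodic_steady_state(
    net: LungNetwork,
    settings: VentilatorSettings,
    dt: float = 1e-3,
) -> CycleTrajectory:
    """Find the cycled (periodic) steady state of a scenario.

    The one-cycle map is affine, ``v_end = M v0 + c``; M and c are
    identified by propagating the zero state and the unit basis states, the
    fixed point ``v* = (I - M)^{-1} c`` is solved directly, and one
    confirmation cycle checks ``|cycle(v*) - v*| <= 1e-9 l``.  Raises
    :class:`SteadyStateError` if the map is not contracting (impossible for
    a passive RC network, guarded anyway) or confirmation fails.
    """
    problems = validate_network(net) + validate_settings(settings)
    if problems:
        from .drive import ConfigurationError

        raise ConfigurationError("; ".join(problems))
    if settings.target_vt is not None:
        settings = calibrate_drive_to_vt(net, settings)

    labels = net.labels
    n = len(labels)
    drive, exp_boundary, (Ei, aux_i), (Ee, aux_e) = _cycle_propagators(net, settings)

    def run_cycle(v0: np.ndarray) -> np.ndarray:
        z = Ei @ np.concatenate([v0, aux_i])
        z2 = Ee @ np.concatenate([z[:n], aux_e])
        return z2[:n]

    c = run_cycle(np.zeros(n))
    M = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        M[:, j] = run_cycle(e) - c
    rho = max(abs(np.linalg.eigvals(M)))
    if rho >= 1.0:
        raise SteadyStateError(f"cycle map spectral radius {rho:.6f} >= 1: no stable steady state")
    v_star = np.linalg.solve(np.eye(n) - M, c)
    resid = np.max(np.abs(run_cycle(v_star) - v_star))
    if resid > 1e-9:
        raise SteadyStateError(f"fixed-point confirmation failed: residual {resid:.3e} l")

    # sample the steady-state cycle
    t_e = settings.t_tot - settings.t_i
    ti_grid, vi, v_mid = simulate_phase(net, drive, v_star, settings.t_i, dt)
    te_grid, ve, _ = simulate_phase(net, exp_boundary, v_mid, t_e, dt)

    C = np.array([net.compartments[l].C for l in labels])
    mi = build_nodal_maps(net, "flow" if drive.kind == "flow_controlled" else "pressure")
    me = build_nodal_maps(net, "pressure")
    ui = np.asarray(drive(ti_grid), dtype=float)
    ue = np.full_like(te_grid, settings.peep)

    def circuit_series(maps: NodalMaps, vs: np.ndarray, u: np.ndarray):
        Q = vs @ maps.Fv.T + np.outer(u, maps.fu)
        node_p = vs @ maps.Pv.T + np.outer(u, maps.pu)
        p_ao = vs @ maps.av + maps.au * u
        q_ao = vs @ maps.qv + maps.qu * u
        return Q, node_p, p_ao, q_ao

    Qi, npi, pai, qai = circuit_series(mi, vi, ui)
    Qe, npe, pae, qae = circuit_series(me, ve, ue)

    t = np.concatenate([ti_grid, settings.t_i + te_grid])
    v_abs = np.vstack([vi, ve])
    V = v_abs - v_star
    Q = np.vstack([Qi, Qe])
    p_alv = v_abs / C
    q_aw = np.concatenate([qai, qae])
    p_aw = np.concatenate([pai, pae])
    node_p = np.vstack([npi, npe])

    p_ex = dict(zip(labels, v_star / C))
    vt_comp = dict(zip(labels, v_mid - v_star))
    # the volume peak can shift off end-inspiration when compartments
    # exchange gas (pendelluft), e.g. under decelerating flow
    v_peak = dict(zip(labels, V.max(axis=0)))
    v_t = float(np.sum(v_mid - v_star))
    return CycleTrajectory(
        net=net,
        settings=settings,
        labels=labels,
        t=t,
        i_end_insp=len(ti_grid) - 1,
        V=V,
        Q=Q,
        p_alv=p_alv,
        q_aw=q_aw,
        p_aw=p_aw,
        node_p=node_p,
        nodes=mi.nodes,
        v_star=v_star,
        p_ex=p_ex,
        v_t=v_t,
        vt_comp=vt_comp,
        v_peak=v_peak,
        dt=dt,
    )


def node_flow_residuals(traj: CycleTrajectory) -> np.ndarray:
    """Kirchhoff residual (net inflow, l/s) at every internal node and sample.

    Recomputed from the sampled node pressures, alveolar pressures and the
    airway boundary — an independent check that the sampled circuit
    quantities actually satisfy flow balance.
    """
    net = traj.net
    nidx = {nd: i for i, nd in enumerate(traj.nodes)}
    cidx = {l: j for j, l in enumerate(traj.labels)}
    res = np.zeros_like(traj.node_p)
    for parent, child, R in net.edges():
        p_parent = traj.p_aw if parent == "AO" else traj.node_p[:, nidx[parent]]
        if child in nidx:
            p_child = traj.node_p[:, nidx[child]]
            flow = (p_parent - p_child) / R
            res[:, nidx[child]] += flow
            if parent != "AO":
                res[:, nidx[parent]] -= flow
        else:
            p_child = traj.p_alv[:, cidx[child]]
            flow = (p_parent - p_child) / R
            res[:, nidx[parent]] -= flow
    return res
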