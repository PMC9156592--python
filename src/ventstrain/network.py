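"""Airway-tree data model: compartments, shared resistances, ventilator settings.

The lung is represented as a rooted resistive tree fed from the airway
opening.  Internal nodes model the conducting airways; each internal node
carries one named *shared* resistance on its upstream edge.  Every leaf is an
elastic compartment reached through its own terminal resistance, with a
linear compliance ``C`` and an unstressed rest volume ``V_rest``.

Units are fixed throughout the package: pressures in cmH2O, volumes in
litres, time in seconds, resistances in cmH2O*s/l, compliances in l/cmH2O.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import yaml

__all__ = [
    "Compartment",
    "LungNetwork",
    "VentilatorSettings",
    "Scenario",
    "baseline_scenario",
    "validate_network",
    "validate_settings",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
    "scenario_hash",
]

MODES = ("CF", "DF", "SF", "CP")

#: amplitude key expected for each mode (``target_vt`` is accepted for any)
AMPLITUDE_KEYS = {"CF": "q_aw", "DF": "q_max", "SF": "q_max", "CP": "p_set"}


@dataclass(frozen=True)
class Compartment:
    """One elastic lung compartment (a leaf of the airway tree)."""

    label: str
    R: float  # terminal resistance, cmH2O*s/l
    C: float  # compliance, l/cmH2O
    V_rest: float = 1.0  # unstressed rest volume, l


@dataclass(frozen=True)
class LungNetwork:
    """Rooted airway tree with shared resistances and compartment leaves.

    Parameters
    ----------
    compartments
        Mapping label -> :class:`Compartment`.
    shared_resistances
        Mapping resistance name -> value (cmH2O*s/l), one per internal node.
    topology
        Mapping internal-node name -> ``(resistance_name, children)``, where
        children are internal-node names or compartment labels.  The unique
        node that appears in no child list is the root; its resistance
        connects it to the airway opening.
    """

    compartments: Mapping[str, Compartment]
    shared_resistances: Mapping[str, float]
    topology: Mapping[str, tuple[str, tuple[str, ...]]]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.compartments)

    def root(self) -> str:
        children = {c for _, kids in self.topology.values() for c in kids}
        roots = [n for n in self.topology if n not in children]
        if len(roots) != 1:
            raise ValueError(f"topology has {len(roots)} roots, expected 1")
        return roots[0]

    def edges(self) -> list[tuple[str, str, float]]:
        """All edges as (parent, child, resistance); parent 'AO' is the airway opening."""
        out: list[tuple[str, str, float]] = []
        root = self.root()
        rname, _ = self.topology[root]
        out.append(("AO", root, self.shared_resistances[rname]))
        for node, (_, kids) in self.topology.items():
            for child in kids:
                if child in self.topology:
                    crname, _ = self.topology[child]
                    out.append((node, child, self.shared_resistances[crname]))
                else:
                    out.append((node, child, self.compartments[child].R))
        return out

    def path_resistance(self, label: str) -> float:
        """Total series resistance from the airway opening to a compartment."""
        parent = {c: n for n, (_, kids) in self.topology.items() for c in kids}
        if label not in self.compartments:
            raise KeyError(label)
        total = self.compartments[label].R
        node = parent.get(label)
        while node is not None:
            rname, _ = self.topology[node]
            total += self.shared_resistances[rname]
            node = parent.get(node)
        return total

    def with_rest_volumes(self, vrest: float | Mapping[str, float]) -> "LungNetwork":
        """Return a copy with rest volumes replaced (uniform scalar or per label)."""
        comps = {}
        for lab, c in self.compartments.items():
            v = vrest if isinstance(vrest, (int, float)) else vrest[lab]
            comps[lab] = replace(c, V_rest=float(v))
        return replace(self, compartments=comps)


@dataclass(frozen=True)
class VentilatorSettings:
    """Ventilator drive settings: mode, PEEP, timing, and one amplitude.

    Exactly one of ``q_aw`` (CF), ``q_max`` (DF/SF), ``p_set`` (CP) or
    ``target_vt`` (any mode; triggers calibration) must be set.
    """

    mode: str
    peep: float
    t_i: float
    t_tot: float
    q_aw: float | None = None
    q_max: float | None = None
    p_set: float | None = None
    target_vt: float | None = None

    # convenience alias used in examples and docs
    @property
    def PEEP(self) -> float:
        return self.peep

    def amplitude(self) -> tuple[str, float]:
        """Return the single set amplitude as (key, value)."""
        set_ = {
            k: v
            for k, v in (
                ("q_aw", self.q_aw),
                ("q_max", self.q_max),
                ("p_set", self.p_set),
                ("target_vt", self.target_vt),
            )
            if v is not None
        }
        if len(set_) != 1:
            raise ValueError(
                f"exactly one amplitude must be set, got {sorted(set_) or 'none'}"
            )
        return next(iter(set_.items()))


class Scenario(NamedTuple):
    """A complete simulation scenario: network plus ventilator settings."""

    network: LungNetwork
    settings: VentilatorSettings

    # ergonomic passthroughs
    @property
    def compartments(self):
        return self.network.compartments


_BASELINE_R = {"A": 1.0, "B": 15.0, "C": 11.0, "D": 15.0, "E": 7.0}
_BASELINE_C = {"A": 0.08, "B": 0.06, "C": 0.05, "D": 0.02, "E": 0.02}

#: shared resistances quoted with the simulation description (default)
_SHARED_TEXT = {"R0": 1.0, "R1": 1.0, "R2": 2.0, "R3": 1.0}
#: alternative row from the parameter table (R1 = 3)
_SHARED_TABLE1 = {"R0": 1.0, "R1": 3.0, "R2": 2.0, "R3": 1.0}

_DEFAULT_TOPOLOGY = {
    "n1": ("R0", ("A", "n2")),
    "n2": ("R1", ("B", "n3")),
    "n3": ("R2", ("C", "n4")),
    "n4": ("R3", ("D", "E")),
}


def baseline_scenario(mode: str = "CF", shared: str = "text") -> Scenario:
    """The default five-compartment scenario used throughout the simulations.

    Compartments A-E have resistances (1, 15, 11, 15, 7) cmH2O*s/l and
    compliances (0.08, 0.06, 0.05, 0.02, 0.02) l/cmH2O; all rest volumes are
    1 l.  Ventilator: PEEP 2 cmH2O, t_i = 1 s, t_tot = 3 s, with Q_aw = 1.7 l/s
    (CF), Q_max matched to the same tidal volume for DF/SF, and
    P_set = 13.75 cmH2O for CP.

    Parameters
    ----------
    mode
        One of CF, DF, SF, CP.
    shared
        ``"text"`` (default) uses shared resistances R0=1, R1=1, R2=2, R3=1;
        ``"table1"`` selects the alternative R1=3 parameter-table row.
    """
    if shared not in ("text", "table1"):
        raise ValueError(f"shared must be 'text' or 'table1', got {shared!r}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    comps = {
        lab: Compartment(lab, _BASELINE_R[lab], _BASELINE_C[lab], 1.0)
        for lab in "ABCDE"
    }
    net = LungNetwork(
        compartments=comps,
        shared_resistances=dict(_SHARED_TEXT if shared == "text" else _SHARED_TABLE1),
        topology=dict(_DEFAULT_TOPOLOGY),
    )
    amp: dict[str, float] = {}
    if mode == "CF":
        amp["q_aw"] = 1.7
    elif mode == "DF":
        amp["q_max"] = 3.4  # triangle of area 1.7 l over 1 s
    elif mode == "SF":
        amp["q_max"] = 1.7 * 3.141592653589793 / 2.0  # half-sine of area 1.7 l
    else:
        amp["p_set"] = 13.75
    settings = VentilatorSettings(mode=mode, peep=2.0, t_i=1.0, t_tot=3.0, **amp)
    return Scenario(net, settings)


def validate_network(net: LungNetwork) -> list[str]:
    """Check all structural and positivity invariants; return violations.

    An empty list means the network is valid.  Violations are human-readable
    descriptions; nothing is raised.
    """
    v: list[str] = []
    labels = list(net.compartments)
    if len(set(labels)) != len(labels):
        v.append("compartment labels are not unique")
    for lab, c in net.compartments.items():
        if c.label != lab:
            v.append(f"compartment key {lab!r} does not match label {c.label!r}")
        if not c.R > 0:
            v.append(f"compartment {lab}: resistance must be > 0 (got {c.R})")
        if not c.C > 0:
            v.append(f"compartment {lab}: compliance must be > 0 (got {c.C})")
        if not c.V_rest > 0:
            v.append(f"compartment {lab}: rest volume must be > 0 (got {c.V_rest})")
    for name, r in net.shared_resistances.items():
        if not r > 0:
            v.append(f"shared resistance {name}: must be > 0 (got {r})")

    # structural checks on the tree
    nodes = set(net.topology)
    if nodes & set(labels):
        v.append("internal node names collide with compartment labels")
    seen_children: dict[str, str] = {}
    used_res: list[str] = []
    for node, (rname, kids) in net.topology.items():
        if rname not in net.shared_resistances:
            v.append(f"node {node}: unknown shared resistance {rname!r}")
        used_res.append(rname)
        for child in kids:
            if child in seen_children:
                v.append(f"{child!r} has two parents ({seen_children[child]}, {node})")
            seen_children[child] = node
            if child not in nodes and child not in net.compartments:
                v.append(f"node {node}: child {child!r} is neither a node nor a compartment")
    if len(set(used_res)) != len(used_res):
        v.append("a shared resistance is assigned to more than one node")
    unused = set(net.shared_resistances) - set(used_res)
    if unused:
        v.append(f"shared resistances not placed on any edge: {sorted(unused)}")
    roots = [n for n in nodes if n not in seen_children]
    if len(roots) != 1:
        v.append(f"topology must have exactly one root node, found {sorted(roots)}")
    else:
        # reachability: walk down from the root; every node and leaf must be hit
        reached: set[str] = set()
        stack = [roots[0]]
        while stack:
            n = stack.pop()
            if n in reached:
                v.append(f"cycle detected at node {n!r}")
                break
            reached.add(n)
            if n in net.topology:
                stack.extend(net.topology[n][1])
        for lab in labels:
            if lab not in reached:
                v.append(f"compartment {lab} is not connected to the airway opening")
        for n in nodes:
            if n not in reached:
                v.append(f"internal node {n} is not connected to the airway opening")
    n_leaves = sum(1 for c in seen_children if c in net.compartments)
    if n_leaves != len(labels):
        v.append(
            f"number of leaves ({n_leaves}) differs from number of compartments ({len(labels)})"
        )
    return v


def validate_settings(settings: VentilatorSettings) -> list[str]:
    """Check ventilator-settings invariants; return violations."""
    v: list[str] = []
    if settings.mode not in MODES:
        v.append(f"unknown mode {settings.mode!r}; expected one of {MODES}")
    if not 0 < settings.t_i < settings.t_tot:
        v.append(f"require 0 < t_i < t_tot (got t_i={settings.t_i}, t_tot={settings.t_tot})")
    if settings.peep < 0:
        v.append(f"PEEP must be >= 0 (got {settings.peep})")
    try:
        key, val = settings.amplitude()
    except ValueError as e:
        v.append(str(e))
        return v
    if not val > 0:
        v.append(f"amplitude {key} must be > 0 (got {val})")
    if settings.mode in AMPLITUDE_KEYS and key not in (AMPLITUDE_KEYS[settings.mode], "target_vt"):
        v.append(f"mode {settings.mode} expects amplitude {AMPLITUDE_KEYS[settings.mode]!r} or 'target_vt', got {key!r}")
    if settings.mode == "CP" and key == "p_set" and not val > settings.peep:
        v.append(f"CP requires P_set > PEEP (got P_set={val}, PEEP={settings.peep})")
    return v


# ---------------------------------------------------------------------------
# scenario config (YAML) serialization


def scenario_to_dict(scn: Scenario) -> dict:
    net, s = scn
    d = {
        "network": {
            "shared_resistances": {k: float(v) for k, v in net.shared_resistances.items()},
            "topology": {
                n: {"resistance": r, "children": list(kids)}
                for n, (r, kids) in net.topology.items()
            },
            "compartments": {
                lab: {"R": float(c.R), "C": float(c.C), "V_rest": float(c.V_rest)}
                for lab, c in net.compartments.items()
            },
        },
        "ventilator": {
            "mode": s.mode,
            "peep": float(s.peep),
            "ti": float(s.t_i),
            "ttot": float(s.t_tot),
        },
    }
    key, val = s.amplitude()
    d["ventilator"][key] = float(val)
    return d


def scenario_from_dict(d: Mapping) -> Scenario:
    nd = d["network"]
    comps = {
        lab: Compartment(lab, float(c["R"]), float(c["C"]), float(c.get("V_rest", 1.0)))
        for lab, c in nd["compartments"].items()
    }
    topo = {
        n: (spec["resistance"], tuple(spec["children"]))
        for n, spec in nd["topology"].items()
    }
    net = LungNetwork(
        compartments=comps,
        shared_resistances={k: float(v) for k, v in nd["shared_resistances"].items()},
        topology=topo,
    )
    vd = dict(d["ventilator"])
    amp = {k: float(vd[k]) for k in ("q_aw", "q_max", "p_set", "target_vt") if k in vd}
    settings = VentilatorSettings(
        mode=str(vd["mode"]),
        peep=float(vd["peep"]),
        t_i=float(vd["ti"]),
        t_tot=float(vd["ttot"]),
        **amp,
    )
    return Scenario(net, settings)


def save_scenario(scn: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scn), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def scenario_hash(scn: Scenario) -> str:
    """Deterministic short hash of the fully resolved scenario config."""
    blob = json.dumps(scenario_to_dict(scn), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
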