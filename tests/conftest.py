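import hypothesis
import numpy as np
import pytest

import ventstrain as vs

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def baseline():
    return vs.baseline_scenario("CF")


@pytest.fixture(scope="session")
def baseline_traj(baseline):
    net, settings = baseline
    return vs.find_periodic_steady_state(net, settings)


@pytest.fixture(scope="session")
def all_mode_trajs():
    """Steady-state trajectories for all four modes on the baseline scenario."""
    out = {}
    for mode in ("CF", "DF", "SF", "CP"):
        net, settings = vs.baseline_scenario(mode)
        out[mode] = vs.find_periodic_steady_state(net, settings)
    return out


@pytest.fixture()
def single_compartment():
    """Degenerate one-leaf network: series R_total = 2 + 1 = 3, C = 0.05."""
    comp = vs.Compartment("A", R=1.0, C=0.05, V_rest=1.0)
    net = vs.LungNetwork(
        compartments={"A": comp},
        shared_resistances={"R0": 2.0},
        topology={"n1": ("R0", ("A",))},
    )
    return net


def random_network(rng: np.random.Generator) -> vs.LungNetwork:
    """A random valid serial-backbone network (1-4 nodes, 2-6 leaves)."""
    n_nodes = int(rng.integers(1, 5))
    labels = []
    topo = {}
    shared = {}
    for k in range(n_nodes):
        rname = f"R{k}"
        shared[rname] = float(rng.uniform(0.1, 5.0))
        n_leaves = int(rng.integers(1, 3)) if k < n_nodes - 1 else int(rng.integers(1, 4))
        kids = []
        for _ in range(n_leaves):
            lab = chr(ord("A") + len(labels))
            labels.append(lab)
            kids.append(lab)
        if k < n_nodes - 1:
            kids.append(f"n{k + 2}")
        topo[f"n{k + 1}"] = (rname, tuple(kids))
    comps = {
        lab: vs.Compartment(
            lab,
            R=float(rng.uniform(0.5, 20.0)),
            C=float(rng.uniform(0.01, 0.1)),
            V_rest=float(rng.uniform(0.2, 2.0)),
        )
        for lab in labels
    }
    return vs.LungNetwork(comps, shared, topo)
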