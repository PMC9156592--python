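"""Optional matplotlib figures mirroring the standard experiment views.

matplotlib is an optional dependency (``pip install ventstrain[plot]``);
nothing else in the package imports this module.
"""

from __future__ import annotations

from typing import Mapping

from .energetics import EnergeticsTrace
from .solver import CycleTrajectory


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_mode_comparison(results: Mapping[str, tuple[CycleTrajectory, EnergeticsTrace]],
                         quantity: str = "icp"):
    """One panel per mode of a per-compartment quantity over inspiration.

    ``quantity``: ``icp``, ``strain``, ``strain_rate`` or ``volume``.
    Returns the matplotlib Figure.
    """
    plt = _mpl()
    modes = list(results)
    fig, axes = plt.subplots(1, len(modes), figsize=(4 * len(modes), 3.2), sharey=True)
    if len(modes) == 1:
        axes = [axes]
    ylabel = {
        "icp": "ICP_elastic (cmH2O·l/s)",
        "strain": "strain (–)",
        "strain_rate": "strain rate (1/s)",
        "volume": "V above residual (l)",
    }[quantity]
    for ax, mode in zip(axes, modes):
        traj, trace = results[mode]
        for j, lab in enumerate(traj.labels):
            if quantity == "volume":
                ax.plot(traj.t, traj.V[:, j], label=lab)
            else:
                arr = {"icp": trace.icp, "strain": trace.strain,
                       "strain_rate": trace.strain_rate}[quantity]
                ax.plot(trace.t, arr[:, j], label=lab)
        ax.set_title(mode)
        ax.set_xlabel("t (s)")
    axes[0].set_ylabel(ylabel)
    axes[-1].legend(title="compartment", fontsize=8)
    fig.tight_layout()
    return fig


def plot_sweep(result, x: str | None = None, y: str = "S_max"):
    """Per-mode panels of a sweep table: ``y`` against the swept variable."""
    plt = _mpl()
    tab = result.table.dropna(subset=[y])
    x = x or {"peep": "peep", "v_rest": "v_rest", "v_t_set": "v_t_set"}[result.name]
    modes = sorted(tab["mode"].unique())
    fig, axes = plt.subplots(1, len(modes), figsize=(4 * len(modes), 3.2), sharey=True)
    if len(modes) == 1:
        axes = [axes]
    for ax, mode in zip(axes, modes):
        g = tab[tab["mode"] == mode]
        for lab, gg in g.groupby("compartment"):
            gg = gg.sort_values(x)
            ax.plot(gg[x], gg[y], label=lab)
        ax.set_title(mode)
        ax.set_xlabel(x)
    axes[0].set_ylabel(y)
    axes[-1].legend(title="compartment", fontsize=8)
    fig.tight_layout()
    return fig
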