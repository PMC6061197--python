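"""Figure helpers for state diagrams, duration curves and rasters."""

from __future__ import annotations

import numpy as np


def plot_state_diagram(diagram, axes=None):
    """H_s and PLV heat maps over the (g_in/g_ex, D) grid."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5), constrained_layout=True)
    for ax, values, title in zip(axes, (diagram.H_s, diagram.plv), ("H_s", "PLV")):
        im = ax.pcolormesh(
            diagram.ratios, diagram.Ds, values, vmin=0, vmax=1, shading="nearest"
        )
        ax.set_yscale("log")
        ax.set_xlabel("g_in / g_ex")
        ax.set_ylabel("D")
        ax.set_title(title)
        ax.figure.colorbar(im, ax=ax)
    return axes


def plot_duration_curves(table, ax=None, kinds=("active", "quiescent")):
    """Mean period duration vs noise intensity, one curve per composition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5), constrained_layout=True)
    for (name, kind), sub in table.groupby(["composition", "kind"]):
        if kind not in kinds:
            continue
        sub = sub.sort_values("D")
        ax.errorbar(sub.D, sub.mean_ms, yerr=sub.se_ms, label=f"{name} {kind}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("D")
    ax.set_ylabel("mean duration (ms)")
    ax.legend(fontsize=8)
    return ax


def plot_raster(raster, ax=None, max_neurons=512):
    """Spike raster (time vs neuron id) for up to ``max_neurons`` neurons."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5), constrained_layout=True)
    keep = raster.ids < max_neurons
    ax.plot(raster.times[keep], raster.ids[keep], ".", ms=1, color="k")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    ax.set_xlim(raster.t_start, raster.t_end)
    return ax
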