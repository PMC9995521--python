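"""Optional matplotlib figures for sweep curves, response maps and traces."""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_sweep(summary, highlight=("IAA", "Geosmin"), ax=None):
    """Response-versus-concentration curves; designated odours highlighted."""
    plt = _plt()
    ax = ax or plt.subplots()[1]
    for name, row in summary.curves.iterrows():
        if name in highlight:
            ax.semilogx(summary.grid, row.to_numpy(), lw=2.5, label=name)
        else:
            ax.semilogx(summary.grid, row.to_numpy(), color="0.7", lw=0.6, zorder=0)
    ax.set_xlabel("concentration")
    ax.set_ylabel(f"PN SDF, {summary.mode} across glomeruli (Hz)")
    ax.legend()
    return ax


def plot_heatmap(matrix, ax=None):
    """Condition x glomerulus PN activity map."""
    plt = _plt()
    ax = ax or plt.subplots()[1]
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_xlabel("glomerulus")
    ax.figure.colorbar(im, ax=ax, label="mean PN SDF (Hz)")
    return ax


def plot_traces(record, gids, ax=None):
    """Membrane-potential traces of recorded neurons, stacked."""
    plt = _plt()
    ax = ax or plt.subplots()[1]
    idx, V = record.traces["V"]
    t = (np.arange(V.shape[1]) + 1) * record.dt
    lookup = {g: i for i, g in enumerate(idx)}
    for offset, gid in enumerate(gids):
        ax.plot(t, V[lookup[gid]] + 50.0 * offset, lw=0.5,
                label=f"{record.population_of(gid)} {gid}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("V (mV, offset)")
    ax.legend(loc="upper right", fontsize="small")
    return ax
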