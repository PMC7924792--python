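"""Minimal plotting helpers; all figures derive from SweepResult tables."""

from __future__ import annotations

import pandas as pd

__all__ = ["heatmap", "line_plot"]


def heatmap(table: pd.DataFrame, x: str, y: str, value: str = "p_hat", out=None):
    """Pivot a sweep table into a (y, x) heatmap of ``value``.

    Mirrors the rescue-probability surfaces over e.g. (N_c, r_M) or
    (delta, mu).  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot_table(index=y, columns=x, values=value)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.pcolormesh(
        pivot.columns.to_numpy(float),
        pivot.index.to_numpy(float),
        pivot.to_numpy(),
        shading="nearest",
        vmin=0.0,
        vmax=max(1.0, float(pivot.to_numpy().max())),
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label=value)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig


def line_plot(table: pd.DataFrame, x: str, value: str = "p_hat", out=None):
    """Line plot of ``value`` against one swept parameter, with Wilson CIs
    when present."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = table.sort_values(x)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t[x], t[value], "o-")
    if {"ci_low", "ci_high"}.issubset(t.columns) and value == "p_hat":
        ax.fill_between(t[x], t["ci_low"], t["ci_high"], alpha=0.25)
    ax.set_xlabel(x)
    ax.set_ylabel(value)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
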