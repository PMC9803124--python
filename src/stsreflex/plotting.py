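"""Cycle plots: mean +/- std bands with phase-boundary lines."""

from __future__ import annotations

import numpy as np

from .analysis import CycleStats


def plot_cycles(
    stats: CycleStats,
    channels: list[str],
    ref: CycleStats | None = None,
    titles: dict | None = None,
):
    """Plot mean +/- std cycle bands for the given channels.

    Returns the matplotlib figure. Vertical lines mark the mean lift-off and
    momentum-transfer cycle percentages; a reference CycleStats (e.g. from
    synthetic or experimental traces) is overlaid in grey when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pct = np.linspace(0.0, 100.0, len(stats.mean))
    n = len(channels)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.2 * n), sharex=True, squeeze=False)
    for ax, ch in zip(axes[:, 0], channels):
        if ref is not None and ch in ref.mean.columns:
            rm = ref.mean[ch].to_numpy()
            rs = ref.std[ch].to_numpy()
            ax.fill_between(pct, rm - rs, rm + rs, color="0.7", alpha=0.5)
            ax.plot(pct, rm, color="0.4", lw=1.0, label="reference")
        m = stats.mean[ch].to_numpy()
        s = stats.std[ch].to_numpy()
        ax.fill_between(pct, m - s, m + s, color="tab:green", alpha=0.3)
        ax.plot(pct, m, color="tab:green", lw=1.5, label="simulated")
        for name, style in (("liftoff", "--"), ("momentum_transfer", ":")):
            b = stats.boundary_pct_mean.get(name)
            if b is not None:
                ax.axvline(b, color="tab:green", ls=style, lw=0.8)
        ax.set_ylabel((titles or {}).get(ch, ch))
    axes[-1, 0].set_xlabel("STS cycle [%]")
    axes[0, 0].legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig
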