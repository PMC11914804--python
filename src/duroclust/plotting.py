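"""Quick-look figures for single runs."""

from __future__ import annotations

import numpy as np

from .experiments import RunResult


def plot_run(result: RunResult, path: str | None = None):
    """Two-panel summary: cluster numbers and degradation over time,
    plus the final cell configuration colored by cluster.

    Returns the matplotlib figure; saves it when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(result.times, result.S1, label="S1")
    ax1.plot(result.times, result.S2, label="S2")
    ax1.set_xlabel("time (tau)")
    ax1.set_ylabel("cluster number")
    twin = ax1.twinx()
    twin.plot(result.times, result.degraded_percent, color="0.5", ls="--",
              label="degraded %")
    twin.set_ylabel("degraded area (%)")
    if result.tdegr is not None:
        ax1.axvline(result.tdegr, color="k", lw=0.8)
        ax1.annotate("Tdegr", (result.tdegr, ax1.get_ylim()[1]), ha="left")
    ax1.legend(loc="upper left")

    part = result.final_partition
    L = result.params.Lstar
    colors = part.labels % 10
    ax2.scatter(result.final_positions[:, 0], result.final_positions[:, 1],
                c=colors, cmap="tab10", s=25)
    ax2.set_xlim(0, L)
    ax2.set_ylim(0, L)
    ax2.set_aspect("equal")
    ax2.set_title(f"final clusters (S1 = {result.S1[-1]:.2f})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
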