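"""Optional plots: grid-angle force profiles, intact vs ablated."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_grid_forces"]

_SHOWN = ("FCR", "ECRL", "ECU")


def plot_grid_forces(grid_forces: pd.DataFrame, motion: str, path: str | Path) -> Path:
    """Mean +- sd force vs grid angle for FCR, ECRL, ECU, both conditions."""
    sub = grid_forces[(grid_forces["motion"] == motion) & (grid_forces["limb"] == "")]
    fig, axes = plt.subplots(1, len(_SHOWN), figsize=(4 * len(_SHOWN), 3.2), sharex=True)
    for ax, muscle in zip(axes, _SHOWN):
        for condition, style in (("intact", "--"), ("apl_ablated", "-")):
            g = (
                sub[(sub["muscle"] == muscle) & (sub["condition"] == condition)]
                .groupby("grid_value")["force"]
                .agg(["mean", "std"])
                .sort_index()
            )
            ax.plot(g.index, g["mean"], style, label=condition)
            ax.fill_between(g.index, g["mean"] - g["std"], g["mean"] + g["std"], alpha=0.2)
        ax.set_title(muscle)
        ax.set_xlabel("grid angle (deg)")
    axes[0].set_ylabel("force (N)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.suptitle(motion)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
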