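"""Simple report figures: the population auROC map and fitted kernels."""

from __future__ import annotations

from typing import Dict, Optional

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .lickreg import KernelResults  # noqa: E402
from .ratedyn import AurocTimecourse  # noqa: E402


def plot_auroc_map(timecourses: Dict[str, AurocTimecourse],
                   food_time: Optional[float] = None,
                   path: Optional[str] = None):
    """Heat map of auROC vs time, one row per unit (blue = decrease below
    baseline, red = increase), the standard population view of feeding
    responses."""
    units = sorted(timecourses)
    mat = np.vstack([timecourses[u].auroc for u in units])
    t = timecourses[units[0]].window_starts / 60.0
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(units) + 1.5))
    im = ax.imshow(mat, aspect="auto", cmap="RdBu_r", vmin=0, vmax=1,
                   extent=[t[0], t[-1], len(units) - 0.5, -0.5])
    if food_time is not None:
        ax.axvline(food_time / 60.0, color="k", ls="--", lw=1)
    ax.set_yticks(range(len(units)), units)
    ax.set_xlabel("time (min)")
    ax.set_title("auROC vs pre-lickspout baseline")
    fig.colorbar(im, ax=ax, label="auROC")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_kernels(results: KernelResults, unit_id: str = "",
                 path: Optional[str] = None):
    """Lick and bout kernels with significant lags marked."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for name, table, color in (("lick", results.lick_kernel, "goldenrod"),
                               ("bout", results.bout_kernel, "darkorange")):
        ax.plot(table.index, table["coef"], color=color, label=name)
        sig = table[table["significant"]]
        ax.plot(sig.index, sig["coef"], "*", color=color, ms=10)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("lag from event onset (s)")
    ax.set_ylabel("coefficient (spikes/s per event)")
    ax.set_title(f"event kernels {unit_id}".strip())
    ax.legend()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
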