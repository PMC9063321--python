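"""Minimal rendering of lifted motifs as connectivity heatmap strips."""

from __future__ import annotations

import numpy as np

from .core_dfnc import devectorize_upper
from .lifting import EvoDfnc

__all__ = ["plot_motif"]


def plot_motif(motif: EvoDfnc, n_panels: int = 8, ax_list=None):
    """Render a motif as a left-to-right strip of connectivity heatmaps.

    ``n_panels`` frames are sampled evenly across the motif's duration; the
    color range is symmetric at the 95th percentile of the motif's absolute
    values.  Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    idx = np.linspace(0, motif.tau - 1, min(n_panels, motif.tau)).round().astype(int)
    vmax = float(np.percentile(np.abs(motif.frames), 95))
    if ax_list is None:
        fig, ax_list = plt.subplots(1, len(idx), figsize=(2.2 * len(idx), 2.4))
        ax_list = np.atleast_1d(ax_list)
    else:
        fig = ax_list[0].figure
    for ax, t in zip(ax_list, idx):
        ax.imshow(
            devectorize_upper(motif.frames[t]),
            cmap="RdBu_r", vmin=-vmax, vmax=vmax, interpolation="nearest",
        )
        ax.set_title(f"t={t + 1}", fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle(f"EVOdFNC {motif.id + 1}")
    return fig
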