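"""Plots: supershift position profiles and MNase protection heatmaps."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mnase import ProtectionMatrix
from .supershift import SupershiftProfile


def plot_profiles(
    profiles: Sequence[SupershiftProfile],
    path: str | Path | None = None,
    title: str | None = None,
):
    """Relative supershift vs dyad offset, one line per TFBS, SEM shading."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for p in profiles:
        t = p.table.sort_values("dyad_offset")
        ax.plot(t["dyad_offset"], t["mean"], label=f"{p.tfbs_id} ({p.nps_id})")
        sem = t["sem"].to_numpy()
        has_sem = ~np.isnan(sem)
        ax.fill_between(
            t["dyad_offset"][has_sem],
            (t["mean"].to_numpy() - sem)[has_sem],
            (t["mean"].to_numpy() + sem)[has_sem],
            alpha=0.25,
        )
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("TFBS center, bp from dyad")
    ax.set_ylabel("relative supershift (log2)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_protection_heatmap(
    matrices: Sequence[ProtectionMatrix],
    path: str | Path | None = None,
    title: str | None = None,
):
    """Protection across the insert per digestion timepoint (rows)."""
    matrices = sorted(matrices, key=lambda m: m.timepoint)
    img = np.vstack([m.protection for m in matrices])
    fig, ax = plt.subplots(figsize=(7, 0.5 + 0.4 * len(matrices)))
    im = ax.imshow(img, aspect="auto", cmap="hot", vmin=0, vmax=1,
                   extent=(1, img.shape[1], len(matrices) - 0.5, -0.5))
    ax.set_yticks(range(len(matrices)))
    ax.set_yticklabels([f"{m.timepoint} min" for m in matrices])
    ax.set_xlabel("insert position (bp)")
    fig.colorbar(im, ax=ax, label="MNase protection")
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
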