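"""Figure helpers: Pr heatmaps over structural images, profile plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from azquant.profiles import ProfileResult


def pr_heatmap(
    prmap: pd.DataFrame,
    az: pd.DataFrame,
    channel_image: np.ndarray,
    pixel_size_um: float,
    path: str | Path | None = None,
    cmap: str = "inferno",
):
    """Per-AZ release probability rendered over the structural channel."""
    merged = az.merge(prmap[["az_id", "pr_hat"]], on="az_id")
    fig, ax = plt.subplots(figsize=(6, 6))
    extent = (0, channel_image.shape[1] * pixel_size_um,
              channel_image.shape[0] * pixel_size_um, 0)
    ax.imshow(channel_image, cmap="gray", extent=extent)
    sc = ax.scatter(merged["x_um"], merged["y_um"], c=merged["pr_hat"],
                    cmap=cmap, s=18, linewidths=0)
    fig.colorbar(sc, ax=ax, label="Pr")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def profile_plot(profile: ProfileResult, path: str | Path | None = None):
    """Two-channel normalized profile with the ring call annotated."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.distance_um, profile.chanA_norm, label="channel A", lw=1.5)
    ax.plot(profile.distance_um, profile.chanB_norm, label="channel B", lw=1.5)
    if np.isfinite(profile.dip_frac):
        ax.set_title(f"dip = {profile.dip_frac:.2f}"
                     f" ({'ring' if profile.has_ring else 'no ring'})")
    ax.set_xlabel("distance (µm)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
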