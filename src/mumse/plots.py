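"""Static summary figures: MSE profiles per condition and network heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .mse import MSEProfile  # noqa: E402
from .network import ConnectivityGraph  # noqa: E402


def mse_profile_figure(rest: MSEProfile, task: MSEProfile,
                       path: str | Path | None = None):
    """Sample entropy vs. scale factor for both conditions."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    scales = sorted(rest.entropy_by_scale)
    ax.plot(scales, [rest.entropy_by_scale[s] for s in scales], "o-", label="rest")
    ax.plot(scales, [task.entropy_by_scale[s] for s in scales], "s-", label="task")
    ax.set_xlabel("scale factor")
    ax.set_ylabel("sample entropy")
    title = " / ".join(p for p in (rest.electrode, rest.band) if p)
    ax.set_title(title or "MSE profile")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def network_heatmap(g: ConnectivityGraph, path: str | Path | None = None):
    """Phase-coherence weight matrix as a heatmap."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.imshow(g.W, vmin=0, vmax=1, cmap="viridis")
    step = max(1, g.n // 16)
    ticks = range(0, g.n, step)
    ax.set_xticks(list(ticks), [g.labels[i] for i in ticks], rotation=90, fontsize=6)
    ax.set_yticks(list(ticks), [g.labels[i] for i in ticks], fontsize=6)
    label = " / ".join(p for p in (g.band, g.condition) if p)
    ax.set_title(f"phase coherence {label}".strip())
    fig.colorbar(im, ax=ax, label="rPC")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
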