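"""Trace visualization: neuron-by-time heatmaps and stacked waveforms."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .traces import TraceSet

__all__ = ["plot_heatmap", "plot_waveforms"]


def plot_heatmap(
    traces: TraceSet,
    neurons: Sequence[str] | None = None,
    out_path: str | Path | None = None,
    cmap: str = "viridis",
):
    """Membrane voltage as an image: one row per neuron, columns = time."""
    names = list(neurons) if neurons is not None else list(traces.names)
    sub = traces.subset(names)
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(names) + 1.5))
    im = ax.imshow(
        sub.voltage,
        aspect="auto",
        interpolation="nearest",
        extent=(sub.time[0], sub.time[-1], len(names) - 0.5, -0.5),
        cmap=cmap,
    )
    ax.set_yticks(range(len(names)))
    ax.set_yticklabels(names)
    ax.set_xlabel("time (s)")
    fig.colorbar(im, ax=ax, label="membrane voltage (mV)")
    if traces.protocol_id:
        ax.set_title(traces.protocol_id)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_waveforms(
    traces: TraceSet,
    neurons: Sequence[str] | None = None,
    out_path: str | Path | None = None,
):
    """Stacked voltage-vs-time waveforms, one axis per neuron."""
    names = list(neurons) if neurons is not None else list(traces.names)
    fig, axes = plt.subplots(
        len(names), 1, sharex=True, figsize=(8, 1.1 * len(names) + 1)
    )
    axes = np.atleast_1d(axes)
    for ax, nm in zip(axes, names):
        ax.plot(traces.time, traces.trace(nm), lw=0.8)
        ax.set_ylabel(nm, rotation=0, ha="right", va="center")
    axes[-1].set_xlabel("time (s)")
    if traces.protocol_id:
        axes[0].set_title(traces.protocol_id)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
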