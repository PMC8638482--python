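"""Small plotting helpers for reconstruction comparisons."""

from __future__ import annotations

import numpy as np

from .core import ImageSeries
from .metrics import temporal_profile

__all__ = ["plot_nmse_curves", "plot_temporal_profiles", "show_frames"]


def plot_nmse_curves(curves: dict, ax=None):
    """Frame-by-frame NMSE curves, one line per method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, values in curves.items():
        ax.plot(np.arange(len(values)), values, marker="o", label=label)
    ax.set_xlabel("frame")
    ax.set_ylabel("NMSE")
    ax.legend()
    return ax


def plot_temporal_profiles(series_map: dict, x_column: int, axes=None):
    """x-t profiles through one column, one panel per series."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, len(series_map), squeeze=False)
        axes = axes[0]
    for ax, (label, series) in zip(axes, series_map.items()):
        ax.imshow(temporal_profile(series, x_column).T, cmap="gray", aspect="auto")
        ax.set_title(label)
        ax.set_xlabel("frame")
    return axes


def show_frames(series: ImageSeries, frames=(0,), axes=None):
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, len(frames), squeeze=False)
        axes = axes[0]
    for ax, t in zip(axes, frames):
        ax.imshow(series.magnitude[t], cmap="gray")
        ax.set_title(f"frame {t}")
        ax.axis("off")
    return axes
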