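"""Final image formation and quantitative evaluation.

Coil images are combined by root-sum-of-squares (no sensitivity maps needed);
reconstruction quality is summarized by the per-frame normalized mean-square
error over a region of interest,

    NMSE(I_ref, I_recon) = ||I_ref - I_recon||^2 / ||I_ref||^2,

and by x-t temporal profiles through a chosen image column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ImageSeries

__all__ = ["rss_combine", "nmse", "temporal_profile", "nmse_to_csv"]


def rss_combine(coil_images: np.ndarray, provenance: str = "") -> ImageSeries:
    """Root-sum-of-squares of complex coil images ``[coil, frame, y, x]``."""
    coil_images = np.asarray(coil_images)
    mag = np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))
    return ImageSeries(magnitude=mag, provenance=provenance)


def nmse(
    ref: ImageSeries | np.ndarray,
    recon: ImageSeries | np.ndarray,
    roi: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame NMSE over the ROI (full frame by default)."""
    ref_m = ref.magnitude if isinstance(ref, ImageSeries) else np.asarray(ref)
    rec_m = recon.magnitude if isinstance(recon, ImageSeries) else np.asarray(recon)
    if ref_m.shape != rec_m.shape:
        raise ValueError("reference and reconstruction shapes disagree")
    if roi is None:
        roi = np.ones(ref_m.shape[1:], dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    r = ref_m[:, roi]
    x = rec_m[:, roi]
    denom = np.sum(r**2, axis=1)
    if np.any(denom <= 0):
        raise ValueError("reference ROI energy is zero in some frame")
    return np.sum((r - x) ** 2, axis=1) / denom


def temporal_profile(series: ImageSeries | np.ndarray, x_column: int) -> np.ndarray:
    """x-t profile: magnitude along one spatial column across frames ([frame, y])."""
    mag = series.magnitude if isinstance(series, ImageSeries) else np.asarray(series)
    if not 0 <= x_column < mag.shape[2]:
        raise IndexError(f"column {x_column} out of bounds")
    return mag[:, :, x_column]


def nmse_to_csv(path, values: np.ndarray, label: str = "nmse") -> None:
    """Write per-frame NMSE values to CSV."""
    pd.DataFrame({"frame": np.arange(len(values)), label: values}).to_csv(
        path, index=False
    )
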