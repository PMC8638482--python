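"""Scaling normalization between stage-1 output and the acquired data.

The CS-reconstructed k-space and the measured k-space are modeled as
differing by a single complex scale per frame (and, here, per coil):
``d_recon = beta * d_acq``.  beta is estimated by least squares over the
overlapping k-space locations and the reconstructed-only samples are divided
by it, so the stage-2 kernel sees data on the acquired scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ScaleEstimate", "estimate_beta", "estimate_frame_betas", "apply_normalization"]

_BETA_MIN = 1e-12


@dataclass
class ScaleEstimate:
    """Complex scale between reconstructed and acquired data on an overlap."""

    beta: complex
    n_overlap: int
    residual_rel: float


def estimate_beta(
    recon: np.ndarray, acq: np.ndarray, overlap_mask: np.ndarray | None = None
) -> ScaleEstimate:
    """Least-squares fit of ``recon = beta * acq`` over the overlap.

    ``beta = <acq, recon> / ||acq||^2``; ``residual_rel`` is the remaining
    fraction ``||recon - beta*acq|| / ||recon||`` on the overlap.
    """
    recon = np.asarray(recon)
    acq = np.asarray(acq)
    if overlap_mask is not None:
        overlap_mask = np.asarray(overlap_mask, dtype=bool)
        recon = recon[overlap_mask]
        acq = acq[overlap_mask]
    if recon.size == 0:
        raise ValueError("empty overlap: cannot estimate beta")
    energy = np.vdot(acq, acq).real
    if energy <= 0:
        raise ValueError("acquired overlap energy is zero")
    beta = complex(np.vdot(acq, recon) / energy)
    resid = recon - beta * acq
    rnorm = np.linalg.norm(recon.ravel())
    residual_rel = float(np.linalg.norm(resid.ravel()) / rnorm) if rnorm > 0 else 0.0
    return ScaleEstimate(beta=beta, n_overlap=int(recon.size), residual_rel=residual_rel)


def estimate_frame_betas(
    raw_recon: np.ndarray, acquired: np.ndarray, overlap_mask: np.ndarray
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-(coil, frame) beta estimates.

    ``raw_recon`` and ``acquired``: ``[coil, frame, ky, kx]``;
    ``overlap_mask``: boolean ``[frame, ky]`` (the acquired locations).
    Returns the complex beta array ``[coil, frame]`` and a diagnostics table.
    """
    n_coils, n_frames = raw_recon.shape[:2]
    betas = np.ones((n_coils, n_frames), dtype=complex)
    rows = []
    for c in range(n_coils):
        for t in range(n_frames):
            sel = overlap_mask[t]
            est = estimate_beta(raw_recon[c, t][sel], acquired[c, t][sel])
            betas[c, t] = est.beta
            rows.append(
                {
                    "coil": c,
                    "frame": t,
                    "abs_beta": abs(est.beta),
                    "arg_beta": float(np.angle(est.beta)),
                    "residual_rel": est.residual_rel,
                    "n_overlap": est.n_overlap,
                }
            )
    table = pd.DataFrame(rows)
    logger.debug("beta table:\n%s", table.to_string(index=False))
    return betas, table


def apply_normalization(
    recon_kt: np.ndarray,
    betas: np.ndarray,
    acquired_mask: np.ndarray,
    acquired_kt: np.ndarray | None = None,
) -> np.ndarray:
    """Divide reconstructed-only samples by beta; acquired samples untouched.

    ``recon_kt``: ``[coil, frame, ky, kx]``; ``betas``: ``[coil, frame]``;
    ``acquired_mask``: boolean ``[frame, ky]``.  If ``acquired_kt`` is given,
    acquired locations are taken verbatim from it (otherwise from
    ``recon_kt`` itself).
    """
    betas = np.asarray(betas, dtype=complex)
    if np.any(np.abs(betas) < _BETA_MIN):
        raise ValueError("degenerate scale: |beta| below 1e-12")
    scaled = recon_kt / betas[:, :, None, None]
    src = acquired_kt if acquired_kt is not None else recon_kt
    keep = acquired_mask[None, :, :, None]
    return np.where(keep, src, scaled)
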