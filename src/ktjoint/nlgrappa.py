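"""Nonlinear GRAPPA: stage-2 parallel-imaging interpolation.

Each k-space line missing from the uniform lattice is predicted as a
truncated second-order polynomial of neighboring acquired lattice data across
all coils: a constant term, all first-order source samples
``S_l(ky + b*R, kx + h)``, their squares, and the products of same-line
samples one and two readout columns apart.  The coefficient set is calibrated
on the fully sampled ACS block by Tikhonov-regularized least squares, jointly
over all frames, one stacked solve per target offset ``r in 1..R-1``
predicting all target coils at once.

Source-block geometry follows GRAPPA conventions: blocks ``b = b1..b2`` in
units of R lines bracket the target, columns ``h = h1..h2`` in readout
samples.  Sources clipped outside k-space are zero-filled by default
(``edge_mode="zero"``); ``"strict"`` raises instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sampling import SamplingPlan

logger = logging.getLogger(__name__)

__all__ = ["KernelGeometry", "NLGKernel", "build_features", "calibrate", "apply_kernel"]


@dataclass
class KernelGeometry:
    """Source geometry of the interpolation kernel.

    ``orf`` is the outer reduction factor R (= the sampling plan's r1).
    Feature count = 1 + 2*L*B*H + L*B*(H-1) + L*B*(H-2) with B = b2-b1+1,
    H = h2-h1+1 (second-order groups drop out when ``second_order=False``).
    """

    n_coils: int
    orf: int
    b1: int = -1
    b2: int = 2
    h1: int = -2
    h2: int = 2
    second_order: bool = True
    edge_mode: str = "zero"

    def __post_init__(self) -> None:
        if self.b2 <= self.b1 and not (self.b1 <= 0 <= self.b2):
            raise ValueError("source blocks must bracket the target line")
        if self.h2 < self.h1:
            raise ValueError("h2 must be >= h1")
        if self.orf < 1:
            raise ValueError("orf must be >= 1")
        if self.edge_mode not in ("zero", "strict"):
            raise ValueError(f"unknown edge_mode {self.edge_mode!r}")

    @property
    def n_blocks(self) -> int:
        return self.b2 - self.b1 + 1

    @property
    def n_cols(self) -> int:
        return self.h2 - self.h1 + 1

    @property
    def offsets(self) -> tuple[int, ...]:
        return tuple(range(1, self.orf))

    @property
    def n_features(self) -> int:
        L, B, H = self.n_coils, self.n_blocks, self.n_cols
        n = 1 + L * B * H
        if self.second_order:
            n += L * B * H + L * B * max(H - 1, 0) + L * B * max(H - 2, 0)
        return n


@dataclass
class NLGKernel:
    """Calibrated coefficient set: one weight matrix per target offset."""

    geometry: KernelGeometry
    weights: dict = field(default_factory=dict)  # offset r -> [n_features, L]
    regularization: float = 0.0
    calib_residual_rel: float = 0.0

    @property
    def n_target_columns(self) -> int:
        return self.geometry.n_coils * len(self.geometry.offsets)


def _source_grid(kspace: np.ndarray, base_line: int, geom: KernelGeometry) -> np.ndarray:
    """Gather sources -> ``G[l, b, h, kx]`` with zero-filled edges.

    ``kspace``: ``[L, n_pe, n_kx]``; sources at rows ``base_line + b*orf``
    and columns ``kx + h``.
    """
    L, n_pe, n_kx = kspace.shape
    B, H = geom.n_blocks, geom.n_cols
    pad_l, pad_r = max(-geom.h1, 0), max(geom.h2, 0)
    padded = np.pad(kspace, ((0, 0), (0, 0), (pad_l, pad_r)))
    G = np.zeros((L, B, H, n_kx), dtype=kspace.dtype)
    for bi, b in enumerate(range(geom.b1, geom.b2 + 1)):
        row = base_line + b * geom.orf
        if row < 0 or row >= n_pe:
            if geom.edge_mode == "strict":
                raise IndexError(
                    f"source row {row} outside k-space (edge_mode='strict')"
                )
            continue
        for hi, h in enumerate(range(geom.h1, geom.h2 + 1)):
            G[:, bi, hi, :] = padded[:, row, pad_l + h : pad_l + h + n_kx]
    return G


def _features_from_grid(G: np.ndarray) -> np.ndarray:
    """Stack feature groups from ``G[l, b, h, kx]`` -> ``[n_kx, F]``.

    Order: constant; first-order (coil-major, then block, then column);
    squares; adjacent-column products; skip-one-column products.
    """
    L, B, H, n_kx = G.shape
    first = G.reshape(L * B * H, n_kx)
    groups = [np.ones((1, n_kx), dtype=G.dtype), first]
    groups.append((G * G).reshape(L * B * H, n_kx))
    if H >= 2:
        groups.append((G[:, :, :-1] * G[:, :, 1:]).reshape(L * B * (H - 1), n_kx))
    if H >= 3:
        groups.append((G[:, :, :-2] * G[:, :, 2:]).reshape(L * B * (H - 2), n_kx))
    return np.concatenate(groups, axis=0).T


def _features_linear(G: np.ndarray) -> np.ndarray:
    L, B, H, n_kx = G.shape
    return np.concatenate(
        [np.ones((1, n_kx), dtype=G.dtype), G.reshape(L * B * H, n_kx)], axis=0
    ).T


def build_features(
    kspace: np.ndarray, ky: int, kx, geom: KernelGeometry
) -> np.ndarray:
    """Feature vector(s) for target line ``ky`` (offset already subtracted:
    ``ky`` here is the *base* lattice line; see :func:`apply_kernel`).

    ``kspace``: one frame ``[L, n_pe, n_kx]``.  ``kx`` may be a scalar or an
    array of column indices; returns ``[len(kx), n_features]`` (or a single
    vector for a scalar ``kx``).
    """
    G = _source_grid(kspace, ky, geom)
    feats = _features_from_grid(G) if geom.second_order else _features_linear(G)
    scalar = np.isscalar(kx)
    kx = np.atleast_1d(kx)
    out = feats[kx]
    return out[0] if scalar else out


def _calibration_rows(acs_kspace, acs_lines, geom):
    """Stack (features, targets) over frames / sliding targets / columns.

    ``acs_kspace``: ``[frame, L, n_pe, n_kx]`` (full grid, ACS lines
    populated); ``acs_lines``: sorted array of ACS line indices.
    Calibration sources and targets are both restricted to the ACS block and
    to interior readout columns, so no zero-filled samples enter the fit.
    Only bases aligned with the lattice phase (``base % orf == 0``) are used,
    matching the geometry the kernel is applied with.
    """
    n_frames, L, n_pe, n_kx = acs_kspace.shape
    lo, hi = acs_lines.min(), acs_lines.max()
    col_lo, col_hi = max(-geom.h1, 0), n_kx - max(geom.h2, 0)
    cols = np.arange(col_lo, col_hi)
    if cols.size == 0:
        raise ValueError("readout too narrow for the kernel column range")
    acs_set = set(int(x) for x in acs_lines)
    per_offset = {}
    for r in geom.offsets:
        A_rows, T_rows = [], []
        for base in range(lo, hi + 1):
            if base % geom.orf:
                continue
            target = base + r
            src_rows = [base + b * geom.orf for b in range(geom.b1, geom.b2 + 1)]
            if target not in acs_set:
                continue
            if any(s not in acs_set for s in src_rows):
                continue
            for t in range(n_frames):
                G = _source_grid(acs_kspace[t], base, geom)
                feats = (
                    _features_from_grid(G)
                    if geom.second_order
                    else _features_linear(G)
                )
                A_rows.append(feats[cols])
                T_rows.append(acs_kspace[t, :, target][:, cols].T)  # [n_cols, L]
        if not A_rows:
            raise ValueError(
                f"ACS block too small for kernel geometry at offset r={r}: "
                "no valid calibration targets"
            )
        per_offset[r] = (np.concatenate(A_rows), np.concatenate(T_rows))
    return per_offset


def calibrate(
    acs_kspace: np.ndarray,
    geom: KernelGeometry,
    acs_lines: np.ndarray,
    reg_rel: float = 1e-6,
) -> NLGKernel:
    """Fit the kernel on ACS data, jointly over frames.

    ``acs_kspace``: ``[frame, L, n_pe, n_kx]`` with the ACS lines populated
    (other lines are ignored).  ``reg_rel`` scales the Tikhonov term by the
    mean diagonal of the normal matrix; features are rms-normalized before
    the solve to condition the second-order terms (folded back into the
    returned weights, so application uses raw features).
    """
    acs_lines = np.asarray(acs_lines)
    if acs_lines.size == 0:
        raise ValueError("no ACS lines given")
    per_offset = _calibration_rows(acs_kspace, acs_lines, geom)
    weights = {}
    total_res, total_tgt = 0.0, 0.0
    reg_used = 0.0
    for r, (A, T) in per_offset.items():
        n_eq, n_feat = A.shape
        if n_eq < n_feat and reg_rel <= 0:
            raise ValueError(
                f"underdetermined calibration at offset r={r} "
                f"({n_eq} equations, {n_feat} features): set reg_rel > 0"
            )
        scales = np.sqrt(np.mean(np.abs(A) ** 2, axis=0))
        scales = np.where(scales > 0, scales, 1.0)
        As = A / scales
        AtA = As.conj().T @ As
        reg = reg_rel * float(np.mean(np.diag(AtA).real))
        if reg_rel <= 0:
            # unregularized: fail loudly on rank deficiency
            rank = np.linalg.matrix_rank(AtA)
            if rank < n_feat:
                raise ValueError(
                    f"rank-deficient calibration system at offset r={r} "
                    f"(rank {rank} < {n_feat}): increase reg_rel"
                )
        AtT = As.conj().T @ T
        ws = np.linalg.solve(AtA + reg * np.eye(n_feat), AtT)
        w = ws / scales[:, None]
        weights[r] = w
        resid = A @ w - T
        total_res += float(np.sum(np.abs(resid) ** 2))
        total_tgt += float(np.sum(np.abs(T) ** 2))
        reg_used = max(reg_used, reg)
    residual_rel = float(np.sqrt(total_res / total_tgt)) if total_tgt > 0 else 0.0
    logger.info(
        "nonlinear GRAPPA calibration: %d offsets, %d features, residual_rel=%.3e",
        len(weights), geom.n_features, residual_rel,
    )
    return NLGKernel(
        geometry=geom,
        weights=weights,
        regularization=reg_used,
        calib_residual_rel=residual_rel,
    )


def apply_kernel(
    uniform_kt: np.ndarray,
    kernel: NLGKernel,
    plan: SamplingPlan,
    acquired_kt: np.ndarray | None = None,
) -> np.ndarray:
    """Fill all non-lattice lines of every frame/coil from the lattice.

    ``uniform_kt``: ``[coil, frame, ky, kx]``, complete on the uniform
    lattice (and carrying measured values at acquired locations).  ACS lines
    keep their measured values; acquired locations are returned bit-identical
    to the input.  ``acquired_kt`` optionally supplies the measured data for
    the ACS override (defaults to ``uniform_kt`` itself, which already holds
    measured values there).
    """
    geom = kernel.geometry
    if geom.orf != plan.r1:
        raise ValueError(
            f"kernel geometry orf={geom.orf} inconsistent with plan r1={plan.r1}"
        )
    if geom.n_coils != uniform_kt.shape[0]:
        raise ValueError("kernel coil count disagrees with data")
    if plan.offset_mode != "fixed":
        raise ValueError("kernel application requires a frame-invariant lattice")
    n_coils, n_frames, n_pe, n_kx = uniform_kt.shape
    out = uniform_kt.copy()
    if geom.orf == 1:
        return out
    lattice_lines = np.flatnonzero(plan.uniform_mask[0])
    src = acquired_kt if acquired_kt is not None else uniform_kt
    acs_lines = np.flatnonzero(plan.acs_mask)
    lattice_set = set(int(x) for x in lattice_lines)
    for t in range(n_frames):
        frame = uniform_kt[:, t]  # [L, n_pe, n_kx]
        for ky in range(n_pe):
            if ky in lattice_set:
                continue
            r = ky % geom.orf  # lattice offset 0 => base = ky - r on lattice
            base = ky - r
            if r not in kernel.weights:
                raise ValueError(f"kernel has no weights for offset r={r}")
            G = _source_grid(frame, base, geom)
            feats = (
                _features_from_grid(G) if geom.second_order else _features_linear(G)
            )
            out[:, t, ky, :] = (feats @ kernel.weights[r]).T
    # measured ACS lines override predictions
    for ky in acs_lines:
        out[:, :, ky, :] = src[:, :, ky, :]
    return out
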