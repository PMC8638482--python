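"""k-t FOCUSS: compressed-sensing recovery in the x-f domain.

Stage 1 of the joint framework.  The randomly-subsetted k-t acquisition of a
single coil is recovered on the uniform lattice by approximating the sparse
(l1) recovery problem

    min ||rho||_1  s.t.  ||d - F rho||_2 <= eps

with FOCUSS iteratively-reweighted l2 minimization.  Writing rho = W q with a
diagonal weight matrix W, each reweighting solves the ridge problem

    min_q ||d - F W q||^2 + lam ||q||^2

whose solution rho = W W^H F^H (F W W^H F^H + lam I)^{-1} d is computed by
conjugate gradients on the (Hermitian positive-definite) bracketed system,
never forming a matrix.  W is then updated elementwise to |rho|^0.5.

The readout (frequency-encode) axis is inverse-transformed first, so the
reconstruction decouples into independent 2-D (PE x frame) subproblems per
readout column; all columns are solved simultaneously with a batched CG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import cfft, cifft, kt_to_xf, xf_to_kt
from .sampling import SamplingPlan

logger = logging.getLogger(__name__)

__all__ = [
    "FocussConfig",
    "FocussState",
    "xf_forward",
    "init_weights",
    "cg_solve",
    "cg_solve_operator",
    "focuss_iterate",
    "focuss_reconstruct",
]


@dataclass
class FocussConfig:
    """Tunables of the FOCUSS solver.

    outer_iters : number of reweightings after the ACS-based initialization
        (each reweighting reruns the CG ridge solve with the updated W).
    lambda_rel : ridge parameter as a fraction of the mean acquired power.
    weight_power : exponent of |rho| in the weight update (0.5 by default,
        which targets the l1 objective).
    weight_floor_rel : elementwise floor on W as a fraction of its maximum,
        keeping re-entry possible for zero-initialized components.
    baseline_subtract : optionally subtract the temporal-average k-space
        (estimated from acquired samples) before solving and add it back,
        the classic temporal-DC-removed variant.
    """

    outer_iters: int = 2
    cg_max_iters: int = 40
    cg_tol: float = 1e-6
    lambda_rel: float = 0.01
    weight_power: float = 0.5
    weight_floor_rel: float = 1e-4
    baseline_subtract: bool = False


@dataclass
class FocussState:
    """Solver state: the diagonal of W plus iteration bookkeeping."""

    weights: np.ndarray
    lam: float
    outer_iters: int = 2
    cg_max_iters: int = 40
    cg_tol: float = 1e-6
    weight_power: float = 0.5
    weight_floor: float = 0.0
    objective_trace: list = field(default_factory=list)


def xf_forward(kt_line_data: np.ndarray) -> np.ndarray:
    """k-t ([t, ky, ...]) -> x-f ([f, y, ...]); adjoint/inverse of F."""
    return kt_to_xf(kt_line_data, t_axis=0, ky_axis=1)


def _floor_weights(w: np.ndarray, floor_rel: float) -> np.ndarray:
    floor = floor_rel * (w.max() if w.size else 0.0)
    return np.maximum(w, floor)


def init_weights(
    kt_data: np.ndarray,
    acs_mask: np.ndarray,
    weight_power: float = 0.5,
    weight_floor_rel: float = 1e-4,
) -> np.ndarray:
    """Initial W from the low-resolution (ACS-only) x-f image.

    Zero-fills everything outside the ACS block, transforms to x-f and takes
    ``|rho|**weight_power`` floored at ``weight_floor_rel * max``.

    ``kt_data``: ``[frame, ky, ...]``; ``acs_mask``: boolean ``[ky]``.
    """
    acs_mask = np.asarray(acs_mask, dtype=bool)
    if not acs_mask.any():
        raise ValueError(
            "empty ACS block: initialize weights uniformly instead "
            "(e.g. np.ones_like) or provide ACS lines"
        )
    shape = [1, acs_mask.size] + [1] * (kt_data.ndim - 2)
    lowres = kt_data * acs_mask.reshape(shape)
    rho0 = xf_forward(lowres)
    w = np.abs(rho0) ** weight_power
    return _floor_weights(w, weight_floor_rel)


def _batched_cg(apply_m, b, tol, max_iters, dot_axes, x0=None):
    """CG for M x = b, batched over trailing axes not in ``dot_axes``.

    ``apply_m`` must be Hermitian positive (semi-)definite per batch element.
    Returns (x, n_iters, converged_mask, relative_residuals).
    """

    def _dot(u, v):
        return np.sum(np.conj(u) * v, axis=dot_axes).real

    if x0 is None:
        x = np.zeros_like(b)
        r = b.copy()
    else:
        x = x0.copy()
        r = b - apply_m(x)
    p = r.copy()
    rs = _dot(r, r)
    bnorm = np.sqrt(_dot(b, b))
    bnorm_safe = np.where(bnorm > 0, bnorm, 1.0)
    n_it = 0
    for n_it in range(1, max_iters + 1):
        mp = apply_m(p)
        denom = _dot(p, mp)
        alpha = np.where(denom > 0, rs / np.where(denom > 0, denom, 1.0), 0.0)
        x = x + alpha * p
        r = r - alpha * mp
        rs_new = _dot(r, r)
        if np.all(np.sqrt(rs_new) <= tol * bnorm_safe):
            rs = rs_new
            break
        beta = np.where(rs > 0, rs_new / np.where(rs > 0, rs, 1.0), 0.0)
        p = r + beta * p
        rs = rs_new
    rel = np.sqrt(rs) / bnorm_safe
    return x, n_it, np.sqrt(rs) <= tol * bnorm_safe, rel


def cg_solve_operator(
    d: np.ndarray,
    forward,
    adjoint,
    weights: np.ndarray,
    lam: float,
    cg_tol: float = 1e-6,
    cg_max_iters: int = 40,
    dot_axes=None,
    y0=None,
):
    """One FOCUSS ridge solve for a general masked-encoding operator.

    ``forward`` maps an x-f-like array to the measurement domain (already
    masked, zero off the acquired support); ``adjoint`` is its adjoint.
    Returns ``(rho, info)`` with ``rho = W^2 adjoint(y)`` where ``y`` solves
    ``(forward W^2 adjoint + lam I) y = d`` by conjugate gradients.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(weights))):
        raise ValueError("non-finite inputs")
    if dot_axes is None:
        dot_axes = tuple(range(d.ndim))
    w2 = weights * weights

    def apply_m(y):
        return forward(w2 * adjoint(y)) + lam * y

    y, n_it, conv, rel = _batched_cg(apply_m, d, cg_tol, cg_max_iters, dot_axes, x0=y0)
    rho = w2 * adjoint(y)
    info = {
        "cg_iters": n_it,
        "converged": bool(np.all(conv)),
        "max_rel_residual": float(np.max(rel)),
        "y": y,
    }
    return rho, info


def cg_solve(
    d: np.ndarray,
    mask: np.ndarray,
    weights: np.ndarray,
    lam: float,
    cg_tol: float = 1e-6,
    cg_max_iters: int = 40,
):
    """FOCUSS ridge solve for masked k-t data.

    ``d``: k-t samples ``[frame, ky, ...]`` with zeros off the acquired
    support; ``mask``: boolean ``[frame, ky]``; ``weights``: x-f weights of
    the same shape as the x-f image.  Batched over any trailing axes.
    """
    mask = np.asarray(mask, dtype=bool)
    msk = mask.reshape(mask.shape + (1,) * (d.ndim - 2))

    def forward(rho):
        return xf_to_kt(rho) * msk

    def adjoint(y):
        return kt_to_xf(y * msk)

    return cg_solve_operator(
        d * msk, forward, adjoint, weights, lam,
        cg_tol=cg_tol, cg_max_iters=cg_max_iters, dot_axes=(0, 1),
    )


def _objective(d, forward, rho, weights, lam):
    """Eq-5-style objective ||d - F W q||^2 + lam ||q||^2 with rho = W q."""
    resid = d - forward(rho)
    wsafe = np.where(weights > 0, weights, 1.0)
    q = np.where(weights > 0, rho / wsafe, 0.0)
    return float(np.vdot(resid, resid).real + lam * np.vdot(q, q).real)


def focuss_iterate(
    d: np.ndarray,
    forward,
    adjoint,
    init_w: np.ndarray,
    lam: float,
    outer_iters: int = 2,
    cg_tol: float = 1e-6,
    cg_max_iters: int = 40,
    weight_power: float = 0.5,
    weight_floor_rel: float = 1e-4,
    dot_axes=None,
):
    """Run the FOCUSS outer loop for a general operator; returns (rho, state).

    Performs ``outer_iters + 1`` CG ridge solves, updating the weights to
    ``|rho|**weight_power`` (floored) between solves.  If the objective
    increases across reweightings the best iterate is kept and a warning is
    emitted.
    """
    weights = _floor_weights(np.asarray(init_w, dtype=float), weight_floor_rel)
    best_rho, best_sur = None, np.inf
    trace = []
    rho = None
    y_prev = None
    for l in range(outer_iters + 1):
        rho, info = cg_solve_operator(
            d, forward, adjoint, weights, lam,
            cg_tol=cg_tol, cg_max_iters=cg_max_iters, dot_axes=dot_axes,
            y0=y_prev,
        )
        y_prev = info["y"]
        obj = _objective(d, forward, rho, weights, lam)
        resid2 = float(np.vdot(d - forward(rho), d - forward(rho)).real)
        # the majorize-minimize surrogate the reweighting provably decreases
        surrogate = resid2 + 2 * lam * float(np.sum(np.abs(rho)))
        trace.append(obj)
        logger.debug(
            "FOCUSS outer iter %d: objective=%.6g, surrogate=%.6g, "
            "cg_iters=%d, converged=%s",
            l, obj, surrogate, info["cg_iters"], info["converged"],
        )
        if surrogate < best_sur:
            best_sur, best_rho = surrogate, rho
        elif surrogate > best_sur * (1 + 1e-2):
            warnings.warn(
                "FOCUSS surrogate objective increased across reweightings; "
                "returning best iterate",
                RuntimeWarning,
            )
            rho = best_rho
            break
        if l < outer_iters:
            weights = _floor_weights(np.abs(rho) ** weight_power, weight_floor_rel)
    state = FocussState(
        weights=weights, lam=lam, outer_iters=outer_iters,
        cg_max_iters=cg_max_iters, cg_tol=cg_tol, weight_power=weight_power,
        objective_trace=trace,
    )
    return rho, state


def _temporal_baseline(d: np.ndarray, acq: np.ndarray) -> np.ndarray:
    """Per-line temporal average of the acquired samples (k-space DC frame)."""
    counts = acq.sum(axis=0)  # [ky]
    shape = (acq.shape[1],) + (1,) * (d.ndim - 2)
    counts = counts.reshape(shape)
    total = np.sum(d, axis=0)
    return np.where(counts > 0, total / np.where(counts > 0, counts, 1), 0.0)


def focuss_reconstruct(
    kspace: np.ndarray,
    plan: SamplingPlan,
    config: FocussConfig | None = None,
    fill: str = "lattice",
    return_raw: bool = False,
):
    """Stage-1 reconstruction of one coil's k-t data.

    Parameters
    ----------
    kspace : complex ``[frame, ky, kx]``, zero off the acquired support.
    plan : the sampling plan whose acquired mask produced ``kspace``.
    fill : ``"lattice"`` (default) fills only the uniform-lattice and ACS
        lines, leaving the rest for the parallel-imaging stage; ``"all"``
        fills every line (the coil-wise CS-only baseline).
    return_raw : also return the un-overridden model prediction, used by the
        scaling-normalization step.

    Returns the data-consistent k-t array (measured samples verbatim,
    reconstructed values elsewhere on the fill support, zero outside), plus
    the solver state, plus (optionally) the raw prediction.
    """
    cfg = config or FocussConfig()
    if fill not in ("lattice", "all"):
        raise ValueError(f"unknown fill mode {fill!r}")
    acq = plan.acquired_mask
    if kspace.shape[:2] != acq.shape:
        raise ValueError("kspace frame/PE dimensions disagree with plan")

    # decouple readout columns
    hyb = cifft(kspace, axis=-1)
    msk = acq[..., None]
    d = hyb * msk

    baseline = None
    if cfg.baseline_subtract:
        baseline = _temporal_baseline(d, acq)
        d = (d - baseline[None]) * msk

    weights = init_weights(
        d, plan.acs_mask, cfg.weight_power, cfg.weight_floor_rel
    )
    power = np.mean(np.abs(d[acq]) ** 2) if acq.any() else 0.0
    lam = cfg.lambda_rel * power

    def forward(rho):
        return xf_to_kt(rho) * msk

    def adjoint(y):
        return kt_to_xf(y * msk)

    rho, state = focuss_iterate(
        d, forward, adjoint, weights, lam,
        outer_iters=cfg.outer_iters, cg_tol=cfg.cg_tol,
        cg_max_iters=cfg.cg_max_iters, weight_power=cfg.weight_power,
        weight_floor_rel=cfg.weight_floor_rel, dot_axes=(0, 1),
    )
    hyb_recon = xf_to_kt(rho)
    if baseline is not None:
        hyb_recon = hyb_recon + baseline[None]
    raw = cfft(hyb_recon, axis=-1)

    if fill == "lattice":
        fill_mask = plan.uniform_mask | plan.acs_mask[None, :]
    else:
        fill_mask = np.ones_like(acq)
    out = np.where(fill_mask[..., None], raw, 0)
    out = np.where(msk, kspace, out)  # hard data consistency

    if return_raw:
        return out, state, raw
    return out, state
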