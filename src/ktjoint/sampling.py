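"""Tailored k-t undersampling: uniform lattice, Gaussian random subset, ACS.

The acquisition is decoupled into two operators applied in sequence: a uniform
(lattice) undersampling of the phase-encode direction with reduction factor
``r1`` — the structured pattern a GRAPPA-type parallel-imaging step needs —
and, within those lattice lines, a frame-varying random subset with reduction
factor ``r2`` drawn from a zero-mean Gaussian density over line position — the
incoherent pattern a compressed-sensing step needs.  A block of ``n_acs``
fully sampled auto-calibration (ACS) lines at the k-space center is acquired
in every frame, both to calibrate the parallel-imaging kernel and to
initialize the compressed-sensing weights.

Line indexing is 0-based with the PE center line at ``n_pe // 2`` (the DC line
of the centered-DFT convention in :mod:`ktjoint.core`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingPlan",
    "make_uniform_mask",
    "make_random_subset",
    "make_acs_mask",
    "compose_acquired",
    "net_reduction_factor",
    "apply_mask",
    "make_sampling_plan",
    "save_plan",
    "load_plan",
    "save_plan_group",
    "load_plan_group",
]


def make_uniform_mask(
    n_pe: int, n_frames: int, r1: int, offset_mode: str = "fixed"
) -> np.ndarray:
    """Uniform lattice mask: every ``r1``-th PE line, per frame.

    ``fixed`` uses offset 0 in all frames (the default: a frame-invariant
    lattice is what the stage-2 kernel calibration assumes); ``interleaved``
    shifts the offset by ``frame % r1``.
    """
    r1 = int(r1)
    if r1 < 1 or r1 > n_pe:
        raise ValueError(f"r1 must satisfy 1 <= r1 <= n_pe; got {r1}")
    if offset_mode not in ("fixed", "interleaved"):
        raise ValueError(f"unknown offset_mode {offset_mode!r}")
    lines = np.arange(n_pe)
    mask = np.zeros((n_frames, n_pe), dtype=bool)
    for t in range(n_frames):
        offset = 0 if offset_mode == "fixed" else t % r1
        mask[t] = (lines - offset) % r1 == 0
    return mask


def _gaussian_probs(candidates: np.ndarray, n_pe: int, density_sigma: float) -> np.ndarray:
    center = n_pe // 2
    sigma = density_sigma * n_pe
    logp = -0.5 * ((candidates - center) / sigma) ** 2
    p = np.exp(logp - logp.max())
    return p / p.sum()


def make_random_subset(
    uniform_mask: np.ndarray,
    r2: float,
    density_sigma: float,
    seed: int,
    force_center: bool = True,
) -> np.ndarray:
    """Frame-varying random subset of the uniform lattice lines.

    Per frame, ``round(U / r2)`` of the ``U`` lattice lines are kept, drawn
    without replacement with inclusion probability proportional to a zero-mean
    Gaussian in (line - center) with standard deviation
    ``density_sigma * n_pe`` — a variable density that tapers toward outer
    k-space.  Systematic (stratified-CDF) sampling is used so the marginal
    inclusion probabilities match the renormalized density exactly.  The
    lattice line closest to the PE center is always kept so the DC component
    of every frame is observed.  Reproducible: frame ``t`` uses ``seed + t``.
    """
    if r2 < 1:
        raise ValueError(f"r2 must be >= 1; got {r2}")
    if density_sigma <= 0:
        raise ValueError("density_sigma must be > 0")
    uniform_mask = np.asarray(uniform_mask, dtype=bool)
    n_frames, n_pe = uniform_mask.shape
    center = n_pe // 2
    out = np.zeros_like(uniform_mask)
    for t in range(n_frames):
        candidates = np.flatnonzero(uniform_mask[t])
        n_u = candidates.size
        n_keep = int(round(n_u / r2))
        if n_keep > n_u:
            raise ValueError(f"requested {n_keep} lines but only {n_u} available")
        if n_keep == n_u:
            out[t] = uniform_mask[t]
            continue
        if n_keep == 0:
            continue
        rng = np.random.default_rng(seed + t)
        p = _gaussian_probs(candidates, n_pe, density_sigma)
        if force_center:
            # the center-most lattice line is always acquired; the remaining
            # n_keep-1 lines are drawn from the renormalized density, so all
            # inclusion probabilities stay proportional to the Gaussian
            ci = int(np.argmin(np.abs(candidates - center)))
            others = np.delete(candidates, ci)
            p_others = np.delete(p, ci)
            p_others = p_others / p_others.sum()
            chosen = _systematic_sample(others, p_others, n_keep - 1, rng)
            chosen = np.append(chosen, candidates[ci])
        else:
            chosen = _systematic_sample(candidates, p, n_keep, rng)
        out[t, chosen] = True
    return out


def _systematic_sample(
    candidates: np.ndarray, p: np.ndarray, n_keep: int, rng: np.random.Generator
) -> np.ndarray:
    """Systematic sampling: inclusion probability min(n_keep * p_i, 1)."""
    w = n_keep * p
    c = np.cumsum(w)
    c[-1] = n_keep  # guard rounding
    u = rng.uniform(0.0, 1.0)
    points = u + np.arange(n_keep)
    idx = np.searchsorted(c, points, side="left")
    idx = np.unique(np.clip(idx, 0, candidates.size - 1))
    # duplicates only arise if some w_i > 1 (very peaked density); top up with
    # the highest-probability unselected candidates
    while idx.size < n_keep:
        remaining = np.setdiff1d(np.arange(candidates.size), idx)
        extra = remaining[np.argsort(p[remaining])[::-1][: n_keep - idx.size]]
        idx = np.union1d(idx, extra)
    return candidates[idx]


def make_acs_mask(n_pe: int, n_acs: int) -> np.ndarray:
    """Boolean PE vector: ``n_acs`` contiguous lines centered on ``n_pe//2``."""
    if n_acs < 0 or n_acs > n_pe:
        raise ValueError(f"n_acs must satisfy 0 <= n_acs <= n_pe; got {n_acs}")
    mask = np.zeros(n_pe, dtype=bool)
    if n_acs:
        start = n_pe // 2 - n_acs // 2
        mask[start : start + n_acs] = True
    return mask


def compose_acquired(random_mask: np.ndarray, acs_mask: np.ndarray) -> np.ndarray:
    """Acquired set per frame: random subset OR the ACS block (all frames)."""
    random_mask = np.asarray(random_mask, dtype=bool)
    acs_mask = np.asarray(acs_mask, dtype=bool)
    if random_mask.shape[1] != acs_mask.shape[0]:
        raise ValueError("mask PE dimensions disagree")
    return random_mask | acs_mask[None, :]


def net_reduction_factor(n_pe: int, r1: float, r2: float, n_acs: int) -> float:
    """Net acceleration R = n_pe / (n_pe/(r1*r2) + n_acs).

    ACS lines count as additional acquisitions; no overlap deduction is made.
    """
    if n_pe < 1:
        raise ValueError("n_pe must be >= 1")
    if r1 * r2 < 1:
        raise ValueError("r1*r2 must be >= 1")
    if n_acs < 0:
        raise ValueError("n_acs must be >= 0")
    denom = n_pe / (r1 * r2) + n_acs
    if denom <= 0:
        raise ValueError("degenerate reduction-factor denominator")
    return n_pe / denom


def apply_mask(kspace: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero-fill k-t data outside the mask (acquired lines kept bit-identical).

    ``kspace`` is ``[..., frame, ky, kx]``; ``mask`` is ``[frame, ky]``.
    """
    kspace = np.asarray(kspace)
    mask = np.asarray(mask, dtype=bool)
    if kspace.shape[-3] != mask.shape[0] or kspace.shape[-2] != mask.shape[1]:
        raise ValueError(
            f"mask shape {mask.shape} incompatible with kspace shape {kspace.shape}"
        )
    return np.where(mask[..., :, :, None], kspace, 0)


@dataclass
class SamplingPlan:
    """The full decoupled k-t sampling scheme.

    Holds the uniform lattice mask (M_u), the random-subset mask (M_r M_u),
    the ACS vector, and the parameters that generated them.
    """

    n_pe: int
    n_fe: int
    n_frames: int
    r1: int
    r2: float
    n_acs: int
    uniform_mask: np.ndarray
    random_mask: np.ndarray
    acs_mask: np.ndarray
    seed: int = 0
    density_sigma: float = 0.25
    offset_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.random_mask.shape != self.uniform_mask.shape:
            raise ValueError("random_mask and uniform_mask shapes differ")
        if np.any(self.random_mask & ~self.uniform_mask):
            raise ValueError("random subset must lie within the uniform lattice")

    @property
    def acquired_mask(self) -> np.ndarray:
        """Boolean [frame, ky]: random subset OR ACS (ACS in every frame)."""
        return compose_acquired(self.random_mask, self.acs_mask)

    @property
    def net_r(self) -> float:
        return net_reduction_factor(self.n_pe, self.r1, self.r2, self.n_acs)

    def lines_per_frame(self) -> np.ndarray:
        return self.acquired_mask.sum(axis=1)


def make_sampling_plan(
    n_pe: int,
    n_fe: int,
    n_frames: int,
    r1: int,
    r2: float,
    n_acs: int,
    seed: int = 0,
    density_sigma: float = 0.25,
    offset_mode: str = "fixed",
) -> SamplingPlan:
    """Build the complete plan: lattice, Gaussian random subset, ACS block."""
    uniform = make_uniform_mask(n_pe, n_frames, r1, offset_mode)
    random = make_random_subset(uniform, r2, density_sigma, seed)
    acs = make_acs_mask(n_pe, n_acs)
    return SamplingPlan(
        n_pe=n_pe,
        n_fe=n_fe,
        n_frames=n_frames,
        r1=int(r1),
        r2=float(r2),
        n_acs=int(n_acs),
        uniform_mask=uniform,
        random_mask=random,
        acs_mask=acs,
        seed=int(seed),
        density_sigma=float(density_sigma),
        offset_mode=offset_mode,
    )


# ---------------------------------------------------------------------------
# HDF5 persistence


def save_plan_group(h5, plan: SamplingPlan) -> None:
    h5.create_dataset("uniform_mask", data=plan.uniform_mask.astype(np.uint8))
    h5.create_dataset("random_mask", data=plan.random_mask.astype(np.uint8))
    h5.create_dataset("acs_mask", data=plan.acs_mask.astype(np.uint8))
    for key in ("r1", "r2", "n_acs", "seed", "density_sigma", "n_fe"):
        h5.attrs[key] = getattr(plan, key)
    h5.attrs["offset_mode"] = plan.offset_mode


def load_plan_group(h5) -> SamplingPlan:
    uniform = h5["uniform_mask"][()].astype(bool)
    random = h5["random_mask"][()].astype(bool)
    acs = h5["acs_mask"][()].astype(bool)
    n_frames, n_pe = uniform.shape
    return SamplingPlan(
        n_pe=n_pe,
        n_fe=int(h5.attrs.get("n_fe", n_pe)),
        n_frames=n_frames,
        r1=int(h5.attrs["r1"]),
        r2=float(h5.attrs["r2"]),
        n_acs=int(h5.attrs["n_acs"]),
        uniform_mask=uniform,
        random_mask=random,
        acs_mask=acs,
        seed=int(h5.attrs.get("seed", 0)),
        density_sigma=float(h5.attrs.get("density_sigma", 0.25)),
        offset_mode=str(h5.attrs.get("offset_mode", "fixed")),
    )


def save_plan(path, plan: SamplingPlan) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        save_plan_group(f, plan)


def load_plan(path) -> SamplingPlan:
    import h5py

    with h5py.File(path, "r") as f:
        return load_plan_group(f)
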