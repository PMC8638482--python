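# Methods

This note records the model implemented by `ktjoint`, the numerical choices
behind it, and what the synthetic experiments do and do not demonstrate.

## Sampling model

The acquisition operator is a composition `M_r · M_u` applied to the fully
sampled k-t data: `M_u` keeps every R₁-th phase-encode line (the same lattice
in every frame, offset 0, so the stage-2 kernel sees one geometry;
an `interleaved` mode that shifts the lattice per frame exists for
experimentation but is rejected by the kernel stage), and `M_r` keeps, per
frame independently, `round(U/R₂)` of the `U` lattice lines. In addition the
`n_acs` center lines are acquired in every frame. Line indexing is 0-based
with the DC line at `n_pe // 2`, matching the centered-DFT convention used
throughout.

The random subset is drawn with inclusion probability proportional to a
zero-mean Gaussian in (line − center) with standard deviation
`density_sigma · n_pe` (default `density_sigma = 0.25`), renormalized over
the frame's lattice lines. Two refinements:

* **Systematic (stratified-CDF) sampling** is used instead of sequential
  without-replacement draws. Sequential sampling distorts marginal inclusion
  probabilities when more than one line is kept; systematic sampling keeps
  them exactly `min(n·p_i, 1)`, which is what the Monte-Carlo histogram test
  verifies.
* **The center-most lattice line is always acquired** so every frame observes
  the x-f DC component (the FOCUSS weight initialization needs low-frequency
  content). Rather than forcing it post hoc — which would skew neighboring
  lines' frequencies — the center is included deterministically and the
  remaining `n−1` lines are drawn from the renormalized density, so all other
  inclusion probabilities remain proportional to the Gaussian.

Frame `t` uses seed `seed + t`; identical parameters and seed reproduce masks
bit-identically.

The net reduction factor is reported as
`R = n_pe / (n_pe/(R₁R₂) + n_acs)`, with ACS lines counted as additional
acquisitions and no overlap deduction, even though the acquired mask itself
is the union (which can overlap). A consequence worth noting: because the
random subset can overlap the ACS block by a data-dependent amount, the
*acquired-line count* of the union is only monotone in R₁, R₂ in expectation;
the randomly drawn count itself is deterministic and monotone.

## Stage 1: k-t FOCUSS

Per coil, the readout axis is inverse-transformed first, decoupling the
problem into independent (phase-encode × frame) subproblems per readout
column; all columns are solved simultaneously by a batched solver. In the
x-f domain the recovery problem is `min ‖ρ‖₁ s.t. ‖d − Fρ‖ ≤ ε` with F the
unitary centered transform x-f → k-t restricted to acquired samples. FOCUSS
parametrizes ρ = W q and alternates:

1. ridge solve `min_q ‖d − FWq‖² + λ‖q‖²`, computed in the dual
   (measurement) domain: conjugate gradients on
   `(F W² Fᴴ + λI) y = d`, then `ρ = W² Fᴴ y`. The dual system is Hermitian
   positive definite and has the dimension of the acquired data. Each outer
   solve is warm-started from the previous dual solution.
2. weight update `W ← diag(max(|ρ|^p, floor))` with `p = 0.5` (the ℓ₁
   target).

Weights are initialized from the ACS-only low-resolution x-f image, the
standard FOCUSS initialization; an empty ACS block raises with guidance to
supply uniform weights instead.

Defaults (all exposed in `FocussConfig`): 2 reweightings after
initialization, `cg_max_iters = 40`, `cg_tol = 1e-6`,
`λ = 0.01 ×` mean acquired power, `weight_floor = 1e-4 ×` max weight,
`weight_power = 0.5`. These are ordinary values for FOCUSS-type solvers;
the small-scale recovery benchmarks use a more aggressive schedule
(30 reweightings, floor 1e-8, λ ≈ 0) because they chase exact sparse
recovery rather than a good image under noise.

Two details that matter:

* **Divergence monitoring.** The per-solve objective `‖d−FWq‖² + λ‖q‖²` is
  not comparable across reweightings (W changes its meaning), and the data
  residual alone may legitimately rise as the iteration trades fidelity for
  sparsity. The quantity the reweighting provably decreases (by the
  majorize–minimize argument for IRLS with p = 0.5, up to the weight floor)
  is `‖d − Fρ‖² + 2λ‖ρ‖₁`; the solver tracks it and returns the best iterate
  with a warning if it ever increases by more than 1%.
* **Monotonicity within CG.** CG on the dual system is monotone in the error
  energy norm of that system, which does not strictly imply monotonicity of
  the mapped primal objective at every iterate; in practice it holds, and the
  test asserts it with a small (1e-8 relative) slack on a well-conditioned
  instance.

After the final solve, ρ is transformed back to k-t. The output is assembled
with hard data consistency: measured samples verbatim, reconstructed values
on the uniform lattice (plus ACS), zeros elsewhere — the remaining lines are
stage 2's job. The constrained ε-form is realized as the Lagrangian plus this
final override, since ε is a free parameter of the formulation. The CS-only
baseline uses the same solver with the fill region widened to all of k-space.
An optional `baseline_subtract` flag removes the temporal-average k-space
(estimated from acquired samples) before solving and restores it afterwards —
the classic temporal-DC-removed variant — and is off by default.

## Scaling normalization

The hand-off assumes `d_recon = β · d_acq` with one complex β per frame *and
per coil* (coil gains differ; the per-coil granularity strictly generalizes a
per-frame-only scale and reduces the residual). β is the least-squares fit
`⟨acq, recon⟩/‖acq‖²` over the overlap, taken as all acquired locations.
Because the stage-1 output already overrides acquired samples with
measurements, β is estimated from the *pre-override* model prediction against
the acquired data — otherwise it would be identically 1 and the normalization
vacuous. The reconstructed-only lattice samples are then divided by β;
measured samples are never touched. Normalizing twice is a no-op (the
re-estimated β is 1 to within 1e-10, which is tested).

## Stage 2: nonlinear GRAPPA

Each missing line `ky + r` (r = 1..R₁−1, base `ky` on the lattice) of every
frame and coil is predicted as a truncated second-order polynomial of the
source samples `S_l(ky + bR₁, kx + h)` over all coils l, blocks b = B₁..B₂
and columns h = H₁..H₂: a constant, all first-order terms, their squares, and
products of same-line samples one and two columns apart. Feature count
`1 + 2LBH + LB(H−1) + LB(H−2)`; default geometry b = −1..2, h = −2..2
(4 blocks × 5 columns — typical GRAPPA choices), giving 273 features for
4 coils.

Calibration slides the target over the ACS block jointly over all frames
(a per-frame-kernel option exists), restricted to lattice-aligned bases
(`base % R₁ == 0`) and interior readout columns so the calibration equations
use exactly the geometry the kernel is applied with and contain no
zero-filled samples. One stacked least-squares problem per target offset
solves for all target coils at once. Features are rms-normalized before the
solve to condition the second-order block (the scales are folded back into
the returned weights), and a Tikhonov term `reg_rel ×` mean normal-matrix
diagonal (default 1e-6) regularizes it; `reg_rel = 0` is allowed and fails
loudly on rank deficiency. With the second-order groups disabled the method
reduces to conventional linear GRAPPA (verified against an independent dense
implementation).

At application, sources clipped outside k-space are zero-filled by default
(`edge_mode="zero"`); `"strict"` raises instead. Measured ACS lines overwrite
predictions, so the output is bit-identical to the input at every acquired
location.

## Synthetic data

The phantom emulates a short-axis cine series on an `ny × nx` grid
(default 128 × 128, 12 frames, 2 cardiac cycles): a piecewise-smooth torso
ellipse with static lungs, chest-wall ribs, spine and small vessels; an inner
ventricle disc whose radius varies as `base · (1 + amp · sin(2π·cycles·t/T))`
(defaults 0.18 and 0.25 of the field of view) with a blood pool whose
brightness pulses in phase and two papillary-muscle dots orbiting inside it;
and a smooth nonzero phase map. Edges are sigmoid-softened at about one
pixel. Setting the contraction amplitude to zero freezes the cardiac phase
entirely, so the series is exactly static. All time dependence runs through
the cyclic phase, so frames repeat exactly after one cycle and single-voxel
time courses contain only harmonics of the cycle frequency.

Coil sensitivities are Gaussian magnitude lobes (σ ≈ 0.9 of the half-FOV,
with small seeded jitter) centered around the FOV perimeter with a gentle
linear phase ramp per coil, divided pointwise by their root-sum-of-squares so
RSS ≡ 1; a single coil degenerates to the uniform map. The lobes are broad
enough to be smooth (high-frequency energy is checked with a Hann-windowed
spectral accounting, since the maps are not FOV-periodic) yet localized
enough to carry real spatial encoding — flatter maps degrade the
parallel-imaging stage measurably.

Acquisition multiplies the phantom by each sensitivity, takes the unitary
2-D DFT per frame, adds i.i.d. complex Gaussian noise in k-space with
standard deviation `noise_sigma_rel × max|k|` (default 5e-4, about 30 dB
image-domain SNR for the default phantom — noise in k-space and image domain
are equivalent under the unitary transform), and applies the acquired mask.
The fully sampled noisy k-space is kept as the reference.

What the phantom does *not* model: MR relaxation and steady-state contrast,
off-resonance/banding, respiratory motion, through-plane motion, and
realistic coil coupling/noise correlation. Passing tests therefore
demonstrate the correctness and relative behavior of the reconstruction
machinery under controlled conditions, not clinical image quality.

## Experiments and problem sizes

The end-to-end comparison runs the proposed method, the coil-wise CS-only
baseline and zero-filling on the default 128 × 128 × 12 × 4 phantom with
r1 = 2, r2 = 2, 24 ACS lines — all three on the same acquired mask, so the
net reduction factor is matched by construction — and compares frame-mean
NMSE medians over 5 phantom seeds in the test suite (3 seeds in the
acceptance script). The sweep harnesses re-mask a fully sampled synthetic
dataset for several (r1, r2) splits at fixed ACS count, or several
(r1, r2, n_acs) combinations at fixed net R (validated within 0.05), and
tabulate per-frame NMSE; which split wins is data-dependent, so orderings
are logged rather than asserted. Test fixtures use 48 × 48 and 64 × 64 grids;
these sizes keep the full suite at a few minutes while leaving every code
path exercised at the default scale somewhere.

## Known limitations

* The FOCUSS defaults favor robustness over exact sparse recovery; on
  noiseless exactly-sparse instances the aggressive schedule above is needed
  to reach the ℓ₁ solution.
* The kernel stage requires the ACS block to contain the full source span
  `(B₂−B₁)·R₁ + 1` lines; small ACS blocks with large R₁ are rejected rather
  than silently extrapolated.
* β-normalization assumes a single complex scale per (frame, coil); line- or
  position-dependent mismatch is out of scope.
* The interleaved lattice mode is incompatible with the (frame-invariant)
  kernel stage and exists only for studying the CS stage.
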