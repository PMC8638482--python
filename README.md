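# ktjoint

Joint compressed-sensing + nonlinear-GRAPPA reconstruction of accelerated
dynamic cardiac (cine) MRI.

## The problem

Dynamic cardiac MRI needs both high spatial and high temporal resolution, but
k-space can only be traversed so fast: cine acquisitions are routinely
undersampled well below the Nyquist rate and reconstructed by exploiting
redundancy. Two complementary families do this: **compressed sensing (CS)**
leverages the sparsity of the image series in the x–f (space × temporal
frequency) domain under incoherent sampling, and **parallel imaging (PI)**
leverages the spatial encoding of a multi-coil receive array under uniform
lattice sampling. Their sampling requirements conflict, so naive combinations
cannot push both to their limits.

`ktjoint` implements a decoupled two-stage framework for multi-coil Cartesian
k-t data, together with the tailored sampling scheme it requires:

1. **Sampling.** The phase-encode direction is undersampled on a uniform
   lattice with reduction factor R₁ (the PI pattern); within the lattice, a
   frame-varying random subset with reduction factor R₂ is drawn from a
   zero-mean Gaussian density over line position (the CS pattern); a block of
   n_acs fully sampled auto-calibration (ACS) lines at the k-space center is
   acquired in every frame. The net acceleration is

       R = n_pe / ( n_pe / (R₁·R₂) + n_acs ).

2. **Stage 1 — k-t FOCUSS.** Per coil, the random subset is "inverted": the
   x–f image ρ is recovered by approximating

       min ‖ρ‖₁  s.t.  ‖d − Fρ‖₂ ≤ ε

   with iteratively reweighted ℓ₂ minimization. Writing ρ = W q with diagonal
   W, each reweighting solves `min_q ‖d − FWq‖² + λ‖q‖²` via conjugate
   gradients and updates W ← diag(|ρ|^½). This restores the uniform lattice.

3. **Normalization.** The reconstructed and measured k-space are matched by a
   per-frame, per-coil complex scale β estimated by least squares over their
   overlap (d_recon = β·d_acq).

4. **Stage 2 — nonlinear GRAPPA.** The lines missing from the lattice are
   interpolated by a truncated second-order polynomial of neighboring
   acquired samples across all coils (constant + linear terms + squares +
   cross-column products), calibrated on the ACS block by Tikhonov-regularized
   least squares.

5. **Combination and metrics.** Root-sum-of-squares coil combination;
   per-frame normalized mean-square error NMSE = ‖I_ref − I_rec‖²/‖I_ref‖²
   over a region of interest; x-t temporal profiles.

A coil-wise CS-only baseline (FOCUSS on the full acquired mask, no lattice
completion) and plain zero-filling are included for comparison, plus sweep
harnesses over (R₁, R₂) splits and ACS counts at fixed net R. Because no
public raw datasets accompany the method, the package ships a synthetic
beating-heart cine phantom with smooth complex coil sensitivities and a
k-space noise model, so every stage is testable end to end.

## Worked example

```python
import ktjoint as kj

spec = kj.PhantomSpec(seed=0)          # 128 x 128, 12 frames, 4 coils
data, plan, truth, sens = kj.make_default_dataset(spec, r1=2, r2=2, n_acs=24, seed=0)

model = kj.KTJointModel(data, plan, method="proposed")
results = model.fit()
print(results.summary())
```

prints

```
k-t joint reconstruction results
========================================
method:            proposed
data:              4 coils, 12 frames, 128 x 128
sampling:          r1=2, r2=2, n_acs=24, sigma=0.25
net reduction R:   2.286
acquired lines/fr: 46.1 of 128
runtime:           9.11 s
scaling beta:      |beta| in [0.9976, 0.9987], median residual 7.124e-03
kernel:            273 features, calib residual 2.328e-02
NMSE vs reference: mean 3.5318e-04 (min 3.3435e-04, max 3.7121e-04)
```

Reading this: 46 of 128 phase-encode lines per frame were acquired (net
R ≈ 2.29 by the accounting above); the stage-1/stage-2 hand-off was almost
perfectly scaled (|β| ≈ 1); the 273-feature second-order kernel calibrated to
a 2.3% relative residual on the ACS lines; and the reconstruction differs
from the fully sampled reference by a frame-mean NMSE of 3.5e-4 — compared
with about 4.0e-4 for the coil-wise CS-only baseline and 1.9e-3 for
zero-filling on the same acquired data (`method="cs_only"` /
`method="zero_filled"`).

`results.nmse()`, `results.temporal_profile(col)`, `results.beta_table` and
`results.kernel` expose the per-frame metrics and stage diagnostics;
`ktjoint.sweep_acceleration` / `ktjoint.sweep_acs` run the matched-net-R
parameter sweeps. A `ktjoint` command-line interface wraps the same
functionality (`ktjoint simulate|mask|recon|evaluate|sweep --help`).

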