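# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `mrcprecon`, and what the package's tests do and do not
establish about real data.

## Forward model and conventions

All reconstructions share one linear forward model per 2-D slice,
`y = Ex + n`, where `x` is the complex image, `y` the multicoil k-space
samples, and `E` applies coil sensitivities, a 2-D Fourier transform, and
the sampling pattern.  Conventions, fixed globally:

- **FFT**: centered (DC at the grid center) and orthonormal, so Parseval's
  identity holds exactly and regularization weights transfer across grid
  sizes.
- **Mask**: a phase-encode line selector applied symmetrically on the
  forward and adjoint sides (projection form), so the normal operator
  `EᴴE` depends only on measured lines.  With root-sum-of-squares-normalized
  maps, `‖E‖ ≤ 1`, which keeps every inner CG solve well conditioned.
- **Indexing**: 0-based; the ACS block is the half-open centered range
  `[n_pe//2 − n_acs//2, n_pe//2 + n_acs//2)`; equidistant grids are anchored
  so the central (DC) line is always sampled, as scanners do.  Retrospective
  undersampling keeps every extra-th grid line (anchored at the center) plus
  the full ACS block, so higher-R masks nest inside lower-R ones exactly.

3-D Cartesian volumes fully sampled along the slice direction are converted
to independent 2-D problems by an inverse FFT along slices.  Volume-wise
normalization divides a slice stack by the maximum magnitude of its
zero-filled root-sum-of-squares reconstruction; the statistic is a design
choice (any volume-wise scalar would do) picked because it is deterministic
and makes image intensities — and therefore regularization weights and
network activations — comparable across volumes.

## Calibration

**ESPIRiT.**  The sliding-window calibration matrix is built from the
central fully sampled block (default 24×24, kernel 5×5); right-singular
vectors with singular value ≥ 0.02·σ_max span the signal subspace, are
transformed to image space, and the per-pixel dominant eigenvector of the
resulting operator is the sensitivity map.  Maps keep unit per-pixel norm
over the whole FOV — the background is deliberately *not* cropped to zero —
and the per-pixel phase is referenced to the first coil, which makes
repeated estimations bit-identical (one map set is estimated per dataset and
shared by all reconstructions of that dataset).  The singular-value cutoff
and the no-crop choice are configurable.

**GRAPPA.**  Missing lines are interpolated from 4 sampled neighbor lines ×
5 readout columns across all coils; weights are fit by least squares over
ACS sliding windows with a small Tikhonov term (τ = 1e-12 × mean diagonal of
the Gram matrix — a pure numerical stabilizer; planted-kernel tests pin the
solve to 1e-8 accuracy, which a larger τ would visibly bias).  Window
positions are aligned with the equidistant grid parity (`acs_phase`), i.e.
the fit uses exactly the source/target geometry later used for filling;
boundary sources outside the grid contribute zero.  Measured lines always
pass through unchanged, so GRAPPA output is data-consistent by construction.

## Classical reconstructions

**CG-SENSE** solves `(EᴴE + λI)x = Eᴴy` by conjugate gradients from zero
(default λ = 0.01 on volume-normalized data, 30 iterations, relative
tolerance 1e-6).  The solver records both the residual norm and the
quadratic objective per iterate; the objective is the quantity CG decreases
monotonically (residual norms can oscillate on well-conditioned systems, and
do — tests assert monotonicity on the objective).

**Wavelet CS** solves `min ‖y − Ex‖² + λ‖Wx‖₁` by FISTA (default λ = 0.008,
60 iterations, step 1/L with L from power iteration) with an orthogonal
Daubechies-4 transform, 4 periodized levels, on an internally zero-padded
grid when the image side is not a multiple of 16; all coefficients including
the coarse scale are soft-thresholded (this makes the single-coil
closed-form oracle exact).  The protocol this package follows describes the
penalty as "ℓ2-wavelet" while citing the sparsity-promoting CS framework;
both readings are implemented (`penalty="l1" | "l2"`, ℓ1 default) and the
discrepancy is surfaced here rather than silently resolved.  For orthogonal
W the ℓ2 variant reduces to Tikhonov regularization.

## Unrolled reconstruction

The network alternates, for a fixed number of unrolls (default 12),

1. a residual CNN `N_θ` on the 2-channel (real, imaginary) image — input
   projection, `n_blocks` residual blocks (two 3×3 convolutions + ReLU,
   block output scaled by 0.1 before the skip), output projection, global
   skip; all-zero weights give exactly the identity;
2. a data-consistency step `x ← (EᴴE + λI)⁻¹(Eᴴy + λN_θ(x))`, solved by CG
   warm-started at `N_θ(x)` (default 10 inner iterations).

Weights are shared across unrolls (parameter count independent of unroll
count) and `λ` is a single scalar trained jointly with θ, stored as its
logarithm so positivity is structural (initialized at 0.05).  A per-unroll
λ is a straightforward extension but the default follows the single-scalar
reading.  The backbone internals (64 channels, 8 blocks by default, ReLU,
He initialization) are configurable; physics stays in native complex
arithmetic and only the denoiser sees the 2-channel real representation.

**Gradients.**  The package implements exact backpropagation through the
CNN and *implicit* differentiation through each data-consistency solve: the
gradient of the solve's output w.r.t. its inputs requires one additional CG
solve with the same operator (`(EᴴE+λI)⁻¹` applied to the incoming
gradient), which is exact in the limit of converged inner CG and is the
standard treatment for CG blocks inside unrolled networks.  With truncated
inner CG the gradient is approximate; finite-difference tests therefore pin
exactness in settings where CG converges (unitary or small dense problems),
and training-level tests assert loss descent rather than gradient equality.
Networks run in float32 by default (float64 in gradient tests).

## Training

Both strategies minimize the normalized ℓ1–ℓ2 k-space loss
`‖u−v‖₂/‖u‖₂ + ‖u−v‖₁/‖u‖₁` with Adam (lr 3e-4, batch = one slice, global
gradient-norm clipping at 1.0), seeded end to end (one master seed fans out
to initialization, shuffling, and split streams).

- **Supervised**: the reference image is the coil-combined GRAPPA
  reconstruction of a moderately accelerated (R = 2) acquisition; the loss
  compares full-grid per-coil k-space of reference and output (full-grid
  comparison uses all reference information; comparing on a subset is a
  configuration away but not the default).
- **SSDU (self-supervised)**: the measured lines Ω of each example are split
  into disjoint Θ (fed to the reconstruction) and Λ (held out for the loss);
  Λ is drawn without replacement from the non-ACS measured lines with 1-D
  Gaussian probability centered on k-space center (default ρ = |Λ|/|Ω∖ACS| =
  0.4, σ = n_pe/4 — values from the SSDU methodology class, exposed in
  config), the ACS block always stays in Θ, and a fresh split is drawn every
  epoch (seeded) to reduce split-selection bias.  The reconstruction
  structurally cannot read Λ samples; a test asserts bit-identical output
  when Λ data is zeroed.

## Synthetic data

The generator emulates what matters for reconstruction physics, not sequence
physics:

- **Phantom**: bright curvilinear "ducts" (random-walk centerlines with a
  ~1.2-px Gaussian cross-section, peak intensity ≈ 1) over a dim elliptical
  body (intensity 0.08, soft edge), plus a smooth random phase — the
  high-contrast sparse geometry of heavily T2-weighted duct imaging.  The
  duct/background mean-contrast contract (≥ 5×) is tested.
- **Coils**: smooth Gaussian lobes on a ring with low-order polynomial
  phase, RSS-normalized — body/spine array-class encoding (6–36 coils
  supported).
- **Noise**: i.i.d. complex Gaussian per sample per coil on sampled lines
  only (the standard thermal-noise model).  σ = 0.02 per component (duct
  SNR ≈ 50 in the combined image) stands in for the high-field regime;
  σ = 0.08 for the low-field one.  Field strength is emulated *only* through
  noise level — no relaxation, echo-train, triggering, or motion modeling.

Consequently, passing tests show the algorithms are implemented correctly
and that the training strategies work on data obeying the stated forward
model; they do not certify performance on in-vivo data with motion,
sequence-specific contrast, imperfect coil estimates at scale, or anatomy
far from the phantom distribution.

## The end-to-end benchmark

`mrcprecon.experiment.run_benchmark` is the study design in miniature, sized
for a single CPU core: 200 phantom slices (64×64, 8 coils, one shared coil
geometry per dataset) acquired at R = 2 with 16 ACS lines and σ = 0.02
noise; volume-normalized; ESPIRiT maps (16×16 calibration — the block cannot
exceed the 16 available ACS lines) estimated once and shared; GRAPPA
references built per slice; inputs retrospectively undersampled to R = 4.
The last 20 slices are held out.  Both models use 4 unrolls, 2 residual
blocks, 32 channels, 6 inner DC iterations, and train for 10 epochs — sizes
chosen so the complete experiment (two trainings plus evaluation) runs in
roughly 13 minutes; the reported orderings are stable well before the loss
fully plateaus.  Held-out PSNR/SSIM are computed against the known phantom
ground truth (reconstructions are rescaled by the stored normalization
factor first), and one-sided Wilcoxon tests compare the trained models
against the baselines.

## Known limitations

- 1-D (phase-encode) Cartesian acceleration and slice-by-slice 2-D
  reconstruction only; no 2-D CAIPI-style undersampling, non-Cartesian
  trajectories, partial Fourier, or true 3-D regularization.
- The ISMRMRD-style HDF5 dialect is a minimal subset written and read by
  this package (XML header with matrix sizes and acceleration, one compound
  record per acquired line); it mirrors the standard's organization but is
  not a drop-in reader for arbitrary scanner exports.
- Single-map ESPIRiT only is consumed downstream; multi-set (soft-SENSE)
  reconstruction is out of scope.
- The CPU NumPy training loop is adequate for the benchmark scale; training
  paper-scale volumes (hundreds of 384×480 slices, 12 unrolls, 8 blocks,
  64 channels) would require a GPU framework.
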