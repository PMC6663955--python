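# Methods

This note documents the models, numerical choices and limitations behind
`spectenh`. It states how quantities are computed; every number quoted as a
result elsewhere (README, tests) is produced by the code at run time.

## Problem setting

In hepatic radioembolization, a ⁹⁹ᵐTc-MAA SPECT/CT scan taken before
treatment is used to estimate the lung shunting fraction (LSF) — the
fraction of hepatic activity that shunts to the lungs, a safety-critical
quantity — and to detect extrahepatic depositions. Iterative reconstruction
with full physics modelling (attenuation, collimator response, scatter)
gives the best images but is slow; filtered back projection (FBP) is
instant but artefact-ridden. The package implements the accelerated
reconstruction scheme in which FBP output is upgraded by a trained
image-enhancement CNN, together with the reference reconstructions and
evaluation metrics needed to judge it — all at "desk scale" on synthetic
data, since no patient data is used.

## Digital phantoms (`spectenh.phantom`)

**Torso phantom.** An anthropomorphic torso is modelled with an elliptical
body (soft-tissue attenuation), two lung ellipsoids, a liver ellipsoid, and
five spheres: 2.0 / 4.1 / 8.1 mL extrahepatic spheres at uptake ratio 2.7
against the liver background, a 15.7 mL solid sphere and an 18.7 mL sphere
with a 5.6 mL cold core inside the liver at ratio 7.7. Lungs receive
uniform activity such that LSF = lung / (lung + liver-region) equals the
configured 5.2 %, and the volume is rescaled to 157 MBq total. The
ellipsoid geometry and the attenuation values (0.015 /mm soft tissue,
0.004 /mm lung, appropriate for 140 keV photons) are package choices — the
physical phantom this emulates specifies its activity configuration, not a
voxelized geometry — and everything is exposed in `TorsoPhantomSpec`.

Grids are isotropic; the desk default is 64³ at 7.8 mm (the clinical-matrix
variant, 128³ at 3.9 mm, spans the same ~50 cm extent). Masks are stored as
a single disjoint integer label volume with a JSON role table.

**Synthetic training volumes.** New liver activity distributions are
composed by repeatedly stamping spheres of random diameter at random
in-liver locations and filling each with a same-shape activity patch copied
from a *different* donor volume, until every liver voxel has been visited
(later spheres overwrite earlier ones; patch voxels that fall outside the
donor's liver contribute zero). The canonical diameter range is 7–20 pixels
on the 3.9 mm grid; on coarser grids the experiment driver rescales the
range so the physical sphere sizes (27–78 mm) are preserved. Volumes are
rescaled to 150 MBq.

Two departures from the minimal reading are deliberate:

* donor libraries are randomized torso phantoms with a smooth
  multiplicative liver texture (±35 %, 2.5-voxel correlation length), so
  patches are heterogeneous the way reconstructed patient livers are;
* synthetic volumes inherit the donor's lungs and receive uniform lung
  activity at an LSF drawn from a configurable range (default 2–10 %).
  Without a lung compartment the headline LSF evaluation would be vacuous
  on held-out synthetic volumes. Set `lung_lsf_range=None` for liver-only
  volumes.

## Analytic system model (`spectenh.projector`)

A rotation-based parallel-hole projector. For each of `n_angles` (default
120 over 360°, single head) the volume is resampled into the detector frame
by a precomputed sparse bilinear rotation operator, applied in its
*push* (mass-conserving) form; each voxel is attenuated by
exp(−∫μ dl) along the ray to the detector (half-voxel + cumulative sum
rule); each constant-depth plane is blurred with the depth-dependent
collimator PSF σ(d) = σ₀ + slope·d (defaults σ₀ = 1.6 mm, slope = 0.017,
detector radius 250 mm — a LEHR-like response of ≈3.8 mm intrinsic and
≈7 mm FWHM at 20 cm); rays are summed and scaled by sensitivity × scan
time. Sensitivity defaults to 3 counts/(MBq·s), sized so the default torso
phantom at 20 min yields ≈5×10⁶ photopeak counts after attenuation — a
typical clinical order of magnitude; absolute count levels of the original
acquisitions are not published, so this is a calibration choice.

Every factor of the forward operator (sparse rotation, diagonal
attenuation, symmetric zero-padded Gaussian convolution, ray sum) has an
exact matrix transpose, so `backward` is the exact adjoint of `forward` —
verified to ~1e-16 in the tests. This is the property OSEM's multiplicative
update relies on. Boundary conventions matter for exactness: PSF blurring
uses zero-padded (constant) boundaries, which keep the convolution matrix
symmetric.

**Scatter** is an effective model replacing Monte Carlo photon transport
(declared out of scope): S = f × (primary ⊛ G) with scatter-to-primary
fraction f = 0.3 and an 80 mm FWHM Gaussian G per projection, applied with
wrap-around boundaries so counts are conserved exactly. The photopeak
window receives primary + S; the lower energy window (108–129 keV metadata)
receives S itself, i.e. under this model the scatter window is a perfect
estimate of photopeak scatter, and the dual-energy-window k factor
downstream expresses the *assumed* relation. Noise is Poisson per bin,
seeded; shorter scans are simulated either by re-projecting at a smaller
scan time or by binomial thinning of recorded counts (exact for Poisson
data; 20 min → 5 min is fraction 0.25).

## FBP (`spectenh.recon_fbp`)

Ramp filtering is done per projection row with the band-limited ramp
kernel in closed form (h(0) = 1/4d², h(n) = −1/π²n²d² for odd n), embedded
in an 8×-length FFT so circular wrap-around is negligible; the residual DC
leakage of the truncated kernel is removed by zeroing the zero-frequency
bin. Back-projection uses the projector's adjoint with attenuation and PSF
disabled, scaled by π/n_angles and the discretization/count calibration
d²/(sensitivity·time)², which makes total activity of a non-attenuated
phantom correct to a few percent. First-order Chang attenuation correction
divides each voxel by its angle-averaged survival factor; the average is
normalized by the rotation operator's resampling support so the correction
is exactly 1 where μ = 0. A 5 mm FWHM Gaussian post-filter is applied and
negatives are clipped (activity is non-negative and the LSF metric assumes
non-negative values). Scatter is *not* corrected — FBP is deliberately the
fast, approximate method whose output the network upgrades. Its absolute
calibration is consequently biased high by the scatter fraction; all
comparisons use activity-normalized metrics.

## OSEM references (`spectenh.recon_osem`)

Standard ordered-subsets EM, x ← x · AᵀS[y_S/(A_S x + s_S + ε)] / A_Sᵀ1,
subsets interleaving the angle set (balanced angular coverage), uniform
scale-correct initialization, ε = 1e−10 × max(y). Scatter enters the
denominator additively — the standard placement that preserves
non-negativity and count statistics. Two presets:

* **MC mode** (`reconstruct_mc`): attenuation + PSF + the simulator's own
  scatter operator recomputed from the current estimate each subset;
  10 iterations × 8 subsets, no post-filter. Because the data were
  generated with the same scatter model, this commits an inverse crime *on
  purpose*: it makes the mode the best-possible reference, mirroring the
  role a validated Monte Carlo reconstructor plays clinically (where the
  reference reconstructor also generated the simulation data it was judged
  on).
* **CLINIC mode** (`reconstruct_clinic`): attenuation + PSF +
  dual-energy-window scatter correction — the lower-window counts smoothed
  with a 5 mm FWHM Gaussian and scaled by k = 0.5 — plus a 5 mm post-filter;
  10 × 8 as well. With the effective scatter model the lower window holds
  the true scatter, so k = 0.5 systematically undercorrects by half — an
  intentional imperfection standing in for the approximations of clinical
  scatter correction.

## Training data (`spectenh.trainset`)

The central data-generation idea is the *reconstruct-then-re-project*
scheme: a reference volume (a full-model OSEM reconstruction of original
projections, or a synthetic volume built from such references) is declared
ground truth, re-projected through the simulator with scatter and fresh
Poisson noise at the target scan time, and FBP-reconstructed; the network
trains from those FBP slices to the ground-truth slices. Because the input
is derived from the target itself, the mapping is self-consistent — unlike
pairing FBP of the raw projections with an iterative reconstruction of the
same projections (`direct_pairs`, retained as the ablation arm, which the
tests show trains worse).

Samples are 5 adjacent axial slices (channel-stacked) against the central
ground-truth slice; edge slices replicate the boundary slice so a volume
with n slices yields n pairs (optionally strided for desk-scale budgets).
Both input and target are divided by the *input* volume's total activity
× 10⁻³ — one constant per volume, chosen from the input because ground
truth totals are unavailable at inference, and inverted after enhancement.
Per-volume noise streams derive from (master seed, volume index) via
`numpy.random.SeedSequence`, so datasets are bit-reproducible and
individual volumes can be regenerated independently.

## Enhancement network (`spectenh.enhancer`, `spectenh.nn`)

A 2-D encoder-decoder with concatenation skips: per resolution scale two
3×3 convolutions with ReLU and 2×2 max pooling; the decoder upsamples by
nearest-neighbour followed by convolution (checkerboard-safe),
concatenates the matching encoder output, and applies two 3×3
convolutions; a linear 1×1 projection emits the central slice. Channels
double per scale from `base_channels`. The desk default is 3 scales ×
base 16 (~120k parameters); the reference clinical-scale configuration
would use base 64. Channel widths and depth are capacity choices — the
contribution is the pipeline, not a specific capacity.

The network, its backward passes and the Adam optimizer are implemented
directly in NumPy (float32). Convolutions are evaluated in channels-last
layout either as an im2col GEMM (narrow input) or as one full-grid product
with the (C, 9F) weight matrix plus nine shifted-slice additions (narrow
output), whichever moves less memory; both paths are verified against a
float64 loop reference in the tests. He-normal initialization under a
seed; pooling ties split gradients evenly (deterministic backward).

Training minimizes voxel-wise MSE with Adam at learning rate 1e−4 and
early-stops when the validation loss has not improved for a patience
window (reference patience 20 epochs; desk default 5); the weights of the
minimum-validation-loss epoch are returned, and that minimum is the
network-performance measure used by the ablations. Separate networks are
trained per scan time. Inference enhances all slices of a volume and clips
negatives. The desk experiments use batch 8 rather than the batch-128
reference: with the learning rate fixed, parameter movement is bounded by
the Adam step count, and smaller batches give proportionally more steps
per CPU-second.

## Metrics (`spectenh.metrics`)

* `mse_normalized`: mean over voxels of (r/Σr − g/Σg)², × n_voxels² — a
  fixed display scaling that brings typical desk-scale values to order
  1–50. Scale-invariant in each argument, symmetric, zero iff the
  normalized volumes agree.
* `lsf`: 100 × lung / (lung + liver region), the liver region including
  intrahepatic spheres and cold cores (total hepatic activity — the
  radioembolization convention; the denominator choice is not universal
  and is therefore documented here).
* `uptake_ratio`: mean sphere voxel value / mean liver-background value,
  the background excluding a 2-voxel dilation margin around every sphere
  to limit partial-volume contamination.
* `cnr`: (mean_sphere − mean_background) / population SD of the
  background. Using the background SD (not a noise SD from repeated
  scans) is a definitional choice, stated here because published CNR
  values depend on it.
* `compare_methods`: two-sided Mann-Whitney U via
  `scipy.stats.mannwhitneyu`, exact for ≤8 cases per group without ties,
  normal approximation with tie correction otherwise; all-tied input
  returns p = 1 with a warning.

## Experiment driver and problem sizes

`run_experiment` chains donor generation → synthetic volumes → (optional)
ground-truth reconstruction → training pairs → network training →
evaluation, with all randomness derived from one master seed through fixed
keys, so reruns are bit-identical. Two ground-truth conventions are
supported: `gt_mode="phantom"` (the digital volumes are truth — used for
the headline LSF check, where a true distribution exists by construction)
and `gt_mode="mc_recon"` (the full-model OSEM reconstruction of original
noisy projections is declared truth — the clinical situation, used for the
four-method comparison).

Problem sizes were chosen once for single-CPU runtimes and are not tuned
to outcomes:

* `scripts/acceptance.py` headline run: 64³ grid, 60 angles, 40 synthetic
  training + 5 held-out volumes, every second slice as a training sample,
  batch 8, ≤8 epochs (patience 5).
* test suite pipelines: 32³ grid at 15.6 mm with 48 angles (≈ the π/2 ×
  matrix fully-sampled count at that matrix), 10–12 training volumes,
  ≤18–30 epochs; the ablation tests use 24 angles and ≤6–8 epochs since
  they compare networks against networks.

## What the synthetic study does and does not show

The generator emulates: liver-like heterogeneous activity with hepatic and
extrahepatic lesions and a lung shunt; attenuation; depth-dependent
collimator blur; a broad scatter haze with a populated lower energy
window; Poisson statistics at 20- and 5-minute scan times. It does not
emulate: real photon transport (energy spectra, septal penetration,
detector energy resolution), patient anatomy beyond ellipsoids, motion, or
reconstruction model mismatch — the OSEM references use the very operators
that generated the data. Passing tests therefore demonstrate the internal
consistency and the claimed orderings of the pipeline under its own
physics, not clinical performance.

Two results deserve explicit caveats:

* The headline LSF agreement (within 2 pp of ground truth after
  enhancement) transfers the clinically relevant claim to desk scale and
  passes with large margin — but on data whose scatter and resolution
  degradations the network has seen in distribution.
* At desk scale the enhanced FBP does **not** reach the quality of the
  iterative references: the measured ordering is MSE(MC) ≤ MSE(CLINIC) ≪
  MSE(CNN) < MSE(FBP), with the network's validation loss fully plateaued.
  Reaching reference quality took the original study roughly 10 h of GPU
  training on ~10⁵ samples with a wider network; a single-CPU build
  affords about two orders of magnitude fewer optimizer steps. The
  corresponding acceptance test asserts the reference ordering and is
  expected to fail on the CNN-vs-CLINIC link; the enhancement-improves-FBP
  property (the method's raison d'être) holds and is tested separately.

## Numerical details and edge cases

* Rotation operators are cached per (grid, angle set, PSF geometry);
  the transpose pair makes back-projection exact. 90°-multiple angles are
  exact permutations, which the brute-force projection oracle exploits.
* Chang factors are clipped to ≥1 implicitly by survival ≤ 1; the
  angle-average is support-normalized so air (μ=0) is untouched.
* OSEM guards empty rays with ε and returns a zero volume (with a
  warning) for all-zero data; voxels with zero sensitivity stay zero.
* `sphere_mask` claims the containing voxel for sub-voxel spheres, so
  masks are never empty for in-grid centers.
* Training aborts with a diagnostic if the loss goes non-finite
  (learning-rate/normalization hint). Early stopping guarantees at least
  patience + 1 epochs when any improvement occurred.
* All public randomness is seeded; seeds derived from a master seed stay
  below 2³¹.

## Known limitations

* The projector's bilinear rotation limits ray-level accuracy to ~0.5 %
  against continuous ray marching (second-order in voxel size); tolerances
  in the oracle tests reflect this.
* The effective scatter model has no object dependence beyond the primary
  distribution itself; DEW correction is therefore exactly half-right by
  construction (k = 0.5 on a perfect scatter estimate).
* FBP's absolute activity calibration is biased by the uncorrected
  scatter fraction; only normalized metrics are meaningful across methods.
* The NumPy network trains at roughly 1–2 s per batch-8 step at 64×64;
  this bounds desk-scale capacity studies. The implementation is exact
  (verified against float64 references) but not competitive with GPU
  frameworks in speed.
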