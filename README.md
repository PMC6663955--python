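# spectenh

Accelerated SPECT reconstruction for hepatic radioembolization, at desk
scale: fast filtered back projection (FBP) whose output is upgraded by an
image-enhancement convolutional neural network, evaluated against
full-model and clinical-style iterative (OSEM) reconstructions with the
quantitative measures that matter in the radioembolization workflow.

## The problem

Before radioembolization of liver tumours, a ⁹⁹ᵐTc-MAA SPECT/CT scan is
used to estimate the **lung shunting fraction** (LSF) — the percentage of
hepatic activity shunting to the lungs, a safety limit — and to detect
extrahepatic depositions. Reconstruction with full physics modelling
(attenuation μ-map, depth-dependent collimator response, scatter) gives
the best images but takes minutes to hours; FBP takes seconds but is
artefact-ridden and quantitatively biased. The accelerated scheme
implemented here reconstructs with FBP and passes the result through an
encoder-decoder CNN trained to restore reference-quality images:

* **training pairs** come from a *reconstruct-then-re-project* scheme —
  a reference volume is declared ground truth, re-projected through the
  simulator with scatter and Poisson noise, and FBP-reconstructed; the
  network maps five adjacent FBP slices to the central ground-truth slice;
* **training data is augmented** with synthetic volumes composed by
  stamping spheres (random diameter, canonical 7–20 px at 3.9 mm voxels)
  filled with activity patches copied from *other* volumes, until the
  liver mask is covered;
* training uses Adam (learning rate 1e-4), voxel-wise MSE, and early
  stopping on the validation loss (best-epoch weights kept).

Everything runs on synthetic data generated by the package itself: an
anthropomorphic digital torso phantom (liver, lungs at LSF 5.2 %,
2.0/4.1/8.1 mL extrahepatic spheres at uptake ratio 2.7, a 15.7 mL solid
and an 18.7/5.6 mL cold-core sphere at ratio 7.7, 157 MBq total), an
analytic projector with attenuation, LEHR-like PSF, an effective
two-window scatter model and Poisson noise, and OSEM references
(10 iterations × 8 subsets; "MC" full-model mode and "CLINIC" mode with
dual-energy-window scatter correction at k = 0.5 and 5 mm post-filter).
See `docs/methods.md` for models, defaults and limitations.

## Worked example

Build the torso phantom, simulate a 20-minute scan, reconstruct, and read
the radioembolization metrics:

```python
from spectenh import (
    DetectorConfig, TorsoPhantomSpec, make_torso_phantom,
    forward_project, add_scatter, add_poisson,
    fbp_reconstruct, reconstruct_mc, reconstruct_clinic,
    lsf, uptake_ratio,
)

ps = make_torso_phantom(TorsoPhantomSpec())        # 64^3 desk grid
cfg = DetectorConfig()                    # 120 angles, 20-min scan
proj = add_poisson(add_scatter(forward_project(ps.activity, ps.mu, cfg), cfg), seed=1)

fbp = fbp_reconstruct(proj, ps.mu, cfg)
mc = reconstruct_mc(proj, ps.mu, cfg)
clinic = reconstruct_clinic(proj, ps.mu, cfg)

bg = ps.masks.background_mask()
solid = ps.masks.sphere_masks(inside_liver=True)["sphere_0"]
print(f"true LSF 5.20 | fbp {lsf(fbp, ps.masks):.2f}"
      f" clinic {lsf(clinic, ps.masks):.2f} mc {lsf(mc, ps.masks):.2f}")
print(f"uptake (true 7.7): fbp {uptake_ratio(fbp, solid, bg):.2f}"
      f" clinic {uptake_ratio(clinic, solid, bg):.2f}"
      f" mc {uptake_ratio(mc, solid, bg):.2f}")
```

prints (seed 1):

```
true LSF 5.20 | fbp 5.21 clinic 5.01 mc 5.03
uptake (true 7.7): fbp 4.64 clinic 6.46 mc 6.86
```

FBP overestimates the LSF slightly and crushes lesion contrast (4.64 of a
true 7.7 — partial volume plus unmodelled scatter and resolution); the
model-based reconstructions recover most of the contrast, with the
full-model mode closest to the truth. The enhancement network is trained
and applied end-to-end by the experiment driver:

```bash
spectenh experiment --seed 1 --grid-n 64 --n-train 40 --n-val 5 --out runs/demo
```

which generates a donor library, synthetic training volumes, re-projection
training pairs, trains the network, and reports per-volume normalized MSE
and LSF differences for FBP and the CNN on held-out volumes. Individual
stages (`phantom`, `simulate`, `recon-fbp`, `recon-osem`, `make-trainset`,
`train`, `enhance`, `evaluate`) are available as subcommands; volumes
travel as NIfTI with JSON sidecars.

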