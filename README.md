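# edemaseg

Subcutaneous edema segmentation on abdominal CT slices.

Edema — fluid retention from kidney, heart or liver disease — shows up on CT
as heterogeneous near-water densities (~0 HU) scattered through the
subcutaneous fat, which is otherwise homogeneous at ~-100 HU. Unlike a tumor
or an organ, edema is discontinuous and diffuse, which makes both manual
annotation and supervised learning hard. This package segments it from
densities alone, given a CT slice and a binary mask of the subcutaneous
adipose compartment, and measures its volume.

Two methods are implemented:

- **`gmm`** — the intensity-only baseline: a two-component 1-D Gaussian
  mixture (adipose vs edema densities) fitted by EM; voxels are labelled by
  maximum posterior.
- **`cv_prior`** — a Chan-Vese level set with an adipose density prior. The
  contour is the zero level set of a signed distance function φ (φ ≥ 0 =
  edema) minimizing

  ```
  E = Σ (I − C1)² H(φ) + [(I − C2)² + α·F] (1 − H(φ)) + β |∇H(φ)|
  ```

  where C1/C2 are the region mean densities and F compares the density
  histogram of the evolving adipose region (φ < 0) with an edema-free
  adipose prior via normalized correlation (F = 1 − corr by default). F stays
  near 0 while the background is clean adipose and rises when edema
  contaminates it, driving the contour until the two tissues are separated —
  which is what lets small, isolated edema foci survive where a pure
  intensity rule blurs them. Minimization alternates closed-form mean
  updates with explicit steps of

  ```
  ∂φ/∂t = δ(φ) [ −(I−C1)² + (I−C2)² + α·F + β·div(∇φ/|∇φ|) ]
  ```

The edema-free prior is a pluggable interface; the default is a Gaussian
surrogate fitted on edema-free (binary, grayscale) mask pairs, and an adapter
accepts masks from an externally trained mask-to-texture network. Seeded
synthetic phantoms (adipose ring + edema blobs + noise, with exact ground
truth) and IoU/DSC/AVD/RVD evaluation round out the toolkit.

## Worked example

```python
from edemaseg import (PhantomSpec, generate_phantom, generate_training_pairs,
                      fit_prior, run_segmentation, fit_gmm_em,
                      classify_edema_gmm, apply_mask, compute_metrics)

spec = PhantomSpec()                                  # 256x256 phantom slice
prior = fit_prior(generate_training_pairs(spec, 10, seed=7))
sample = generate_phantom(spec, seed=42)

mask, trace = run_segmentation(sample.image, sample.adipose_mask, prior)
rep = compute_metrics([mask], [sample.edema_mask],
                      spec.pixel_spacing, spec.slice_thickness)
print(f"level set: DSC {rep.dsc_pct:.1f}%  IoU {rep.iou_pct:.1f}%  "
      f"AVD {rep.avd_liters*1000:.3f} mL  ({trace['iterations']} iterations)")

gmm = fit_gmm_em(apply_mask(sample.image, sample.adipose_mask).masked_values())
rep_g = compute_metrics([classify_edema_gmm(sample.image, sample.adipose_mask, gmm)],
                        [sample.edema_mask], spec.pixel_spacing, spec.slice_thickness)
print(f"GMM baseline: DSC {rep_g.dsc_pct:.1f}%  "
      f"(means {gmm.mu_adipose:.1f} / {gmm.mu_edema:.1f} HU)")
```

prints

```
level set: DSC 99.7%  IoU 99.4%  AVD 0.000 mL  (3 iterations)
GMM baseline: DSC 99.8%  (means -100.1 / -1.0 HU)
```

i.e. both methods recover the phantom's edema almost perfectly — fat and
fluid densities are well separated by construction — and the fitted mixture
means sit at the generating densities (-100 / 0 HU). On any single phantom
either method can edge ahead; averaged over the seeded 20-phantom suite the
prior-constrained level set scores higher (it removes the isolated
noise-flipped voxels the intensity-only baseline keeps), which is the
standing regression asserted in `tests/test_acceptance.py` and recomputed by
the acceptance script below.

The same workflow is available from the shell:

```sh
edemaseg phantom --n 5 --seed 1 --out phantoms/
edemaseg fit-prior --n 10 --seed 7 --out prior.json
edemaseg segment-cv --image phantoms/sample000_image.nii.gz \
    --mask phantoms/sample000_adipose.nii.gz --prior prior.json \
    --out edema.nii.gz --trace trace.csv
edemaseg evaluate --pred pred/ --ref ref/ --out report.json
```

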