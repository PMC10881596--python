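# Methods

## Problem and model

Subcutaneous edema appears on abdominal CT as heterogeneous, discontinuous
regions of near-water density (around 0 HU) diffused through the
subcutaneous adipose compartment, which is otherwise homogeneous and strongly
negative (around -100 HU). Given a CT slice and a binary mask of the
subcutaneous adipose compartment, the package separates edema from adipose
tissue two ways:

1. **Two-class GMM baseline.** The in-compartment density distribution is
   modelled as a two-component 1-D Gaussian mixture fitted by EM; a voxel is
   edema when the posterior of the higher-mean (near-water) component reaches
   0.5. Purely intensity-based, no spatial coupling.

2. **Prior-constrained Chan-Vese level set.** The contour is the zero level
   set of a signed distance function `phi` (phi >= 0 = edema). The energy is

   ```
   E = sum_support (I - C1)^2 H(phi)
       + [ (I - C2)^2 + alpha * F ] (1 - H(phi))
       + beta * |grad H(phi)|
   ```

   with `C1`, `C2` the mean densities inside/outside the contour and `F` a
   density-prior constraint: the evolving adipose region (`phi < 0`) is
   binned into a histogram and compared with the histogram of an edema-free
   adipose reference through normalized (Pearson) correlation of the count
   vectors. In the default `dissimilarity` mode `F = 1 - corr`, which is 0
   when the background is pure adipose and grows as edema contaminates it,
   pushing the contour to keep expanding until edema is separated out. A
   `literal_correlation` mode exposing the raw correlation is selectable,
   because the two readings of the constraint's sign cannot be reconciled
   from first principles; the dissimilarity form is the one whose
   minimum/maximum behaviour matches the intended dynamics. Minimization
   alternates closed-form mean updates with explicit gradient steps of

   ```
   dphi/dt = delta(phi) [ -(I-C1)^2 + (I-C2)^2 + alpha*F + beta*kappa ]
   ```

   where `kappa = div(grad phi / |grad phi|)` is the curvature
   (length-shortening) force.

## The edema-free reference

In a full clinical pipeline the edema-free grayscale reference would be
produced by a mask-to-texture generative model trained on edema-free
patients, with the adipose mask coming from an upstream segmentation network.
Both are out of scope here: the adipose mask is an input, and the reference
is a pluggable `PriorMaskGenerator` interface. The default implementation is
a *statistical surrogate*: a Gaussian adipose density model (mean, std,
pooled histogram) fitted on edema-free (binary, grayscale) mask pairs, used
either as a fitted histogram directly or to fill a mask with i.i.d. draws.
An `ExternalMaskAdapter` lets a trained network slot in without code change.

## Discretization and numerical choices

- **Sharp vs smoothed Heaviside.** `phi` is maintained as a signed distance
  field whose magnitude reaches the compartment half-width (~30 px), and the
  adipose region is an order of magnitude larger than the edema region.
  Weighting region statistics with a smoothed arctan Heaviside of width
  `eps = 1.5` lets its slowly decaying tails bleed the far adipose region
  into `C1` (on the default phantom, `C1` lands near -63 HU instead of ~0),
  which drags the effective decision threshold and produces a halo of false
  positives around every edema focus. Region means, the background histogram
  and the energy therefore use the **sharp** Heaviside (`H(phi)=1` iff
  `phi >= 0`, ties inside); the smoothed pair `H_eps` / `delta_eps`
  (`delta_eps(z) = (eps/pi)/(eps^2+z^2)`) is kept for the evolution equation,
  where a sharp delta would act nowhere. With sharp weights the mean updates
  exactly minimize the data terms for fixed `phi`.
- **Forces and step size.** The data forces are squared HU residuals
  (~10^4), so `beta` carries HU^2 scale: default `beta = 0.5 * (100 HU)^2 =
  5000`, which makes the curvature force comparable to the data force for
  structures a few pixels across (removing isolated noise voxels) yet
  negligible on blob-scale boundaries. `dt = 0.4` with the self-limiting
  arctan delta: voxels near the interface move decisively, far voxels barely
  move, and periodic reinitialization (every 20 iterations, via the Euclidean
  distance transform) restores the unit-slope distance field.
- **Prior force.** `F` is recomputed every iteration from the current
  `phi < 0` region and applied as a spatially uniform scalar (the constraint
  has no spatial argument), weight `alpha = 50` against `F in [0, 2]`.
  Histograms use 64 bins over [-200, 100] HU with out-of-range values
  clipped into the end bins. A zero-variance background histogram yields
  `F = 0` with a warning; an empty background terminates the evolution
  (contour vanished).
- **Initialization.** Default seed is the [-50, 50] HU annotation window
  intersected with the adipose mask (deterministic and needs no fitted
  mixture); GMM-label and checkerboard seeds are selectable, and an empty
  seed falls back to the checkerboard. `phi` outside the adipose mask is
  clamped to minus the grid diagonal and frozen: all sums, histograms and
  updates are restricted to the support so that the zero background of a
  grayscale mask can never poison `C2` or the histograms.
- **Stopping.** Convergence when the fraction of support voxels whose sign
  changed in one step falls below 1e-4, else at 300 iterations. Checkpoint
  energies are recorded on freshly reinitialized fields (with re-optimized
  means), so successive checkpoints are comparable.
- **GMM baseline.** Deterministic median-split initialization; collapse
  guards `sigma_floor = 0.5 HU`, `w_floor = 0.01`; per-iteration
  log-likelihood monotonicity asserted; components returned ordered so the
  edema mean exceeds the adipose mean. MAP (posterior 0.5) is the declared
  classification rule.

## Synthetic phantoms

Real annotated edema CT is not redistributable, so correctness is
demonstrated on phantoms with exact ground truth: a 256x256 slice with an
annular adipose compartment (radii 80/110 px, Normal(-100, 15) HU),
`edema_blob_count = 4` blobs (unions of three jittered discs, radii 5-12 px,
rejection-placed inside the ring) with densities Normal(0, 15) truncated to
the [-50, 50] HU annotation window, additive Normal(0, 5) acquisition noise,
1x1 mm pixels, 5 mm slices. Blob count and radii are the package's own
choice of a multifocal-edema analogue; the density parameters keep fat and
fluid separated the way the mixture model assumes. One seed feeds a named
sub-stream per sample, so suites grow without perturbing earlier samples.
Paired fixtures that differ only by added small isolated blobs (radii 2-4 px,
shared ring/noise draws) support the check that the density prior never loses
isolated foci relative to the prior-free configuration.

What the phantoms deliberately omit: organs, bone, skin, contrast phases,
beam hardening and motion artifacts, partial-volume mixing at boundaries,
spatially correlated noise, and the irregular, low-contrast edema margins of
real patients. Passing the phantom suite therefore shows the machinery is
implemented correctly and that the prior helps under the stated density
model; it does not certify clinical accuracy, and the phantom metric levels
(DSC near 100%) are far above what real scans yield.

## Evaluation

IoU and DSC are pooled over all voxels of a scan and reported in percent;
AVD is the absolute predicted-vs-reference volume difference in liters
(voxel count x pixel area x slice thickness, mm^3 -> 1e-6 L); RVD is AVD over
the reference volume in percent, undefined (reported as missing) for an
empty reference. Multi-scan summaries average per-scan values. The
reference-annotation operation reproduces the automatable stages of the
manual protocol — the [-50, 50] HU window inside the adipose mask — and not
the subsequent manual edits. `scripts/acceptance.py` regenerates a
20-phantom suite from a seed and reports mean IoU/DSC/AVD/RVD for both
methods; problem sizes (20 phantoms of 256x256, 10 training pairs) are the
package's default desk-scale study conditions.

## Known limitations

- 2D per-slice evolution only; stacks are combined, not coupled in 3D.
- The statistical surrogate is unimodal Gaussian; real adipose texture is
  spatially correlated and mildly skewed.
- The uniform scalar prior force cannot act differentially across disjoint
  background regions; a regional variant is a possible extension.
- The energy is non-convex and the outcome depends on the seed contour: the
  default threshold seed (and the GMM seed) start near the basin of the
  intended fat/fluid split, whereas the uninformed checkerboard fallback can
  settle in a poor local minimum that partitions the adipose bulk against
  itself. Checkerboard is a last resort, not a recommended mode.
- With well-separated phantom densities the baseline is already strong, so
  the prior's measured margin is small; its qualitative role (keeping the
  contour expanding while the background histogram is contaminated) is
  exercised by the paired small-blob fixtures.
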