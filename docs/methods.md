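# Methods

`hepaseg` implements an end-to-end pipeline for automatic liver lesion
segmentation in the late hepatocellular phase of dynamic contrast-enhanced
liver MRI, together with the evaluation machinery needed to judge such
segmentations against several disagreeing human raters. Clinical image data
of this kind cannot be redistributed, so the package ships a synthetic
phantom generator that reproduces the properties the pipeline actually
depends on; every stage is testable end to end on phantoms.

## Image model and preprocessing

Input volumes are 3D scalar images indexed `(x, y, z)` with anisotropic
voxels: in-plane resolutions around 0.74–1.76 mm and slice spacings of
2–5 mm. MRI gray values carry no absolute scale and differ between scanners
and protocols.

Preprocessing addresses both properties:

* **In-plane resampling to 1 mm** (linear for the image, nearest-neighbor
  for masks). The slice axis is never resampled — with 2–5 mm slices,
  through-plane interpolation would smear small lesions. The final voxel
  size is therefore `1 × 1 × z` mm with `z` the original slice spacing. The
  resampled grid keeps the world origin and rounds the new shape half-up;
  both choices are arbitrary but deterministic.
* **Percentile normalization**: the 2nd and 98th gray-value percentiles,
  measured inside the liver mask, are mapped linearly to 0 and 1. Values
  outside that interval are *not* clipped — extreme values stay
  informative. Percentiles use linear interpolation between order
  statistics (numpy's default; the dominant convention). The fitted affine
  map is applied to the whole volume, not only the liver, because training
  patches include non-liver context. Normalization is fitted *after*
  resampling; the order is configurable but fitting on the grid the network
  sees is the natural default. A constant liver region (degenerate
  percentiles) is a hard error — such a case cannot be normalized.

## Augmentation

Served patches are augmented on the fly with three transforms, freshly
drawn per patch: axis flips (probability 0.5 per axis, applied identically
to image, label and weight), contrast rescaling about the patch mean with
`a ~ U[0.75, 1.25)`, and a mean shift `b ~ N(0, 0.25)`:
`v' = m + a (v − m) + b`. The "gray-value mean" is the per-patch mean — the
only scope available at augmentation time. Labels and weights are never
intensity-transformed.

## The anisotropic U-Net

The network is a five-level encoder–decoder with **valid (unpadded)
convolutions only**: 3×3×1 kernels in-plane, 2×2×1 max pooling, 2×2×1
transposed-convolution upsampling, batch normalization + ReLU after every
convolution except the final 1×1×1 output convolution, dropout (rate 0.1)
after the bottleneck, and a single-channel sigmoid output. Skip connections
center-crop the encoder feature map before concatenation. Because no
convolution pads, an input patch shrinks by a fixed symmetric margin: the
default geometry maps a 236×236×72 input to a 52×52×32 output — a margin of
92×92×20 voxels per side. The margin depends only on the architecture, not
the input extent, which is what makes tiled whole-volume inference exact
(tiles agree bit-for-bit with any other tiling on shared voxels, up to
float tolerance).

Through-plane information enters via 1×1×3 convolutions at the three
lowest-resolution levels only, mirroring how a radiologist reads thick-slice
data: mostly in-plane, with a few adjacent slices. The z-margin budget pins
their number exactly: the slice axis is never pooled, each valid 1×1×3
convolution consumes two slices, and the 72→32 reduction requires twenty
such convolutions on the bottleneck path. Five blocks on that path carry
them (encoder levels 3 and 4, the bottleneck, decoder levels 4 and 3), so
each of a block's two in-plane convolutions is followed by a stack of two
1×1×3 convolutions: 5 × 2 × 2 = 20. The stacked pair acts like a separable
1×1×5 kernel at a fraction of the parameters.

Per-level feature counts default to a doubling series from 32 capped at 512
and are configurable (including an explicit per-level override used by the
reduced-width configurations below); the testable geometry is independent
of widths. The anisotropic network has fewer parameters than the
corresponding full-3D (all 3×3×3) variant — about 59 % at default widths.

The layers themselves (valid conv3d, fused batch-norm+ReLU, max pooling,
transposed convolution, dropout) and their backward passes are implemented
in the package on numpy with numba kernels; weights use Glorot-uniform
initialization, so differently seeded networks differ only through their
initialization stream. Batch-norm running statistics use an exponential
moving average with momentum 0.9 so that inference-mode statistics track
the batch statistics closely even in short trainings.

## Training

Training is a binary voxel task (lesion vs. everything else, liver
parenchyma included) with the Dice loss computed **within a dilated liver
mask** only (per-slice disk of radius 5 voxels, ±1 slice; the dilation
keeps the liver-border context that post-processing later targets). The
smoothing constant is 1.0. Patches are sampled so that 90 % contain at
least one lesion voxel and 10 % at least one liver voxel, enforced as a
deterministic 9:1 cycle; the containment requirement applies to the
loss-contributing output region, not the input margin (a lesion visible
only in the margin contributes nothing to the loss). Cases without lesions
fall back to liver-biased sampling. Input windows are read with mirror
padding at volume borders.

The optimizer is Adam (default learning rate 1e-4, standard moments,
batch size 2). Every 500 iterations (and at the end of every training
segment) the model is validated: full-volume tiled predictions on the
validation cases, binarized at 0.5 within the undilated liver mask, scored
with the Jaccard coefficient and averaged over cases. The parameter state
with the highest validation Jaccard is kept; ties resolve to the earliest
iteration.

## Multi-model training (successive halving)

Deep-network training is not repeatable across seeds. To avoid shipping an
unlucky model, a fixed successive-halving bracket trains 16 differently
seeded models and halves the field at 5k, 10k, 20k and 40k iterations by
validation Jaccard measured at the shared milestone (equal budget per
competitor; ties prefer the lower run id). The survivor trains to 80k. The
bracket totals 240k iterations — exactly 3× one 80k training. No
hyper-parameters are searched; this is a fixed bracket, not the full
bandit-over-brackets scheme. Run state (optimizer moments, sampler state)
persists across stages, i.e. survivors resume rather than restart. Runs
are executed sequentially and are independent between milestones, so the
`workers` parameter can never change results; it exists for interface
compatibility. A run hitting a non-finite loss is recorded as failed and
eliminated at the next selection.

## Post-processing

The raw probability map is restricted to the liver mask and thresholded at
0.5 (strictly greater; the boundary convention is documented and fixed).
Thin false positives where dark structures touch the liver are removed
morphologically: the liver is eroded with a 7×7 per-slice square kernel,
the border band is liver minus erosion, and the tumor mask inside the band
is opened with a 3×3 per-slice square. Kernels are 2D per-slice squares —
the kernels are specified with two dimensions, and with 2–5 mm slices a 2D
reading keeps the physical scale sensible. Interior tumor voxels are never
modified; the operation never adds voxels and is idempotent.

## Evaluation

**Segmentation.** Dice against each rater, the mean across raters, and the
mean pairwise inter-rater Dice yield the uncertainty-aware score
`phi = max(1 − alpha · eps_hat / eps_bar, 0)` with
`eps_hat = 1 − mean(D(A, R_i))` and `eps_bar = 1 − mean(D(R_i, R_j))`. At
`alpha = 0.1`, `phi ≥ 0.9` marks performance as good as a human rater given
the observed inter-rater disagreement. `phi` is computed per case and
averaged (it is undefined for a case whose raters agree perfectly, or with
a single rater; such cases are flagged rather than scored). Summaries
average per-case values.

**Detection.** Lesions are connected components under 6-connectivity (face
connectivity — the strictest standard choice, applied package-wide).
Reference and predicted components are clustered into N:M correspondences
to tolerate split/merged instances. The matcher maximizes the mean
per-correspondence Dice, where a correspondence's Dice is computed on the
union of its members' voxels and components left unmatched enter the mean
as zero-Dice singletons (without that term the optimum would trivially
unmatch every weak pair). The algorithm starts from the connected
components of the full overlap graph and greedily removes the edge whose
removal most increases the objective; on small instances (≤ 8 components)
it attains the exhaustive optimum over all edge subsets, which the test
suite asserts on 100 random instances. A correspondence with Dice > 0.2 is
one true positive; below-threshold correspondences count one false positive
plus one false negative; unmatched components count accordingly. Degenerate
conventions: no positive calls → precision 1; no reference lesions →
recall 1. FPC (false positives per case) is summarized by the median.

**Statistics.** Paired comparisons use the two-sided Wilcoxon signed-rank
test (exact null for small tie-free samples, tie-corrected normal
approximation otherwise — scipy's automatic policy) with Benjamini–Hochberg
control at FDR 0.05 across each comparison family. All-zero differences
give p = 1 by convention.

## Phantoms: what they emulate and what they do not

`PhantomSpec`/`generate_phantom` produce: a liver as an ellipsoid with
smooth low-frequency boundary perturbation; ellipsoidal lesions
(rejection-sampled, fully inside the liver, pairwise disjoint with a
one-voxel gap so they stay distinct 6-connected components; retry cap 1000
per lesion); bright parenchyma with hypointense lesions (45 % of
parenchyma intensity by default) on a dimmer background; additive Gaussian
noise; an arbitrary per-case affine intensity distortion emulating
non-standardized MRI gray values; and an anisotropic grid (defaults 1.2 mm
in-plane / 3 mm slices, mid-range of the clinical protocol). Default extent
96×96×28 voxels with 0–3 lesions of 4–10 mm radius.

`simulate_raters` derives disagreeing reference variants: each lesion is
independently dilated or eroded by a signed radius drawn uniformly within a
magnitude (default 1.5 mm, converted to per-axis voxel radii so anisotropic
grids perturb plausibly), and small lesions (< 150 mm³) are dropped with
probability 0.1 — a rater overlooking a small lesion. Mean inter-rater
Dice decreases monotonically with the magnitude.

Phantoms deliberately omit MRI physics: no bias fields, motion, vessel
trees, partial-volume modelling or multi-phase dynamics. Lesions are
high-contrast ellipsoids, far easier than clinical lesions. Passing tests
on phantoms therefore demonstrates that the *machinery* is correct
(geometry, sampling, loss masking, selection, morphology, scoring) — not
that clinical-grade accuracy would be reached on patient data.

## Smoke-scale training conditions

CPU-scale checks use reduced problem sizes, chosen once:

* *Smoke training*: 10 training / 2 validation / 3 test phantoms at default
  phantom settings; width-reduced default-geometry network (per-level
  features 2, 2, 4, 8, 16; all kernels, levels and margins as in the
  default architecture); input patch 204×204×48 (an admissible extent of
  the same architecture, output 20×20×8 with the same 92×92×20 margin);
  batch size 1, Adam at 1e-2 — a learning rate sized for a 300-iteration
  budget at these widths — 300 iterations, validation every 150. Success is
  post-processed mean Dice > 0.5 on the held-out phantoms for ≥ 4 of 5
  seeds.
* *Toy successive halving*: bracket (4@50, 2@100, 1@200) with a two-level
  network on 24×24×9 patches and 48×48×16-voxel phantoms; checks the
  selection invariant (the survivor dominates every eliminated run at its
  elimination milestone) and worker-count independence.

## Numerical choices and edge cases

* Float32 tensors throughout the network; loss and reductions accumulate in
  float64 where it matters (batch-norm statistics, parameter-gradient sums).
* Threshold comparisons are strict (`>`), both at 0.5 binarization and the
  0.2 correspondence threshold.
* Dice/Jaccard of two empty masks is defined as 1; the masked Dice loss of
  an all-zero weight patch is 0 (logged as degenerate).
* Mirror padding repeats reflection when the requested pad exceeds the
  array extent, so arbitrarily small volumes can feed large input windows.
* Geometry violations (too-small patch, odd extent at a pooling, skip-crop
  parity mismatch) raise a `GeometryError` naming the offending layer.
* All randomness flows through seeded `numpy` generators: phantom
  generation, rater simulation, weight initialization, patch order,
  augmentation and dropout are reproducible bit-for-bit given a seed on a
  fixed platform.

## Known limitations

* The phantom task is far easier than clinical data; absolute scores on
  phantoms say nothing about clinical accuracy.
* The CNN stack is CPU-oriented; the default 32–512-width network is
  buildable and its geometry checkable, but full-scale (80k-iteration)
  training is out of reach without accelerator hardware.
* Successive halving is implemented sequentially; `workers` does not
  parallelize (results are worker-independent by construction).
* The correspondence matcher's optimality is guaranteed by construction
  only where exhaustive search is feasible; on larger instances greedy
  refinement is a heuristic (anchored by the small-instance equivalence).
* Orientation handling is axis-aligned only (no oblique acquisitions, no
  DICOM ingestion, no 4D series).
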