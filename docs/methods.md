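# Methods

## Model

`artmax` is a four-stage feed-forward model of rapid visual
categorization in the ventral stream, trained by a vigilance-gated,
append-only prototype learner.

**S1 (simple cells).** A bank of 64 Gabor filters: 16 receptive-field
sizes from 7×7 to 37×37 pixels in steps of two, at orientations 0°, 45°,
90° and 135° (the orientation names the preferred bar direction). The
per-size envelope width σ and wavelength λ follow the parameter table of
the standard HMAX benchmark implementation (σ from 2.8 to 18.2, λ from
3.5 to 22.8, aspect ratio γ = 0.3, circular aperture); the primary
source does not print these values and states only that its edge stage
was adjusted for comparability with that implementation, so its table is
adopted and exposed in the configuration. Each filter is zero-mean and
unit-L2-norm. Responses are the absolute normalized cross-correlation
between the filter and the L2-normalized image window, computed on valid
windows only (no padding, so maps shrink with filter size). The absolute
value makes responses contrast-polarity invariant, as complex-cell
pooling requires; whether the original used absolute or half-wave
rectification is unstated, and absolute rectification was chosen because
it keeps both polarities informative with half the filters.

**C1 (complex cells).** Max pooling over local position (grid sizes 8,
10, …, 22 per band, overlap half the grid — again the benchmark
implementation's geometry, since only the rule "pool range grows with
the size-band index" is stated) and over the two adjacent filter sizes
of each of 8 scale bands. The two scale grids are cropped to their
common extent before the cross-scale max.

**S2/C2 (prototype tuning).** A prototype is an n×n×4 block of C1
activity, n ∈ {4, 8, 12, 16, 20, 24}. At every valid position of every
band that admits the patch, the S2 response is
`exp(−‖X − p‖² / (2 σ_n²))` with σ_n² = s · 4n² (normalizing by the
element count keeps the dynamic range comparable across patch sizes);
C2 is the global max per prototype over positions and bands, giving a
position- and scale-tolerant feature vector whose length is the pool
size.

**Sharpness s.** The default is s = 5·10⁻⁴. The squared distance
between unrelated C1 patches of natural-statistics imagery is small
(the median elementwise squared difference is about 10⁻³, because C1
activity is sparse and bounded), so a width of σ_n² = 4n² (s = 1) sends
every response to within 10⁻³ of 1 and the tuning function stops
discriminating — which would also make any vigilance threshold below 1
inert. s = 5·10⁻⁴ maps the median unrelated-patch distance to a
response of about e⁻¹ ≈ 0.37, spreading C2 values over (0.2, 1) in
practice. This is the one substantive departure from the obvious
"s = 1" parameterization and is deliberate.

## Learning rule

Each training image is presented exactly once:

1. compute its C2 vector against the current pool;
2. select the P most active units (ties to the older prototype id);
   if the pool holds fewer than P prototypes, the missing slots count
   as mismatches (this bootstraps learning from an empty pool);
3. each selected response below the vigilance ρ is a mismatch and
   triggers extraction of `new_per_mismatch` fresh patches from the
   image's own C1 activity, appended to the pool.

The pool is append-only; re-presenting any learned image adds nothing
because its own patches match themselves with response exactly 1 (the
patch is a verbatim copy of its source window, so the squared distance
at the source location is identically zero). Defaults: P = 5, ρ = 0.9,
one patch per mismatch, patch sizes {4, 8, 12, 16}. There is no
canonical ρ; the convention is to choose it on held-out data for the
highest performance with the fewest prototypes, and
`evaluation.sweep_vigilance` implements that sweep. An optional
`max_prototypes` cap trains a model to a prescribed feature budget.

**Extraction site.** Where a mismatch-triggered patch is cut from is a
genuinely open design point. The default samples a uniformly random
valid (band, row, col) site, matching the convention of the random
training stage this learner extends. Two alternatives ship: `"energy"`
(the window with the highest summed C1 activity; deterministic) and
`"uncovered"` (of 8 candidate sites within one random band, keep the one
farthest from its nearest same-size stored prototype — novelty-directed
extraction). On the synthetic benchmark all three produce statistically
indistinguishable classification accuracy and stability traces (see
Limitations), so the simplest is the default.

## Classification and signal detection

C2 vectors feed a linear SVM (C = 1, raw features — C2 entries already
live in (0, 1] on a common scale, so no standardization). Accuracy is
reported at the equilibrium point: the decision threshold where the
false-positive rate equals the miss rate (ties resolve to the lower
threshold). Sensitivity d′ = z(hit) − z(false alarm) is computed at that
same threshold so it is free of decision bias; rates of exactly 0 or 1
are replaced by 1/(2N) and 1 − 1/(2N). ROC curves over repeated runs are
vertically averaged on a common false-positive-rate grid with pointwise
min/max envelopes. The repeated protocol draws a fresh seeded
equal-count train/test split per run, relearns features on the training
half only, and reports mean ± SD equilibrium accuracy.

## Synthetic benchmark

The generator emulates a face-versus-clutter categorization set.
*Faces* are schematic — a brighter head oval, two dark eye blobs, a dark
mouth bar — rendered over low-pass-filtered noise backgrounds, with
seeded jitter in position (±8 px), part geometry (±15–25 %), and
contrast (±20 %) on a 140×140 canvas (the model's working height).
*Distractors* are block-scrambled faces: 28-px tiles permuted and
rotated in multiples of 90°. A scramble is a permutation, so the two
classes share their pixel histogram (mean luminance matched within
0.005 in practice) and, by construction, their *local* part statistics;
only the configural arrangement distinguishes them, which is exactly
what intermediate-level prototypes are claimed to capture.
Salt-and-pepper corruption replaces an exact count `round(level · n)` of
seeded-random distinct pixels with 0 or 1 (equiprobable), so the nominal
level is exact per image. The benchmark builds a shuffled noise-free
training stream plus one balanced test set of fresh images per noise
level {0, 0.2, 0.4, 0.6, 0.8} (60 + 60 per level at the defaults, 600
test stimuli); training images are always noise-free.

What the generator does **not** emulate: photographic texture, pose and
identity variation, occlusion, or the extreme diversity of real
background photographs. Passing results therefore demonstrate the
mechanics of the model (invariance, stability, noise response), not
photographic-benchmark performance.

## Stability experiment

Images are presented in steps of m = 2. After each step the proposed
model has grown its pool by vigilance learning; the baseline appends an
equal number of uniformly random patches from the same step's images, so
both pools have identical sizes at every step (matched-count protocol).
The test bag is, by default, re-extracted at each step from every image
seen so far except the current step's m images (fresh random-site
patches, 5 per image unless configured otherwise); a fixed held-out bag
is available as an alternative since the growing-bag reading of the
protocol is one of two defensible interpretations. The statistic is the
mean over test patches of the Euclidean distance (flattened n×n×4
values) to the nearest training patch of the same size; cross-size
distances are undefined and never taken. The trend slope is the
least-squares slope of the distance trace against the step index,
skipping steps without a bag.

## Problem sizes

The shipped experiments are sized to be thorough but quick: the
classification acceptance runs use 25 + 25 training and 25 + 25 test
images per seed over 5 seeds with a 20-prototype budget; the noise
sweep uses 20 + 20 training images and a paired test set of 20 + 20
images corrupted at all five levels, over 3 seeds; stability runs use
20-image streams (10 steps) with 20 test patches per bag image over 5
seeds. `scripts/acceptance.py` uses 20 + 20 images per class and
split, 3 seeds for classification and 5 for stability. Larger sets
change none of the qualitative results.

## Numerical choices

- Window norms for S1 come from a padded integral image; norms below
  10⁻¹² are floored (a constant window has zero correlation with any
  zero-mean filter, so the response is 0 there regardless).
- Kernel spectra are cached per (bank, image shape) so a batch of
  same-sized images costs one forward FFT each.
- Top-P ties break toward the lower prototype id; equilibrium-threshold
  ties toward the lower threshold; both for determinism.
- All randomness flows through `numpy` Generators seeded from explicit
  integers or spawned `SeedSequence`s; every public entry point takes a
  seed.
- Degenerate inputs: an all-zero image yields all-zero C1 and
  low-energy patches (legal, flagged with a warning); an empty
  prototype pool yields an empty C2 vector (an untrained model); images
  smaller than a filter skip that filter with a warning.

## Known limitations

- The vigilance mechanism guarantees *representational* stability
  (re-presentation adds nothing, old prototypes are never altered) and
  delivers compact, informative pools. It does **not** reliably beat
  matched-count random sampling on the average-minimum-distance
  diagnostic under this benchmark: because distractors are scrambled
  faces, the local patch statistics of the whole stream are homogeneous,
  so an equal-sized uniform random sample is already an unbiased cover
  of the re-extracted test patches and the expected slope difference is
  ≈ 0 (measured across 12 seeds, three patch sizes, three site policies
  and several vigilance levels). A benchmark whose classes differ in
  local patch diversity (homogeneous targets, heterogeneous clutter, as
  in photographic collections) is expected to separate the two
  learners on this diagnostic; the matched-statistics design was kept
  because it is what makes the *classification* benchmark configural.
- The model is purely feed-forward at inference; the resonance loop is
  implemented at the algorithmic level (match test + append), not as
  neural dynamics.
- Four orientations and no color; rotation invariance beyond 45°
  steps is out of scope.
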