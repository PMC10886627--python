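# Methods

## The problem and the data model

Stimulated Raman scattering (SRS) microscopy images fresh tissue at two
Raman shifts: 2845 cm⁻¹, where photons scatter at CH2 bonds abundant in
lipids, and 2930 cm⁻¹, where they scatter at CH3 bonds abundant in
proteins and DNA.  A specimen therefore arrives as two aligned
nonnegative intensity grids (`ch2`, `ch3`) with acquisition metadata
(pixel size, default 467 nm; scan depth, default 10 µm, kept as
metadata only).  Two derived views feed the rest of the pipeline:

- **Three-channel tensor** `(CH2, CH3, CH3−CH2)`.  The third plane is
  the signed spectral difference; it is *not* clipped at zero because
  lipid-dominant tissue (adipose) has CH2 > CH3 and would lose its
  contrast.  Scaling into [0, 1] is a separate, explicit step.
- **Virtual H&E render** ("SRH").  Clinical instruments map the two
  channels through a proprietary look-up table to mimic an
  H&E-stained slide.  This package implements a documented stand-in: a
  two-endmember linear mixing where the per-pixel stain weight is
  `min((ch2+ch3)/scale, 1)` and the stain color interpolates from an
  eosin-like pink to a hematoxylin-like purple by the CH3 share
  `ch3/(ch2+ch3)`; zero signal renders white.  The render is a pure
  function of the image and the `LUTParams`, is monotone (more CH3 at
  fixed CH2 never reduces purple saturation), and makes no claim of
  matching any vendor's colors.

## Annotations and tiling

Annotations are closed polygons (outer ring plus optional holes) in
0-based pixel coordinates, origin top-left, y down — the convention of
QuPath, whose GeoJSON export dialect
(`properties.classification.name`) is read and written.  The class
vocabulary is closed: tumor, stroma, adipose tissue, muscle, squamous
epithelium, glandular tissue.  Because the virtual-H&E render is
pixel-aligned with the raw image, annotations transfer between the two
modalities by an identity coordinate map.

Images are tiled on a non-overlapping grid (stride = tile size,
anchored at (0,0); incomplete edge tiles dropped).  A tile is kept and
labeled with class *c* only if at least 99% of its area lies inside
the union of class-*c* polygons; a tile reaching 99% for two classes
at once (possible only with overlapping annotations) carries
contradictory information and is excluded, as is any tile below the
threshold for every class.

**Coverage semantics.**  A pixel belongs to a class iff its center
`(x+0.5, y+0.5)` lies inside the polygon union; coverage of a tile is
the fraction of its pixels belonging to the class, evaluated on a
half-open rectangle `[x, x+s) × [y, y+s)`.  An earlier design computed
coverage as clipped-polygon *area* divided by tile area; it was
replaced because area fraction and pixel-count fraction differ in the
fourth decimal on boundary tiles, which makes retention at a sharp
0.99 threshold depend on which definition the auditor uses.  With
pixel-center semantics the implementation (vectorized
point-in-prepared-polygon tests) and an independent ray-casting
rasterizer agree *exactly*, tile for tile, which the test suite
verifies.  Degenerate edge cases (a pixel center exactly on a polygon
edge) are measure-zero for generic float coordinates and are avoided
in all fixtures.

## Distribution-balanced splitting

Whole images — never individual tiles — are assigned to train,
validation and test, so no specimen leaks across subsets.  Default
sizes: 20% of images to test; 10% of the remaining training pool
(rounded to the nearest integer) to validation, i.e. 16 / 6 / 58 for
an 80-image cohort.

Subsets are filled in the order test, validation (training receives
the remainder).  For each subset, unassigned images are drawn uniformly
at random; the first draw is always kept, and a later draw is kept only
if it *strictly* decreases the Jensen–Shannon distance between the
subset's tile-class distribution and the whole-dataset distribution
(ties reject).  The JS distance is the square root of the JS
divergence with base-2 logarithms, so it is a metric on the 6-simplex
bounded by [0, 1].

Two practical amendments make the procedure total:

- **Stall handling.**  The strict-decrease loop can stall when no
  single remaining image lowers the distance.  After 200 consecutive
  rejections (configurable) the image minimizing the post-addition
  distance is accepted.  The split diagnostics record which
  acceptances came from this fallback.
- **Boundary condition.**  Every class must appear in every subset.  A
  filled split violating this is discarded and the procedure restarts
  with a seed derived from (seed, attempt); after a bounded number of
  restarts (default 50) an explicit infeasibility error is raised —
  e.g. immediately, if a class is missing from the cohort entirely.

A `naive_split` (uniform random, same sizes) exists purely as the
baseline against which the procedure's purpose — lower subset-to-total
JS distance — is checked statistically.

## Classifier

The reference architecture is a VGG19-style stack: sixteen 3×3
convolutions in five blocks (64,64 / 128,128 / 256×4 / 512×4 / 512×4),
each block followed by 2×2 max pooling, then flatten → dense 1000 →
dropout 0.5 → dense 100 → dense 6 with softmax.  Weights are randomly
initialized (He scheme, seeded); there is no pretraining.  Reference
training hyperparameters: 100 epochs, batch 100, learning rate 1e-4.
The optimizer is not pinned by the reference configuration; Adam is
used as the standard choice at that learning rate.  The loss is
softmax cross-entropy with per-class weights `w_c = 1/(K·p_c)` (K = 6,
p the tile-class distribution), normalized so `Σ p_c w_c = 1` — the
weighted loss is then comparable in magnitude to the unweighted one,
and a uniform distribution yields unit weights.  During training each
tile is independently flipped horizontally and vertically with
probability ½; dropout and augmentation are inference-off.  The
final-epoch weights are kept (no early stopping); validation metrics
are logged per epoch for audit.

Because no deep-learning framework is assumed, the layers (im2col
convolution, max pooling, dense, inverted dropout), Adam, and the
weighted loss are implemented in numpy inside the package
(`srshisto.nn`), with backpropagation verified against finite
differences in the test suite.  A fixed input-centering layer
(x − 0.5, the VGG practice of mean subtraction) precedes the first
convolution: tiles normalized to [0, 1] are all-positive, which
otherwise slows early symmetry breaking noticeably on small training
runs.

**Desk profile.**  Full-scale VGG19 at 250×250 is constructible but
CPU-hostile.  The `small_cnn` backbone (four 3×3 conv/pool blocks of
width 8/16/32/32, same dense head) accepts 64×64 tiles and trains in
tens of seconds.  The desk profile uses 15 epochs, batch 32 and
learning rate 1e-3: the reference 1e-4 belongs to the 100-epoch
full-scale run and demonstrably underfits a small network within a
≤20-epoch budget.

**Input scaling.**  The pipeline maps the three-channel tensor into
[0, 1] by a fixed global affine range ([−1.5, 1.5] by default) rather
than per-image min/max.  Per-image scaling removes acquisition-gain
differences, but for a specimen containing a single tissue class it
also removes exactly the absolute intensity level that identifies the
class — every single-class image then spans the same [0, 1] range and
classes collapse.  Per-image min/max remains available as an explicit
strategy (`normalize_for_model(..., "per_channel_minmax")`).

## Evaluation

All metrics derive from one 6×6 confusion matrix (rows true, columns
predicted, fixed class order): precision `TP/(TP+FP)`, recall
`TP/(TP+FN)`, F1 `2PR/(P+R)`, and balanced accuracy — the unweighted
mean of the six recalls, the headline figure for imbalanced tile sets.
Zero-denominator metrics return 0 with a logged warning instead of
NaN.  Rendered tables round to 2 decimals (percentages to whole
percent) in the conventional display order (stroma, adipose, squamous,
muscle, glandular, tumor); a machine-readable JSON keeps full
precision.  The misclassification helper `cm[a,b]/rowsum(a)`
reproduces cross-prediction percentages from raw counts.

## Synthetic cohorts

The clinical imaging data are not public, so a generator emulates the
statistical structure the pipeline consumes.  Per specimen, the canvas
is partitioned into 1–4 convex-ish regions (Voronoi cells of random
seed points, shrunk by 4% about their centers so unannotated seams
separate regions and partial-coverage tiles genuinely occur at
borders).  Each region is one tissue class and is filled from a
`ClassSignature`: base (CH2, CH3) means encoding the biochemistry
qualitatively — adipose CH2-dominant (0.90, 0.30); tumor (0.25, 0.85),
squamous (0.12, 0.55) and glandular (0.70, 0.80) CH3-dominant; stroma
(0.55, 0.45) and muscle (0.45, 0.65) intermediate — plus a class-typic
zero-mean texture (vacuoles, fibrous noise, nuclear dots, striations,
layering, glandular rings; amplitude 0.06), a per-image Gaussian
intensity offset (σ = 0.02, an acquisition-gain nuisance), and i.i.d.
Gaussian speckle (σ = 0.05), clipped at 0.  Intensity units are
self-consistent placeholders; no fidelity to the instrument's value
range is claimed.

Class assignment targets the study's published relative class
abundances (tumor 0.23, stroma 0.23, adipose 0.07, muscle 0.03,
squamous 0.39, glandular 0.05).  Every other image carries one forced
region of a cycling class, guaranteeing each class appears in ~n/12
specimens so the split's boundary condition is feasible; the remaining
regions are sampled from the target mixture minus the forced quota,
keeping the realized tile mixture close to the target (JS distance
< 0.1 on an 80-image cohort, which the tests check).  A
`separation_margin` scales all class means radially about their grand
mean — the control knob for task difficulty — and `hard_mode` moves
the squamous signature next to the tumor signature (same texture,
near-identical means), reproducing qualitatively the tumor↔squamous
confusion that dominates errors on real tissue.

What the generator does *not* emulate: real histological morphology,
line-scan stitching artifacts, instrument noise spectra, or
inter-patient biological variance beyond the per-image offset (the
synthetic "patients" are bookkeeping ids).  Passing tests therefore
demonstrate that the pipeline's machinery — tiling, splitting,
weighting, training, evaluation — behaves as specified on data with
the study's statistical shape, not that the classifier would reach any
particular accuracy on real tissue.

## Problem sizes and budgets

Tests and the acceptance script run on one CPU.  Sizes were chosen
once: desk cohorts are 80 images (the study's image count) at 320×320
px with 64×64 tiles and 1–3 regions per image (~480 tiles per cohort);
tiling-oracle equivalence checks run on specimens up to 1000×1000; the
split-vs-naive comparison uses 20 cohorts of 40 images with
Dirichlet-multinomial per-image class tallies, since a rendered cohort
small enough to be cheap cannot place six classes into a 2-image
validation subset at 1–3 regions per image.

## Numerical choices and edge cases

- JS distance: `scipy.spatial.distance.jensenshannon(base=2)`, with
  the p = q case pinned to exactly 0 (scipy can emit NaN from 0/0);
  0·log 0 terms are 0.  The test oracle is an independent hand-written
  KL summation.
- Tile labeling threshold comparisons use `>=` on the exact ratio
  covered-pixels / tile-pixels; IEEE division makes the boundary case
  (e.g. 61875/62500 vs the literal 0.99) exact.
- Argmax ties at prediction break toward the lowest class index.
- Constant planes under min/max normalization map to all zeros.
- All randomness flows through `numpy.random.Generator`; sub-seeds for
  cohort, split, model init and augmentation derive from a master seed
  via `SeedSequence`, so any stage can be re-run in isolation and a
  fixed seed reproduces a run bit-for-bit within one software
  environment (cross-environment bit-exactness is not promised).

## Known limitations

- The virtual-H&E render is a documented surrogate, not the vendor
  mapping; SRH-modality results characterize the pipeline, not the
  instrument's rendering.
- The full 250×250 VGG19 profile is validated for construction and
  shape contracts only; training it is out of CPU scope.
- The iterative split is a greedy heuristic; it is compared against a
  naive baseline, not against optimal distribution-balanced
  partitioning.
- Tile-level metrics only; no patient-level aggregation.
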