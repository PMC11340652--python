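# Methods

`oliveshape` implements an automated morphometric pipeline for
discriminating olive (*Olea europaea*) cultivars from binary silhouettes
of three organs — fruits, leaves and endocarps (stones) — following the
workflow used in olive phenomics: segmentation, contour-based descriptor
extraction, per-organ probabilistic classification, a stacking
meta-classifier over the organ classifiers' probability outputs, and
Shapley-value attribution of descriptors and organs. Because no public
olive silhouette dataset accompanies this code, a synthetic generator
with analytic ground truth stands in for the imaging rig; everything
downstream of the binary mask is the same code a real cohort would use.

## Segmentation and silhouettes

Images are assumed to show one organ on a uniform background. We apply
a global Otsu threshold, try both polarities (dark-on-light and
light-on-dark) and keep the one whose object does not touch three or
more image borders, fill holes, and keep the largest 4-connected
component (second components above 25% of the largest trigger a
multi-object warning; below 100 foreground pixels is an error). The
physical scale comes from configuration, either directly as mm/px or as
25.4/dpi; no ruler detection is attempted. Masks round-trip as binary
PNGs with a JSON metadata sidecar (sample id, cultivar, year, organ,
viewing position, scale).

## Contours and primitives

The mask boundary is traced at the 0.5 iso-level with sub-pixel
precision, resampled to `n_points = 512` at equal arc length, and
smoothed with a periodic Savitzky–Golay filter whose window covers about
8 px of boundary (minimum 9 samples). The window scales with resolution
so that the rasterization staircase is suppressed at every mask size
while millimetre-scale features (a fruit nipple is ≥ 1 mm wide) pass
through; without this the staircase inflates perimeters of small
silhouettes by several percent. The contour is then rotated so its
first principal axis is vertical, oriented apex-up, and centred on the
polygon centroid.

Apex-up disambiguation: fruits and endocarps narrow toward the apex, so
the end whose landmark window (±10% of perimeter) has the larger mean
|curvature| is taken as the apex. For leaves this rule would latch onto
the petiole, so the petiole attachment defines the base instead (the
split is computed first and passed as an orientation hint).

Primitives on the normalized contour:

- **area, perimeter** — shoelace formula and segment sums;
- **caliper dimensions** — height is the y-extent; the width profile is
  the horizontal chord length at 257 evenly spaced heights (shapely
  line–polygon intersections), and width is its maximum;
- **ellipse fit** — stable direct least squares (Halir–Flusser, via
  scikit-image), axes ordered `a ≥ b`, with an RMS radial residual;
- **curvature** — signed curvature from periodic Savitzky–Golay first
  and second arc-length derivatives (window 15 of 512, stated in every
  report since curvature descriptors depend on it); positive on convex
  arcs, `1/r` on circles;
- **symmetry** — transversal asymmetry is one minus the fractional
  overlap of the shape with its mirror image about the vertical axis
  (computed exactly with shapely polygon intersection rather than by
  rasterization — it is resolution-free and equally robust); vertical
  symmetry is the normalized height of the maximum transversal diameter
  (0.5 for an ellipse, >0.5 means widest toward the apex).

## Descriptor catalogs

Counts follow the UPOV-style catalogs used for olives: 24 fruit values
(12 per viewing position A/B), 16 leaf values, 22 endocarp values
(11 per position) with 3 optional cross-position extras (a mucro flag,
mean circularity, width ratio A/B) behind an `--extended-endocarp`
flag. Descriptors named in the olive literature (shape index,
circularity, fitted-ellipse axes, apex curvature, nipple index and
size, petiole thickness, vertical/transversal symmetry, transversal
diameter position and its minimum distance to the contour, base length,
apex-curve area) are implemented as defined above; the remaining slots
are standard contour descriptors (perimeter, convexity, ellipse major
axis) and are flagged *reconstructed* here because no exact formula for
them is fixed by the catalogs. Curvature descriptors are exported
nondimensionalized (κ × organ length); binary descriptors are stored as
0/1 floats so each table is a single numeric matrix.

**Nipple/mucro detection.** The baseline is the arc of an ellipse
fitted to the contour *excluding* the apex landmark window — a
protrusion must not drag its own baseline outward (with a whole-contour
fit, a bump of 5% of fruit height hides itself). A nipple is scored
present when the maximum outward radial deviation in the apex window
exceeds 2% of organ height and the deviation region carries a local
curvature maximum at least twice the window median; its size is the
area between contour and arc over that region (we treat nipple size as
an area, in mm²). The endocarp's apex-curve area is the same integral
without the presence gate and serves as the mucro signal (flag
threshold: 1% of organ area).

**Petiole split.** Leaf pixels are projected on the principal axis and
binned at one-pixel pitch; the petiole is the maximal run of bins below
20% of the maximum width, adjacent to one end and longer than 5% of the
organ length. Thickness is the *median* bin width over the quarter of
the run adjoining the blade (upper) and the distal quarter (lower);
the median resists the blade flare at the junction, which biases a mean
by more than the measurement tolerance.

## Classification

Feature tables are z-scored inside each model pipeline (so scaling is
fit on training folds only). The default base and meta algorithm is
gradient-boosted trees (XGBoost, library defaults echoed into the model
manifest); k-NN, random forests and probability-calibrated SVMs are
selectable. Training protocol for the stacking model:

1. stratified 9/10 train / 1/10 holdout split;
2. stratified 5-fold loop over the training part: the three organ
   classifiers fit on 4/5 and emit class probabilities for the held
   fold, yielding out-of-fold probability matrices — no base model ever
   scores a row it saw in training (asserted structurally);
3. the meta-classifier trains on the concatenated matrices
   (width 3 × n_classes);
4. 5-fold cross-validation on that meta training set gives the CV
   metric; the untouched holdout is scored separately. Both numbers are
   reported, since "meta-classifier accuracy" can legitimately mean
   either.

Joint instances pair fruit and endocarp rows by sample id (stones are
extracted from the sampled fruits, so the pairing is physical); leaves
are paired by a seeded random permutation within each cultivar and
re-drawn across repeats, so no result depends on one arbitrary pairing.
Per cultivar, the joint count is the minimum of the three organ counts.
Evaluation reports one-vs-rest precision/recall/F1 per cultivar,
with mean ± sd over 10 seeded re-splits; the accuracy-vs-k curve draws
seeded random cultivar subsets (default 20 per k, one when k equals the
cultivar count) and reports mean holdout accuracy per organ and stacked.

## Shapley attribution

The value function is interventional: a coalition's value is the model
output with coalition features from the instance and the rest imputed
from background rows (a seeded subsample of at most 100 table rows),
averaged over the background. Exact enumeration over all 2^m
coalitions is available for m ≤ 14 and satisfies efficiency, symmetry
and the null-player property to machine precision; the default
estimator is Monte-Carlo permutation sampling (one feature ordering and
one background row per draw) with per-feature standard errors.
Multiclass models are explained per class on the predicted probability;
global importance is the mean |value| over instances and classes.
Organ contributions run the same estimator on the meta-classifier's
3 × n_classes probability inputs and, per cultivar, sum mean |value|
over each organ's columns, normalized to sum to one.

## Synthetic cohorts

Shapes are star-shaped polar curves: a per-half superellipse (exponent
2 on the base half, 2/`apex_sharpness` on the apex half), a taper
factor `(1 − taper·sinθ)` that moves the widest section toward the base
for taper > 0 (ovoid fruits, lanceolate leaves), a narrow Gaussian
angular bump at the apex (nipple/mucro; σ = 0.12 rad by default — these
are short, pointed protuberances), and band-limited boundary noise
(Fourier orders 6–12, amplitude as a fraction of width, capped at 5%).
Since ρ > 0 the polygon is always simple. Ground truth (area by
quadrature of ½∮ρ²dθ, caliper dimensions and widest-section height from
the dense curve) comes from the continuous curve, independent of
rasterization. Leaves add an axis-aligned petiole rectangle at the
blade base. Rasterization uses an even-odd scanline fill at pixel
centres (unbiased, and consistent with the 0.5 iso-level used for
tracing), default 0.05 mm/px.

Cohorts draw per-sample parameters from lognormal perturbations around
per-cultivar means (taper: additive noise; lengths stay positive by
construction), apply a multiplicative year effect in the second season,
and couple endocarp size to the fruit of the same sample through a
shared latent size factor — mirroring the observation that cultivars
with larger fruits have larger stones, and giving the fruit–endocarp
pairing physical meaning. The fast mode computes descriptors directly
on the analytic polygons; the image mode renders masks and runs the
full raster pipeline. Both modes agree on scale-free descriptors to
within a few percent and the image mode is used wherever the raster
path itself is under test.

Presets (frozen, built from fixed internal seeds):

- `separable3` — three cultivars with widely separated means and 2%
  within-cultivar spread; a correctness fixture, trivially classifiable.
- `overlap14` — fourteen cultivars spanning realistic olive ranges
  (fruit height 15–26 mm, elongation 1.1–2.0; endocarp ≈ 62% of fruit
  height; leaf blades 50–58 mm) with 7% within-cultivar spread and
  per-cultivar year effects of ±6%. Leaf trait ranges overlap heavily
  across cultivars on purpose: in real olive cohorts the leaf is the
  least discriminative organ, and the preset reproduces that ordering
  (single-organ accuracy at 14 cultivars ≈ 0.5 for every organ, stacked
  ≈ 0.86 on this cohort).
- `kalamon_leaf` — one cultivar whose fruit and endocarp means coincide
  with a sibling's but whose leaf blade is twice as wide, emulating the
  one olive cultivar famously identifiable by its leaves.
- `complementary` — organ-complementary signal: fruit separates
  {c1,c2} from c3, endocarp separates c1 from c2, leaves carry nothing;
  stacking must combine organs to win.

What the generator does *not* emulate: photographic artefacts (shadows,
specular highlights, debris), color and texture, endocarp surface
grooves, non-star-shaped outlines, and correlated descriptor noise
beyond the shared size factor. Passing tests therefore demonstrate the
correctness of the measurement and learning machinery under controlled
geometry, not field performance on real photographs.

## Numerical choices and degenerate inputs

- Sample (n−1) standard deviation throughout; CV is undefined (NA) for
  |mean| < 1e-12 or groups below 3 samples.
- Constant features are dropped (with a warning) before PCA; features
  are z-scored before PCA and clustering because the catalogs mix mm²,
  mm and unitless quantities.
- Cultivar clustering: Ward linkage on Euclidean distances between
  per-cultivar means of standardized descriptors, concatenated across
  organs; exported as Newick with heights as ultrametric distances.
- Violin summaries: Gaussian KDE with Silverman bandwidth on a
  128-point grid after removing outliers beyond 1.5×IQR per group;
  quartiles are computed on the full group; groups below 5 points get
  quartiles only.
- Probability matrices are validated to row-sum 1 within 1e-6.
- Degenerate ellipse fits (collinear points) and self-intersecting
  generator curves (ρ ≤ 0 under excess noise) raise errors rather than
  returning garbage; failed samples are logged and skipped during table
  assembly, never imputed.

## Problem sizes

Simulated study sizes are chosen so the whole verification runs on a
laptop-class single core: separable/complementary cohorts use 60
samples per organ (10 per cultivar × 2 years × 3 cultivars), the
14-cultivar cohort 30 per cultivar, geometry and round-trip oracles 50
seeded shapes, Shapley exact-vs-sampled checks 10,000 permutations on
5-feature models, and attribution checks 10 seeded cohorts. Larger
cohorts only sharpen the same comparisons.

## Known limitations

- Descriptor formulas are reconstructions of catalog descriptions, not
  a port of any reference implementation, so absolute descriptor values
  are not comparable to numbers published for real cohorts.
- The A/B position registration of fruits and endocarps is assumed
  given (paired files share a sample id); no automatic registration.
- `base_length` is near zero for smooth ellipse-like endocarps (no flat
  base region exists), which is correct but makes the descriptor
  uninformative on such cohorts.
- Exact Shapley is exponential in feature count and refuses m > 14;
  organ tables (16–24 features) are explained with the sampled
  estimator.
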