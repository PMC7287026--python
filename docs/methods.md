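# Methods

## Problem and model

The package quantifies external degeneration of the *Drosophila* compound
eye from a single bright-field photograph.  The underlying assumption is
that tissue health is encoded in the geometric regularity of the
ommatidial lattice: a healthy eye is a near-perfect hexagonal packing of
bright facets, and neurodegeneration (here the polyQ/SCA1 model and its
genetic modifiers) progressively disorders it.  The method never measures
individual ommatidia; it classifies the texture statistics of the whole
eye surface and converts the class posterior into a severity-weighted
index.

## Eye-ROI detection

All detection happens at quarter resolution (bilinear, antialiased), both
for speed and because the quantile-based thresholds are scale-free.

1. **White top-hat** (input minus its opening by a disc) with a disc of
   diameter 9 px, applied per RGB channel before grayscale conversion.
   The opening removes every bright structure smaller than the disc, so
   the difference isolates exactly the facet-scale bright spots; the
   convex eye's smooth brightness gradient — which would defeat a global
   threshold — is subtracted away.  Erosion/dilation borders use edge
   replication so the image frame does not produce a bright rim that
   would contaminate the quantile threshold.
2. **Thresholding** keeps pixels strictly above the 0.99 quantile of the
   grayscale top-hat image (linear interpolation of order statistics,
   i.e. Hyndman–Fan type 7).  On a constant image nothing is strictly
   above the quantile; this raises a degenerate-input error rather than
   silently returning an empty set.
3. **Robust centroid**: the Weiszfeld fixed-point iteration for the
   geometric (L1) median, initialized at the coordinate-wise median,
   stopping at 1e-6 displacement or 1,000 iterations.  If an iterate
   lands within 1e-9 of a data point the Vardi–Zhang adjusted step is
   used, which handles the case where the median *is* a data point.  The
   L1-median resists the stray bright pixels (glare, dust) that would
   drag the arithmetic mean outside the eye.
4. **Outlier rejection** drops pixels whose distance to the centroid is
   strictly above the 0.8 quantile of the distance distribution (same
   estimator).
5. **Confidence ellipse**: mean and sample covariance (n−1) of the
   surviving pixels, with Mahalanobis radius chi-square(2 df) at 0.90
   (≈ 4.605 = 2·ln 10).  For Gaussian-distributed pixels the ellipse
   covers 90% of them; the construction is the standard Gaussian
   confidence ellipsoid.  Collinear pixel sets (singular covariance) are
   rejected.  The ellipse is masked onto the resized image; pixels
   outside the ellipse are zeroed, keeping a rectangular crop for
   featurization.

The detector is translation-equivariant by construction (every stage is
either pointwise or relative to the pixel cloud), which the tests verify
to within 5 full-resolution pixels on synthetic eyes.

## HOG featurization

Grayscale is Rec. 709 luminance (0.2126, 0.7152, 0.0722 — configurable;
the weights sum to 1 so constants are preserved).  Gradients are centered
differences with edge-replicated borders; orientation is `atan2(gy, gx)`
folded modulo 180° (unsigned: a dark→bright and bright→dark edge are the
same structure).  The descriptor is a 5 × 5 grid of contiguous cells
(band sizes differ by ≤ 1 px when the crop is not divisible — no
resampling, which would alias the lattice), five hard-assigned 36°
orientation bins weighted by gradient magnitude, and per-cell L2
normalization `h/√(‖h‖² + ε²)` with ε = 1e-6.  Bilinear vote-sharing
between neighboring bins exists behind a flag but is off by default; hard
binning is the documented contract.

Consequences of these choices, which the tests pin down: the descriptor
length is cells²·bins = 125; a constant image gives an all-zero vector
(a zero histogram stays zero under the ε-guarded normalization); the
descriptor is invariant to global intensity scaling and shifts, so
classification responds to structure rather than illumination; and
per-cell normalization deliberately discards absolute edge density — the
class signal must live in the orientation *distribution*.

## Classifiers and evaluation

Four classical learners (scikit-learn): RBF-kernel SVM with the kernel
written `exp(−σ‖u−v‖²)` (sklearn's `gamma` convention, so σ maps
directly), a decision tree, AdaBoost over decision trees, and a random
forest of 1,000 trees.  The train/test split is stratified with train
count `ceil(0.75·n_c)` per class — the rounding rule that reproduces the
published per-class test counts (20, 11, 13, 15, 16 from 82, 44, 55, 62,
65).  Hyperparameters come from a stratified 10-fold cross-validated grid
search; grid points are visited in ascending parameter order and only a
strictly better mean accuracy replaces the incumbent, so ties resolve to
the lowest-complexity model (smallest C, then smallest σ).  The default
SVM grid spans σ from 5e-4 to 2: the low end matches raw-intensity
feature scales (including the C = 1, σ = 0.005 optimum reported for the
original photographs), the high end matches the O(1) squared distances of
per-cell-normalized descriptors.

Evaluation statistics are implemented from their definitions:

* **accuracy** = confusion trace / total, with the exact
  (Clopper–Pearson) binomial interval via beta quantiles;
* **Cohen's kappa** = (p_o − p_e)/(1 − p_e) with p_e from the matching
  row/column marginals; undefined (explicit error) when all mass sits in
  one cell;
* **Hand–Till multiclass AUC**: for every unordered class pair the
  rank-based (Mann–Whitney, ties ½) AUC is computed in both directions
  and averaged; the index is the mean over pairs present in the truth.
  ROC curves per pair use the first class's posterior as the score; their
  trapezoidal area equals the rank AUC.

SVM class probabilities are the underlying implementation's standard
probability estimates (Platt-style calibration); this is a fidelity
caveat — the original probability mechanism is not documented, so IREG
values on the original data are not promised numerically, only the
formula and its algebra.

Confusion matrices are oriented rows = predicted, columns = reference.
The published count tables for all four classifiers ship in
`ommaquant.reference` and the package reproduces every published
accuracy, CI bound and kappa from them to three decimals.

## IREG

IREG = [4·P(WT) + 3·P(mod#1) + 2·P(mod#2) + 1·P(mod#3) + 0·P(SCA1)] / 4.
The weight vector is a reconstruction: the printed formula in the source
text is typographically garbled, but the stated [0, 1] range, the
severity ordering WT < mod#1 < mod#2 < mod#3 < SCA1, and the reference
gridlines at 0.25/0.5/0.75 force exactly these weights.  The weights are
configurable.  The score is affine in the posterior, pure classes land on
(1, 0.75, 0.5, 0.25, 0), and moving probability mass toward a more
degenerate class can never increase it.  Malformed inputs (not summing to
1, negative entries) raise instead of being renormalized, so upstream
bugs surface rather than being averaged away.

## Synthetic eye generator

The generator exists so that segmentation, featurization, classification
and IREG are testable end to end with no external data.  It renders a
convex elliptical eye (radially shaded dark-red body) on a dim background
with the ommatidial lattice drawn as the **Voronoi cells of the facet
centers**: bright facet interiors separated by thin dark grooves.  This
choice is load-bearing: stamped circular facets have orientation-isotropic
edges and carry almost no oriented-gradient signal, whereas Voronoi cells
of a regular hexagonal lattice are hexagons whose groove edges fall into
exactly three orientation families 60° apart — the structural signal HOG
measures.  Two other rendering details matter for the descriptor:

* a Gaussian camera PSF (σ = 4 full-resolution px, ≈ 1 px at quarter
  resolution) is applied before noise.  Without it, rasterized edges are
  staircases whose centered-difference orientations collapse onto
  0°/45°/90°/135° — the grid's diagonals — rather than the true lattice
  orientations, and the class signal disappears after downscaling;
* the lattice is rotated 15°, placing the three edge families at 15°,
  75° and 135°, i.e. mid-bin for 36° bins, avoiding the 0/180 wrap-around
  split of an axis-aligned lattice.

Degeneration maps a single disorder level t ∈ [0, 1] linearly onto four
channels between the healthy base spec and a fully degenerated endpoint:

| channel | base (t = 0) | endpoint (t = 1) | visual signature |
|---|---|---|---|
| facet-center jitter σ | 0.5 px | 5.5 px (0.23 spacing) | orientation order decays |
| fusion probability | 0.02 | 1.0 | grooves to the two nearest neighbors erased; facets merge into smooth blobs |
| depigmentation | 0.02 | 0.6 | pale patches, red channel attenuated |
| bristle density | 0.9 | 0.0 | dark interommatidial dots vanish |

The endpoints are calibrated so the five equally spaced class levels
(0, 0.25, 0.5, 0.75, 1 for WT, mod#1–3, SCA1) step the image statistics
in distinguishable increments: the hexagonal order parameter decays
roughly as exp(−k·σ²) in the jitter, so a jitter endpoint of ~0.23 of the
lattice spacing spreads that decay over the whole level range instead of
saturating after the second level, while fusion and bristle loss progress
linearly and separate the severely degenerated levels.  Defaults render a
960 × 1280 frame with eye semi-axes (220, 300) px and 24 px spacing
(~350 facets), echoing the imaging geometry of the study photographs
(2,880 × 2,048 with the eye filling about half the frame) after scaling.

Illumination modes: `diffuse` (facets are brighter red polygons) and
`bright_spot` (a specular white highlight per facet, as produced by
direct illumination); both are segmentable by the default detector.
Rendering is fully deterministic given (spec, seed), and every image
carries its ground truth (eye ellipse, facet centers).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optical vignetting and depth-of-field falloff,
specular glare, body parts and background clutter around the eye,
necrotic black tissue, natural biological variation in eye size and
shape, and the fact that real genotypes are qualitatively distinct
phenotypes rather than points on a single disorder axis.  End-to-end
accuracies on synthetic cohorts therefore validate the pipeline's
mechanics and internal consistency, not field performance on
photographs.

## Problem sizes and numerical choices

The end-to-end acceptance check uses 40 images per class (200 total) at
random in-frame positions, a 75/25 stratified split, and 10-fold CV grid
search — a scale chosen so the whole suite runs in a few minutes on one
CPU.  Quantile estimation is type 7 everywhere (the default of most
statistical environments); strict inequalities at both quantile filters;
Weiszfeld tolerance 1e-6; ε = 1e-6 in HOG normalization; probability
vectors are validated to 1e-8.  Degenerate inputs (constant images,
collinear point sets, singleton classes, empty class pairs) raise typed
errors rather than propagating NaNs; the batch pipeline logs and skips
failing images instead of aborting.

## Known limitations

* The HOG internals of the original analysis are not documented beyond
  cell/orientation counts; numeric equality with the original 125-vectors
  is not expected, only the stated contract.
* SVM probability calibration differs between implementations, so IREG
  values are comparable within a model, not across toolchains.
* The detector assumes one eye per frame and an elliptical ROI.
* Published headline accuracies on the original 308-image dataset are
  external-data results; this package reproduces their printed
  confusion-matrix-derived statistics exactly, and demonstrates the full
  pipeline on synthetic cohorts.
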