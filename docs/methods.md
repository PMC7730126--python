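# Methods

This note documents the models, conventions and design choices behind
`morphoscreen`, in the order the pipeline runs them.

## Screen design

The design is the full Cartesian product of the four factor categories, with
MP varying slowest and SF fastest so condition ids are stable. ECM subsets
are unordered; labels use the canonical letter order L, C, F ("LC", "CF",
"LCF", with "blank" for the empty set). Stiffness is stored as the nominal
kPa value with the paired polymer %w/v kept as metadata, not as a separate
factor. Wells are assigned by a seeded permutation of condition × replicate:
the 384-well row/column names (A1…P24) are provided for realism but carry no
spatial effects, and randomizing the order guards downstream code against
accidentally exploiting enumeration order.

## Synthetic plate generator

The generator is the study-conditions oracle for every statistical claim the
package makes; its defaults are fixed and are not tuned per analysis.

**Condition → mixture.** Each condition's phenotype mixture is
`softmax((baseline + Σ factor-level logits) / T)` over (polarized,
non-polarized, spread, inverted). The planted default logits encode, in
order of strength:

| effect | logits (pol, npol, spr, inv) |
|---|---|
| EGF absent | (0, 0, 0, +7) |
| 8 kPa | (0, 0, 0, +4) |
| 0.5 kPa | (−2, −2, +2.5, 0) |
| 2 kPa | (+2.5, +2.3, 0, 0) |
| 4 kPa | (+2.5, +1.9, 0, 0) |
| fibronectin-containing EC | (−2.5, +2.5, 0, 0) |

so that: EGF withdrawal or high stiffness drives wells to near-pure
inverted; polarized colonies require 2–4 kPa *and* EGF *and* a
fibronectin-free matrix; fibronectin converts would-be polarized wells to
non-polarized; the softest matrix favors spread. Non-polarized is planted
slightly stronger at 2 than 4 kPa while polarized is equal across the two.

**Degradability and within-well mixing.** The temperature `T` is exposed per
degradability level but defaults to 1.0 for both. Degradability instead
controls the *mixing concentration*: each well's realized mixture is drawn
from Dirichlet(c · p) centred on the condition mixture p, with c = 80 for
degradable (GPQG-type) and c = 2 for non-degradable (VPMS-type) matrices.
Because the Dirichlet mean equals p for every c, degradability changes
within-well heterogeneity — non-degradable wells collapse toward a single
dominant phenotype, degradable wells stay mixed — without shifting any
condition's average composition. This is the only construction consistent
with both planted findings the analysis must recover: a null global
degradability effect in the GLM, and non-degradable enrichment among
top-ranked (near-pure) wells. A temperature-based mechanism would violate
the first. One consequence is that mean preservation caps the enrichment:
for a phenotype whose optimal conditions have moderate probability
(polarized, ≈ 0.5–0.6), roughly half of the non-degradable wells land
*below* the degradable band, so the top-5% non-degradable share is bounded
near 50% there, while phenotypes with strong optima show 65–95%.

**Counts.** Per-well colony counts are negative-binomial with mean 163 and
shape 13, chosen so the distribution's median is 159 and its standard
deviation ≈ 47 colonies per well; `dispersion = inf` degenerates to a
constant count for tests.

**Rendering.** Wells are generated directly as the z-collapsed 2D projection
the downstream analysis consumes (1024×1024 px at ~1.3 µm/px by default;
tests use 512–640 px). Colony radii are log-normal with median 11 px
(≈ 29 µm diameter; spread 1.5× with elongation 1.6–2.2 and a low-order
Fourier boundary wobble). Radii this size keep the packing fraction ≈ 8% at
the median count, so non-overlapping rejection-sampling placement (separation
margin 8 px, 200 tries, then drop-with-warning) essentially always succeeds.
The four architectures are: polarized — disk at 700 counts with a 2300-count
annulus spanning 0.32–0.50 of the radius (the actin belt); inverted — dark
interior (450) with a bright rim (1600) over 0.82–1.0 R, angularly modulated
to mimic clumped edge bundles; non-polarized — flat disk (900) with smooth
multiplicative speckle; spread — dim (520), textured, elongated. Background
is 200 counts with additive Gaussian read noise (σ = 25); all magnitudes are
arbitrary-but-fixed 16-bit counts, since no real intensity calibration is
being emulated. What the generator does *not* emulate: 3D structure, PSF and
photophysics, illumination gradients (an optional flag exists for none of
these), colony–colony interactions, segmentation-hostile clumping, and
batch/plate-position effects. Passing tests therefore demonstrate that the
analysis recovers planted condition-level structure under clean imaging, not
robustness to those real-data nuisances.

All randomness flows from one plate seed through `numpy` `SeedSequence`
spawning, one child stream per well, so any subset of wells regenerates
byte-identically.

## Segmentation

Gaussian smoothing (σ = 2 px) → global Otsu threshold → binary hole filling
(inverted colonies have interiors darker than background) → 8-connected
labeling → removal of components under 100 px. Otsu is preferred over
adaptive methods because synthetic backgrounds are flat; a fixed-threshold
override exists for reproducibility tests. Since Otsu always returns a
threshold, a blank-but-noisy well would otherwise shatter into noise blobs;
a contrast guard reports a well empty unless the candidate foreground
exceeds the background by 3 background standard deviations. Touching
colonies are not split (the generator guarantees non-overlap; declumping is
out of scope). Coordinates are 0-based (row, col) pixel centers; bounding
boxes are half-open.

## Morphometry — the 102-measurement contract

The feature manifest is fixed: 20 area-shape + 30 intensity + 52 texture =
102 named measurements per colony (the count is a conformance contract; the
family structure mirrors standard high-content feature sets).

* **Area-shape (20):** area, perimeter, convex area, solidity, extent,
  equivalent diameter, ellipse-equivalent major/minor axes and their ratio,
  eccentricity (from second central moments), compactness
  P²/(4πA) and its reciprocal form factor, max Feret diameter, and the 7 Hu
  moment invariants of the binary mask. The perimeter estimator is the
  weighted boundary-pixel count of `skimage.measure.perimeter`, which
  slightly over-estimates smooth contours — deliberately, so that
  compactness ≥ 1 holds for rasterized shapes (a rasterized r = 50 disk
  measures ≈ 1.09).
* **Intensity (30):** order statistics (mean, median, std, min, max, range,
  quartiles, MAD), integrated intensity, mass displacement (binary vs
  intensity-weighted centroid), edge statistics on the 1-px morphological
  boundary, interior mean and edge/interior ratio; plus a 4-ring radial
  distribution. Pixels get a normalized distance d = dc/(dc + de) (centroid
  distance vs distance transform to the outside), binned into 4 equal-width
  rings; per ring FracAtD (fraction of total intensity), MeanFrac (FracAtD
  over the ring's area fraction) and RadialCV (CV of mean intensity over 8
  angular wedges). Empty rings yield 0 with a logged warning.
* **Texture (52):** intensities are min–max quantized to 8 gray levels
  within the colony; symmetric co-occurrence matrices are computed at
  distances 1 and 4 px in 4 directions (out-of-mask pixels mapped to a
  discarded sentinel level), and 13 Haralick statistics (ASM, contrast,
  correlation, variance, IDM, sum average/variance/entropy, entropy,
  difference variance/entropy, and the two information measures of
  correlation; log base 2) are summarized per distance by their mean and
  range over directions. Degenerate matrices (single gray level, or colony
  smaller than the offset) produce the analytic limits (ASM 1, contrast 0,
  entropies 0) or zeros with a warning.

These conventions make every oracle in the tests well-defined: translation
invariance holds exactly, multiplying intensities by c scales the intensity
family's absolute statistics by c and leaves shape, RadialCV, MeanFrac and
all texture features unchanged (quantization is per-colony min–max).

## Classification

A 100-tree random forest with √p features per split and a fixed seed (no
hyperparameter search; the protocol, not the model, is the interesting
part). The iterative protocol starts from ≥ 30 labelled examples per class,
validates on successive held-out batches of ≥ 10, folds each validated batch
into the training set (emulating an annotator confirming machine
suggestions), and stops once ≥ 15 cumulative validation examples are
correct — the stopping rule is interpreted as *cumulative correct across
iterations* and is configurable, since "at least 15 correctly classified" is
ambiguous about the reference set. In synthetic mode training labels come
from generator ground truth via nearest-centroid matching (within one true
radius); an interactive labelling hook for real data is the obvious
extension point. Class fractions are reported against the total segmented
colony count; an optional confidence floor can leave colonies unclassified
(off by default).

## SVD profiling

Features are z-scored per measurement (constant measurements dropped with a
warning), then decomposed by thin SVD. Variance explained is σᵢ²/Σσ²; the
sign convention — the largest-|loading| entry of each component is made
positive — makes loadings and top-contributor signs reproducible. Component
scores are unit-norm left singular vectors (not scaled by σ); the Pearson
associations are scale-invariant so this choice is inconsequential.
Associations are computed at colony level (each colony's score against its
well-of-origin phenotype frequency, frequencies broadcast to colonies); a
well-averaged variant sits behind a flag, since either reading is
defensible. Zero-variance frequency vectors are flagged undefined rather
than reported as 0. Phenotype co-occurrence is clustered over the four
frequency-across-wells vectors with correlation distance (1 − r) and average
linkage; the first merge is reported explicitly because "which pair is most
co-occurring" is the scientific output.

## GLM factor signatures

Per phenotype, the per-well count pair (n_phenotype, n_other) is modelled as
binomial with a logit link on MP + DG + EC + SF (all categorical).
"Proportions" and "counts per well" are reconciled by using the well's
colony total as the binomial denominator. Dispersion is estimated from the
Pearson χ² on the count scale and applied as a quasi-binomial scale — this
matters: heterogeneous wells make the dispersion ≈ 15–30 on the default
plate, and unscaled Wald tests would declare everything significant.
Zero-colony wells are excluded and listed. Quasi-separation (unbounded
coefficients) triggers a 0.5 continuity correction of the counts and a
flagged refit.

Least-squares means are marginal predictions averaged on the link scale over
the full level grid of the other factors, back-transformed with delta-method
standard errors; under a balanced one-factor design they reduce exactly to
raw level means. Because link-scale averaging is geometric-mean-like, LS
means for rare phenotypes are lower than arithmetic per-well averages; a
linear-on-frequency family (`family="linear"`) is provided for comparability
with classical least-squares treatments. Tukey–Kramer contrasts use the
pair's own unequal-n standard error, q = √2·|diff|/SE against the
studentized range with k = number of levels and the model's residual df;
for k = 2 this reduces exactly to the unadjusted two-sided test.
Significance codes are `***`/`**`/`*` at 0.001/0.01/0.05.

Stepwise-AIC selection is greedy and bidirectional over two-way interaction
terms with main effects forced in, scored by binomial-likelihood AIC and
refitted with quasi-binomial dispersion at the end. The candidate scope is
limited to two-way interactions by default; the full interaction lattice is
combinatorially fragile at 384 wells. Note the honest operating
characteristics of AIC: a null q-df term is admitted with probability
P(χ²_q > 2q) (≈ 0.16 at 1 df), so "no interaction selected" is *not* a
≥ 90% event under a main-effects truth; the tests check per-term inclusion
rates against this behavior rather than pretending AIC is a consistent
selector.

Calibration, verified by simulation in the test suite at reduced plate
sizes: per-factor quasi-F Wald tests hold ≈ 5% type-I error, and
Tukey–Kramer all-pairs familywise error stays within 0.05 + 2 SE, under
binomial nulls.

## Ranked frequency maps

Wells are ranked by a phenotype's frequency, ties broken by colony count
(descending) then well id (ascending) — a documented total order. The top
ceil(5% · N) wells (20 of 384) are joined to the design and each factor
category's level composition is reported as percentages summing to 100.
Ranking is per *well* by default; a condition-level variant that averages
replicate triplicates first is available (`average_replicates=True`), since
either unit of ranking is defensible. Raising the fraction to 1.0 returns
each category's design marginals exactly, a useful self-check.

## Pipeline

`run_pipeline` chains all stages into a run directory with a manifest
(config hash, per-stage row counts, SHA-256 of every declared output); two
runs with the same config are verifiably identical, and `resume=True`
reloads existing artifacts (feature CSVs are re-read with round-trip float
parsing so resumed analyses are bit-identical). The CLI (`morphoscreen
design|simulate|segment|features|classify|analyze|run`) is a thin wrapper
over these functions.

## Problem sizes

Plate-scale statistical analyses (GLM, ranked maps, clustering, calibration
nulls) run on the counts-only simulation path at the full 384-well design.
Image-based stages are exercised on reduced plates — a 16-well,
~45-colonies/well plate spanning the four phenotype optima for
classification, and a 26-condition stride sample of the default design for
the SVD association structure — chosen so the whole suite and the
acceptance script each run in minutes on a single CPU while keeping every
class abundant enough for the training protocol.

## Known limitations

* The 102-measurement manifest is this package's own documented feature set
  with the standard three-family structure; real screens exported from
  other tools will have different (if analogous) measurement names.
* Segmentation assumes flat background and non-touching colonies; there is
  no declumping or illumination correction.
* The GLM treats wells as independent; there are no plate/batch random
  effects because the simulated data contain none.
* Phenotype renderers are stylized architectures: classifier accuracies on
  synthetic plates are upper bounds, not estimates of real-data accuracy.
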