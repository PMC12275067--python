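# Methods

`voctrace` implements a two-platform quality-assessment workflow for
aromatic plant material: GC–MS flavoromics (which compounds drive flavor and
differ between growing regions) and mid-infrared spectroscopy with
chemometrics (can origin be recognized, and marker concentrations predicted,
from a one-minute ATR-FTIR scan).  Because real cohorts of this kind are
rarely public, the package ships a synthetic-data module that emulates the
statistical structure such studies report, and every stage is validated
against it.

## GC–MS quantification and marker screening

Peak tables are indexed on the Kovats scale by linear interpolation between
bracketing n-alkanes (C7–C40); observed indices are matched to reference
values within ±30 index units.  Quantification is relative to a spiked
isotope internal standard,

    X_i = (V_s · C_s / m) · (I_i / I_s) · 10⁻³   [µg/g]

with V_s the spiked volume (µL), C_s its concentration (µg/mL), m the
sample mass (g) and I the peak areas.  Odor relevance is scored by the
relative odor activity value rOAV = C_i / T_i against the compound's odor
threshold T_i; rOAV ≥ 1 marks a flavor contributor and rOAV ≥ 100 a key
contributor.  rOAV is computed on class-mean concentrations (one value per
compound per class); a per-sample-then-average variant would differ only at
second order in the within-class CV.

A compound is flagged as a differential origin marker when three criteria
hold simultaneously: VIP > 1 in an OPLS-DA model of the autoscaled
samples-by-compounds concentration matrix; maximum class rOAV ≥ 1; and
Welch's heteroscedastic one-way ANOVA p ≤ α (default 0.05, raw p-values;
Benjamini–Hochberg correction is available as an option).  Welch's variant
is used because within-origin concentration spreads differ strongly between
compounds and regions.  With 40 null compounds and raw p-values, roughly
`40·α·P(VIP>1 | p≤α)` chance flags per table (≈0.4 empirically) are the
statistically expected cost of the raw-p criterion; the type-I-control test
therefore bounds the null flag *rate* rather than demanding exact set
recovery on every draw.

## Spectral preprocessing

Five row-wise operators: Savitzky-Golay smoothing (11-point window, cubic),
SG first and second derivatives (scaled by the grid step, so a slope is
returned in absorbance per cm⁻¹ regardless of axis direction), standard
normal variate, and multiplicative scatter correction against the mean
spectrum (when transforming held-out data the calibration reference is
reused, preventing leakage).  SG edges are handled by polynomial fits on the
truncated window.  Smoothing and derivatives are independent method options;
they are not fused.

## Synchronous 2D correlation spectroscopy

For a perturbation series of m spectra, deviations from a reference
spectrum (default: the series mean) form the dynamic spectrum, and the
synchronous map is Φ(n₁,n₂) = f(n₁)ᵀf(n₂)/(m−1).  The 1/(m−1) sample
covariance normalization is the default; a 1/m option exists, and rendering
is min–max normalized per image so the two differ by nothing visible.  Maps
are rendered as 128×128 (configurable) 8-bit RGB rasters through a fixed
diverging blue–white–red colormap, wavenumber decreasing left→right and
bottom→top.

How to build *one* image per sample is genuinely open: a sync map needs m ≥ 2
spectra.  The default mode treats a sample's three replicate scans as the
perturbation series with the cohort mean spectrum as reference, so
between-sample composition differences reach the map; a `self-mean` mode
(deviations about the sample's own replicate mean, i.e. pure noise maps) is
provided for contrast.  An important structural caveat, discovered and
verified on synthetic data: the map is a quadratic form in the deviation
vector, hence blind to its sign.  When classes order all markers identically
their mean spectra deviate from the cohort mean along nearly one axis with
opposite signs, and per-sample sync images of the extreme classes become
nearly identical.  Per-sample 2DCOS imaging is therefore benchmarked on the
origin-specific cohort (below), where each class elevates its own marker
block and deviations are mutually non-collinear.

## Kennard–Stone partitioning

Deterministic max–min selection: the farthest pair first, then repeatedly
the sample maximizing its minimum Euclidean distance to the selected set;
ties break to the lowest index.  Multi-subset ratios (7:3, 7:2:1, 2:1) are
realized sequentially — each subset selected from the remainder, the last
subset being the remainder — with largest-remainder rounding of the subset
sizes (so 166 at 7:2:1 gives 116/33/17; explicit size overrides are accepted
to reproduce externally reported counts).

## Latent-variable models

PLS components are extracted by NIPALS with deflation of both blocks; class
membership is coded as centered one-hot columns and predicted by argmax of
the continuous response.  OPLS-DA removes predictor variation orthogonal to
the class coding (orthogonal weights built from the difference between the
X-loading and the predictive weight, one component at a time) before the
predictive fit; the predictive component count defaults to k−1 for k
classes, and the orthogonal count is chosen by maximizing cross-validated
Q², capped at 5.  Metrics: R²X (cumulative, predictive + orthogonal blocks),
R²Y, and Q²/RMSE_CV from 7-fold venetian-blind cross-validation with
deterministic folds.  VIP follows the standard normalization
VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a), whose squares average to 1.

The permutation test refits the fixed model specification under label
permutation (default 200 draws), regresses permuted R²Y and Q² on the
correlation between permuted and true class coding, and declares the model
valid iff the Q²-regression intercept is below 0.05 and the observed Q²
exceeds all but at most 5 % of permuted Q² values.  Both intercepts are
reported; only the Q² rule gates validity.

## SVM hyperparameter search

RBF-SVM (one-vs-one) with fitness = stratified 5-fold CV accuracy on the
training set only (folds shrink automatically when a class has fewer
members).  Three strategies over (c, g): exhaustive log₂ grid 2⁻¹⁰..2¹⁰ at
step 2^0.5 with ties resolved toward smaller c then g; a real-coded GA
(tournament-of-3 selection, BLX-0.5 crossover, Gaussian mutation, elitism
of one) on linear ranges c∈(0,100), g∈(0,1000); and the canonical grey wolf
optimizer on (10⁻⁵, 10³)² searched in log₁₀ coordinates because the box
spans eight decades — α/β/δ leaders, control parameter decaying linearly
2→0, positions clipped to the box.  Defaults: GA 20×100, GWO 20×50.  All
strategies are seeded and their best-fitness traces are monotone by
construction.  The factorial pipeline crosses {all variables, VIP > 1} with
{GS, GA, GWO} and reports train/test ACC, macro F₁/P/R and the best (c, g)
per cell.

## Residual CNN

A compact ResNet classifies per-sample 2DCOS images: 3×3 stem convolution,
four stages of three identity-shortcut residual blocks each (12 blocks;
conv-BN-ReLU-conv-BN plus skip, then ReLU), stride-2 convolutions between
stages, global average pooling, linear softmax head.  Channel widths default
to (16,32,64,128) at 128×128×3; both are configurable.  Training is SGD
with momentum 0.9, initial learning rate 0.01, L2 weight decay 10⁻⁴ on
convolution/linear weights, cross-entropy loss, early stopping on a test
accuracy plateau.  The implementation is pure numpy (im2col convolutions
with hand-written backward passes, verified against finite differences in
the test suite) and fully deterministic under the config seed.  Benchmarks
run scaled down — 32×32 inputs, widths (8,16,32,64), 60 samples — sizes at
which a single CPU trains the model in well under a minute.

## PLSR calibration

One PLS1 model per target compound on centered data; the LV count minimizes
7-fold venetian-blind CV RMSE under the one-standard-error parsimony rule
(cap 10).  Optional VIP > 1 variable selection with refit and LV
reselection.  Reported per evaluation set: R² = 1−SSE/SST, RMSE = √(SSE/n),
and RPD = SD(reference, n−1 denominator)/RMSE; R²_P > 0.8 with RPD_P > 2 is
flagged as fit for practical use.  Prediction-set metrics use only
calibration-set centering.

## Synthetic data: what it emulates, and what it does not

Three origin classes (default cohort 20/15/15 samples).  A 48-compound VOC
panel: eight markers carry class-ordered mean concentrations at the µg/g
scale of published aroma-marker tables (ordering origin_A > origin_C >
origin_B; e.g. 0.47/0.22/0.37 µg/g), with odor thresholds spanning
10⁻¹¹–10⁻⁵; the other 40 compounds share one mean across classes.
Concentrations are lognormal with a CV parameterization (positive,
right-skewed, mean-preserving; default CV 10 %).  Analyte peak areas are
back-computed from the internal-standard relation, so quantification
recovers the planted truth to machine precision — an end-to-end oracle for
the GC–MS stage.

Spectra are linear mixtures of fixed per-compound Gaussian band profiles
(3 bands each, centers 500–3900 cm⁻¹, widths 20–80 cm⁻¹) on the descending
4000→400 cm⁻¹ grid (default step 2 cm⁻¹, 1801 points; tests run coarser
grids since every operator is resolution-agnostic), plus a per-sample
polynomial baseline (degree 2), a per-sample multiplicative scatter factor
(SD 5 %), and per-replicate additive noise (SD 0.003) — three replicate
scans differing only in noise, so replicate averaging, SNV and MSC each
have exactly one distortion to remove.

Two named presets define benchmark conditions once:

* `well_separated_config` — CV 2 %, scatter 2 %, noise 0.001: tight
  biological replication under which between-origin differences dominate,
  the regime where OPLS-DA is expected to reach R²Y > 0.9, Q² > 0.7.
* `origin_specific_config` — each class elevates its own three-marker block
  (0.6 vs 0.2 µg/g, 24 compounds): non-collinear class deviations for the
  2DCOS/CNN benchmark (see the sign-blindness caveat above).

For PLSR parameter recovery the panel is reduced to 24 compounds: with
n = 60 and a 2:1 split, the 40-sample calibration set must exceed the number
of independently varying spectral sources for the planted linear signal to
be identifiable; with 48 sources the error floor is interference between
compounds, not noise, and no preprocessing can remove it.

The generator does not emulate: instrument drift, water-vapor/CO₂ bands,
detector nonlinearity, wavelength miscalibration, correlated compound
concentrations (biosynthetic pathways), retention-time shifts, or
censored/missing peaks.  Passing tests therefore demonstrate correctness of
the algorithms and sane statistical behavior under the stated noise model —
not field performance on real spectra.

## Numerical choices

NIPALS tolerance 10⁻¹⁰ (max 1000 iterations); constant columns dropped with
a warning before scaling; venetian-blind folds are position-deterministic;
Welch ANOVA treats groups whose variances are numerically zero (relative
tolerance 10⁻¹²) as degenerate and excludes the compound with a warning;
MSC rejects slopes below 10⁻⁸; Kennard-Stone ties break to the lowest
index; one global seed fans out to stage seeds through SHA-256, keeping
every stage independently reproducible.

## Known limitations

* OPLS-DA numbers are not expected to equal those of proprietary software
  to the digit (component-selection and scaling conventions differ); the
  implementation is validated against algebraic oracles instead.
* The permutation-validity rule operationalizes a visual plot criterion;
  other operationalizations (e.g. quantile-only) are defensible.
* Per-sample 2DCOS imaging carries the sign-blindness caveat above; for
  cohorts with a single dominant ordering axis, spectrum-based classifiers
  (OPLS-DA, SVM) are the appropriate tools and the image branch is
  secondary.
* The GA searches its linear ranges as specified; on multi-decade boxes the
  GWO's log-space search is structurally advantaged, which mirrors how the
  two optimizers are reported to behave in practice.
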