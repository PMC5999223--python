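# Methods

## The heterogeneity statistic

A thymectomy specimen is worked up into many tissue blocks; every stained
section (slide) yields one value per histomorphological variable (a grade,
a percentage, a count).  Location parameters (mean, median, mode) collapse
these into a per-case value but discard *spatial* heterogeneity — how
unevenly a feature is distributed across the specimen.  `thymentropy`
quantifies that heterogeneity as an entropy, one number per case and
feature, which can then enter ordinary statistics as a covariate.

The computation has three steps.

**1. Discretization into levels.**  Each raw value is mapped to an integer
level by a fixed, a-priori scheme (never data-driven):

| variable class | scheme | L |
|---|---|---|
| follicle counts | width-5 bins over [0, 50), left-closed/right-open | 10 |
| visual gradings (atrophy, follicular hyperplasia) | identity on grades 0–4 | 5 |
| estimated percentages (fat content, B-cell infiltrate) | width-10 % bins over [0, 100] | 10 |

Levels are 0-based; the top edge (50 follicles, 100 %) clamps into the
last level.  Follicle counts formally range to 100 but are binned over
0–50; values in (50, 100] clamp into the top level with a warning.  The
percentage scheme is a design choice of this package (the binning of the
percentages is motivated but not printed in full in the source analysis);
10 levels mirror the follicle choice and the common reduction of grayscale
intensities to ~16 levels in image processing: coarse enough that a 5 % vs
8 % estimation difference does not register, fine enough not to flatten
real heterogeneity.  All schemes are configurable and serializable to
YAML.

**2. Level distribution.**  For one case and feature, the m contributing
slides (measurement points) give an empirical level distribution with raw
relative frequencies p_k = c_k / m.  No smoothing, no bias correction.

**3. Entropy.**  Two estimators are reported, in bits:

* the **point-sum statistic** (the default downstream predictor):
  H = −Σ_{i=1}^{m} p_i log₂ p_i, one term per *measurement point*, p_i the
  empirical frequency of point i's level.  In level terms
  H = −m · Σ_k p_k² log₂ p_k; for a fixed level distribution it grows
  linearly with m.
* the **plug-in Shannon entropy** over levels, Ĥ = −Σ_k p_k log₂ p_k,
  bounded by log₂ min(m, L).

Both are exactly 0 iff all points share one level.  The reference maximum
H_max(m, L) = m · (1/L) · log₂ L treats every point as equiprobable over
L levels (H_max(6, 5) = 2.786, H_max(6, 10) = 1.993, H_max(3, 10) =
0.9966 bit).  Two properties deserve emphasis because they are easy to get
wrong:

* H_max is the m → ∞ limit of the point-sum statistic per point (times m)
  under uniform levels, but **not a finite-m supremum**: two equally
  frequent levels at m = 6 give H = 3.0 bit > H_max(6, 10).  Reports
  therefore never normalize by H_max.
* The point-sum statistic is **not monotone** in distributional spread:
  −Σ p² log₂ p is maximized between concentration and uniformity (0.5 per
  point for two balanced levels vs 0.332 for uniform over 10).  The
  Shannon column is the estimator with the conventional ordering.

## Data model

Two delimited-text tables: a slide table (`case_id, region, slide_id,
staining`, plus one column per registered variable; 16 variables covering
gradings, percentages, counts and areas) and a per-case clinical table
(age, sex, BMI, baseline QMG score, binary 3-point QMG drop and minimal
manifestation status at months 12–36, disease duration, pre-/post-operative
prednisone load in grams of area-under-the-dose-curve).  Reading is strict
about schema and tolerant about rows: unparseable or out-of-range cells
reject the row with a named diagnostic.  A slide missing a variable simply
drops out of that variable's measurement points (m shrinks); nothing is
imputed.  Region codes are validated against a configurable vocabulary
(central plane A plus right/left upper/lower) but carried as metadata only
— every slide is one measurement point regardless of region.

The four default entropy features read follicle count and follicular
hyperplasia grade from CD23-stained sections and intrathymic fat and
atrophy grade from HE-stained ones.

## Statistical layer

* **Group comparisons** gate on Shapiro–Wilk per group at α = 0.05: both
  normal → Welch t-test, otherwise Wilcoxon rank-sum (Mann–Whitney) with
  continuity correction; a constant group forces the rank test.  Welch and
  the rank-sum flavor are this package's choices where the procedure was
  underspecified.
* **Correlations** are Pearson with the two-sided t-transform p-value.
* **Explorative grid**: each of six clinical endpoints is modeled on the
  four entropy features plus intercept — logistic regression for the two
  binary endpoints, OLS otherwise — on complete cases (listwise deletion).
  Cells are per-coefficient two-sided p-values, starred at 5 %.  No
  multiple-testing correction is applied, deliberately: the grid is a
  hypothesis-generating screen, and its p-values must be read as such.
  Logistic separation or non-convergence flags the row (NaN cells) rather
  than aborting.
* **Single-predictor refits** re-estimate each significant linear cell
  alone (slope, p, R²).
* **k-fold CV** (default k = 3) shuffles cases with a fixed seed into
  near-equal folds (remainder distributed one per fold) and reports
  held-out MSE per fold against the full-data training MSE as an
  overfitting check.  Identical seeds give byte-identical reports.
* **Sample-size diagnostic**: Pearson correlation between a feature's
  per-case entropy and m.  It defaults to the Shannon estimator because
  the point-sum statistic scales with m mechanically, which would make the
  diagnostic vacuous.

## Synthetic cohort generator

The generator emulates the structure of the real cohort: 55 cases, blocks
per case ~ round N(11, 5) truncated at 3, one HE and one CD23 slide row
per block, regions assigned round-robin.  Heterogeneity is parameterized
where the statistic lives: per case and feature a level-probability vector
is drawn from a symmetric Dirichlet(α) over the feature's L levels, slide
levels i.i.d. from it, raw values uniform within the level's bin (integer
for counts).  Because back-transformation preserves the level, the
pipeline recovers the generator's true entropies exactly (r = 1), which
the tests exploit.

Defaults, chosen once: α = 0.04 for all features, calibrated so the
per-case Shannon entropy of the follicle count lands at ≈ 0.52 ± 0.5 bit,
the scale observed in the real cohort; demographics use MG-typical
marginals (≈ 65 % female, age ≈ 44 ± 13 clipped to 18–68, BMI ≈ 27 ± 5);
continuous endpoints are linear in the case's true point-sum entropies
plus Gaussian noise, binary endpoints are Bernoulli with a logit-linear
rate.  The single default planted effect — intrathymic-fat entropy on the
post-operative prednisone load, β = 0.8 g/bit with residual sd 9 g — is
sized for ≈ 90 % nominal power of a single-predictor refit at 200 cases
(β · sd(H) / σ ≈ 0.23 with sd(H) ≈ 2.6 bit).

What the generator does *not* emulate: spatial autocorrelation between
regions (slides are exchangeable; the real work-up may not be), dependence
between the four features (independent by default, consistent with the
observed lack of cross-feature correlation), measurement error in the raw
gradings, and case-level missingness patterns.  Passing tests on synthetic
cohorts therefore validate the computational chain and the statistical
calibration of the methods, not any biological claim about real specimens.

## Problem sizes used by the validation suite

Parameter recovery and the sample-size diagnostic run 100 replicates of
200-case cohorts; type-I control runs 100 replicates of 55-case null
cohorts; CV calibration uses n = 300 with noise variance 4; the point-sum
implementation is checked against a literal per-point oracle on every
level sequence with m ≤ 8 over a 5-level alphabet (~4.9 × 10⁵ sequences).

## Known limitations

* **Plug-in bias couples entropy to m.**  Ĥ is biased low by roughly
  (K − 1)/(2m ln 2); with m ranging 3–25 across cases the bias varies by
  ~0.2 bit and induces a mechanical positive correlation of r ≈ +0.1
  between estimated entropy and m even when true heterogeneity is
  independent of m by construction.  Consequently the independence
  diagnostic is expected to read |r| ≲ 0.15 (non-significant at n = 55)
  *typically*, not almost surely; cohorts with many small specimens should
  interpret it cautiously.  A Miller–Madow correction removes only part of
  the effect at m = 3 and is deliberately not applied (raw frequencies
  throughout).
* **Strict per-cell type-I bands flake by multiplicity.**  The null-cohort
  calibration check bounds each of 24 grid cells by the central 95%
  binomial band of Binom(100, 0.05); even under exact calibration all 24
  cells stay inside simultaneously only ~⅔ of the time.  The package's
  OLS cells are exact under the generator's Gaussian noise; single-cell
  excursions at the band edge are expected behavior of the check, not
  evidence of miscalibration.
* The point-sum statistic has no finite-m upper bound tied to H_max (see
  above); comparisons across cases with very different m should prefer the
  Shannon column.
* Logistic grid rows at n = 55 rely on Wald asymptotics; with strongly
  concentrated entropy distributions an occasional singular fit is flagged
  rather than estimated.
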