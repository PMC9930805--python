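# Methods

`dentage` implements a complete dental-age (DA) estimation workflow for
children aged 6–15: scoring of tooth developmental stages, a sex-specific
quadratic calibration of score on chronological age (CA) with analytic
inversion, a synthetic cohort generator emulating the reference study
design, and the method-agreement evaluation protocol (MD/MAD with
normality-gated paired tests, Cohen's kappa for observer agreement).

## Staging and scores

Stages are read for the seven left mandibular permanent teeth, FDI 31–37.

* **Demirjian system.** Eight stages A–H per tooth (plus "no
  calcification", coded `0`). Each (tooth, stage, sex) carries a
  self-weighted score; the seven scores sum to a 0–100 maturity score,
  which is converted to DA by piecewise-linear interpolation in an
  age-norm table.
* **Nolla system.** Each tooth is staged on a 0–10 scale with fractional
  readings restricted to the lattice {k, k+0.2, k+0.5, k+0.7} (k = 0..9)
  plus 10.0. The seven values are summed (0–70) and converted to DA via
  age norms.

Chronological age is computed as calendar days between birth and
examination divided by 365.25, the standard forensic decimal-year
convention; rounding happens only at presentation.

Scores outside a norm table's tabulated range are **clamped** to the
boundary age and flagged; percentile norms do not support extrapolation.

### Surrogate lookup tables

The packaged CSVs in `dentage/data/` (`*_synthetic.csv`, with a SHA-256
manifest) are **synthetic surrogates**, not the historical reference
tables. They are constructed to satisfy every structural property the
methods rely on: per-tooth stage scores monotone in stage order, stage-H
scores summing to exactly 100 per sex, age norms strictly increasing in
age and non-decreasing in score, and earlier female development. Demirjian
stage scores are a per-tooth weight times a monotone stage fraction;
Demirjian age norms follow a logistic maturity curve (midpoint 9.2 yr
male, 8.8 yr female); Nolla age norms follow concave quadratics capped
below 70. Absolute DA values produced through these tables are therefore
internally consistent but not comparable to published population studies;
everything that depends only on table *structure* (monotonicity,
round-trip interpolation, clamping, maturity normalisation) is exact.

## Quadratic calibration (the "new method")

Per sex, the Nolla sum score S is regressed on CA by ordinary least
squares on the design (1, CA, CA²):

    S = a + b·CA + c·CA²,   R² = 1 − SSres/SStot.

Reference coefficients for northeastern Chinese children are a=4.916,
b=7.783, c=−0.232 (males, R²=0.931) and a=−2.751, b=9.785, c=−0.331
(females, R²=0.921). With b > 0 > c the curve rises to a vertex at
v = −b/(2c) (16.77 yr male, 14.78 yr female); the left branch is the
biologically meaningful one and DA is obtained analytically:

    DA = v − sqrt((S_v − S) / (−c)),   S_v = a − b²/(4c).

This vertex form is algebraically identical to the quadratic-formula root
(−b + sqrt(b² − 4c(a−S)))/(2c) but numerically stable near the curve
maximum, where the other form cancels catastrophically. Scores above S_v
clamp to the vertex age; results are further clamped to the calibration
age domain; both clamps are flagged. Curve-family screening
(linear/quadratic/cubic R²) is exposed as a convenience, but the
calibration itself is always quadratic, the family that maximised R² in
the reference data.

Conversion tables tabulate (age, predicted score) on a uniform grid,
default 0.1 yr over the calibration domain; the grid is a presentation
choice, since inversion is closed-form.

### Numerical notes

* The round-trip identity invert(predict(x)) = x holds to below 1e−9 yr
  everywhere except within ~1e−4 yr of the vertex, where the inverse map
  has unbounded derivative and double precision fundamentally limits the
  identity to ~sqrt(machine epsilon) (~5e−8 yr). Verification grids
  therefore stop 1e−4 yr short of the vertex.
* A fit with fewer than three distinct ages raises a rank-deficiency
  error; constant scores yield a degenerate flag with undefined R².
* c = 0 degenerates to a linear model and is flagged; inversion requires
  c < 0.

## Evaluation protocol

Accuracy is summarised per sex × nine 1-year age bins ("6.01–7.00" …
"14.01–15.00"), per sex total, and grand total:

* MD = mean(DA − CA) with SD and 95% CI (t-quantile, n−1 df); MD > 0
  means overestimation.
* MAD = mean(|DA − CA|) with SD; MAD ≥ |MD| always, with equality iff all
  differences share one sign.

CA is rounded to two decimals with **half-up** decimal semantics before
binning, so 7.005 falls in 7.01–8.00 as the bin labels imply.

The paired location test is gated on normality *within each group*: a
one-sample Kolmogorov–Smirnov test of the differences against
Normal(mean, SD) with parameters estimated from the sample. Plugging in
estimated parameters makes the KS p anti-conservative (the Lilliefors
caveat); this is retained deliberately as the field-standard practice the
protocol emulates, and is only a gate, not a reported inference. p > 0.05
selects the paired t-test, otherwise the Wilcoxon signed-rank test.
Groups too small for the KS test (n < 4) default to the t-test; all-zero
differences give p = 1 by convention.

**Wilcoxon policy.** Zeros are dropped, tied absolute differences get
mid-ranks, and for n ≤ 25 the exact conditional null distribution of W+
is built by dynamic programming over the doubled (hence integer)
mid-ranks — each rank enters the sum independently with probability 1/2 —
with the two-sided p = 2·min(P(W+ ≤ w), P(W+ ≥ w)) capped at 1. Above
n = 25 a tie-corrected normal approximation (no continuity correction) is
used. The exact path is implemented in-package because library routines
decline exact p-values under ties; tests cross-check it against full
2^n sign-pattern enumeration and, on tie-free data, against
`scipy.stats.wilcoxon`.

**Kappa.** Observer reproducibility uses unweighted Cohen's kappa,
κ = (p_o − p_e)/(1 − p_e), pooling all (subject, tooth) stage assignments
into one rating sequence per method (e.g. 50 radiographs × 7 teeth = 350
items). Pooling is a design choice; per-tooth averaging is a defensible
alternative the protocol does not use. κ is undefined (NaN) when both
raters are constant and identical.

## Synthetic cohort generator

The generator emulates the reference study's design, not tooth biology:

* **Design.** Nine 1-year bins × sex with fixed cell counts (default:
  20/18 training and 9/8 testing males/females in 6.01–7.00, 20/20 and
  10/10 elsewhere), totalling 358 training + 177 testing = 535. Ages are
  discrete-uniform on the 0.01-yr grid within each bin — the simplest
  distribution consistent with "roughly even" recruitment and the bin
  labels.
* **Latent sum score.** S = a + b·CA + c·CA² + N(0, σ), clipped to
  [0, 70], with the reference coefficients as defaults. σ defaults to 2.5
  score units, which puts the synthetic training R² near the reference
  0.92–0.93 range; it is a tunable, not a fitted value.
* **Tooth allocation.** The target sum is split across teeth by a weight
  profile (default uniform 1/7, the only profile for which a full-maturity
  sum of 70 maps to seven 10.0s without clipping), plus per-tooth Gaussian
  jitter (default SD 0.25 stages) for stage-level heterogeneity. Values
  are snapped to the Nolla lattice with an error-carry scheme — each
  tooth's snapping residual is added to the next before snapping — so the
  realised sum stays within one lattice gap (≤ 0.15) of the target when
  jitter is off. The unsnapped sum is retained as a diagnostic column.
* **Companion Demirjian stages** are derived from the maturity fraction
  m = nolla/10 through eight equal-width bins (m = 0 → no calcification,
  else stage ⌈8m⌉). Real stage systems are not affinely related; this
  mapping only guarantees the structural properties downstream code needs
  (monotone correspondence, correct extremes).
* **Split.** The 7:3 train/test partition is drawn per cell, exactly
  matching the design counts, deterministic under the seed. A single seed
  feeds one `numpy` Generator passed explicitly through every drawing
  operation.

### What passing synthetic tests does and does not show

The generator reproduces the statistical structure the analysis assumes:
stratified ages, a quadratic mean score with additive homoscedastic
noise, lattice quantisation. It does **not** reproduce heteroscedastic
maturation noise (real sum scores saturate near 70 with shrinking
variance), inter-tooth correlation beyond the shared sum, observer error,
or population differences. Consequently end-to-end results quantify
self-consistency of the pipeline, not field accuracy. One structural
consequence: because the calibration slope b + 2c·CA falls below ~1
score/yr near age 15, homoscedastic score noise of 2.5 maps to DA errors
exceeding 1 yr in the oldest bins (bounded only by the vertex and domain
clamps). The synthetic grand-total test MAD (~0.77 yr) is therefore
larger than the reference study's 0.49 yr, and the per-seed grand-total
MD, while unbiased (mean ≈ +0.01 yr over 200 seeds), has a seed-level SD
of ~0.09 yr driven by the same amplification.

## Problem sizes

Default runs use the full 535-subject design; the end-to-end evaluation
in tests and the acceptance script repeats it over 20 seeds, which
completes in a few seconds. Exact Wilcoxon enumeration is capped at
n = 25 (DP) in the implementation and n ≤ 10 (2^n enumeration) in the
oracle tests.

## Known limitations

* The packaged staging tables are synthetic surrogates (above); DA values
  from the *original* Demirjian/Nolla lookups are internally consistent
  only.
* No confidence or prediction intervals are attached to calibrated DA
  estimates.
* The KS normality gate uses estimated parameters (anti-conservative).
* The calibration inverts a score fitted on CA rather than regressing CA
  on score; near the curve vertex this inverse is ill-conditioned, which
  is intrinsic to the method, not the implementation.
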