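# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical and design decisions a maintainer
would want to know.

## The two-sample MR model

A genetic variant j is a valid instrument for an exposure X on an outcome
Y if it is associated with X, independent of confounders of X–Y, and
affects Y only through X. With summary statistics from two non-overlapping
GWAS — exposure effects β̂x_j (SE sx_j) and outcome effects β̂y_j (SE
sy_j) on a common effect allele — the working model is

    β̂x_j ~ N(γ_j, sx_j²),      β̂y_j ~ N(θ·γ_j + α_j, sy_j²),

where θ is the causal effect of interest and α_j the variant's direct
(pleiotropic) effect on the outcome. IVW assumes α_j = 0 on average
(balanced pleiotropy); MR-Egger estimates the average α as its intercept
and remains consistent for θ under InSIDE (α uncorrelated with γ); the
weighted median tolerates up to half the weight coming from invalid
instruments.

All estimators use first-order weights w_j = β̂x_j²/sy_j², i.e. the
exposure betas are treated as fixed when weighting ("NO Measurement Error"
approximation). This is standard for summary-data MR and is accurate when
instruments are strong; with weak instruments it produces the familiar
regression-dilution bias toward the null, which is visible (and small,
|bias| < 0.01 at per-variant F ≈ 125) in the calibration benchmarks.

## Estimators

* **Wald ratio**: θ̂_j = β̂y_j/β̂x_j with SE sy_j/|β̂x_j| (first-order
  delta method; the exposure-side term is deliberately omitted, consistent
  with the weighting above).
* **IVW**: θ̂ = Σw_jθ̂_j / Σw_j. Fixed-effects SE (Σw_j)^(-1/2);
  multiplicative random effects inflate it by max(1, √(Q/(k−1))), with Q
  computed about the fixed-effects estimate. The dispersion is floored at
  1 so random effects can never claim more precision than fixed effects.
  The `auto` model applies random effects at k ≥ 4 and fixed effects at
  k ≤ 3 — the convention used in the liver-enzyme analyses this package
  was built around. Additive random effects are not implemented.
* **Weighted median**: order the Wald ratios, form cumulative weights
  p_j = Σ_{i≤j} w_i − w_j/2 (normalized), and interpolate linearly at 1/2.
  The SE is the standard deviation of the point estimate over a seeded
  parametric bootstrap (default 10,000 replicates) resampling
  β̂x_j ~ N(β̂x_j, sx_j) and β̂y_j ~ N(β̂y_j, sy_j); the closed-form
  alternative is not used consistently across the literature, and the
  bootstrap makes the assumptions explicit. The point estimate is
  deterministic; only the SE is stochastic (and seeded).
* **MR-Egger**: weighted least squares of β̂y on β̂x with free intercept
  and weights 1/sy_j², solved from the 2×2 normal equations. SEs are the
  model-based WLS standard errors times max(1, √(RSS_w/(k−2))) —
  multiplicative overdispersion, floored at 1. P-values are two-sided
  normal for both slope and intercept. Because the Egger fit is not
  invariant to allele orientation, the set is first put in the canonical
  orientation with all β̂x ≥ 0 (joint sign flips, which leave every Wald
  ratio unchanged); variants with β̂x exactly 0 are dropped there.
* Confidence intervals are normal-theory beta ± z₀.₉₇₅·SE throughout.

Known calibration consequences, quantified by simulation in this
repository: the floored random-effects IVW test is slightly conservative
under an exact null (exact size 4.32% at k = 50, by numerical integration
of E[2Φ(−z₀.₉₇₅·max(1, √(Q/df)))] with Q ~ χ²(k−1)); the Egger intercept
test with normal p-values and an estimated dispersion is slightly
anti-conservative (size ≈ 6.7% at k = 50 with pleiotropy dispersion
comparable to the outcome SEs, measured over 200,000 replicates). Both
are properties of the stated conventions, not bugs; switching the Egger
p-values to t(k−2) would remove roughly half the inflation but would
depart from the normal-theory convention used across the suite.

## Harmonization

Allele resolution order for an exposure/outcome record pair (same rsid):

1. identical allele pair → unchanged;
2. swapped pair → negate β̂y, invert EAF;
3. strand-complement pair (A↔T, C↔G relabelling), possibly swapped →
   relabel, then as 1/2. Complement matching is attempted only when the
   labels do not match directly;
4. palindromic pair (A/T or C/G, label comparison uninformative) → orient
   so both EAFs fall on the same side of 0.5, negating β̂y when the
   orientation flips; dropped as ambiguous if either EAF lies in
   [0.42, 0.58] or is missing;
5. anything else → dropped as an allele mismatch.

After alignment, any retained pair with |EAF_x − EAF_y| > 0.20 is dropped
as discordant (likely a mislabelled or population-divergent variant). The
palindromic band and the discordance threshold are judgement calls — the
analyses this mirrors align palindromes "by EAF" and drop "rather
different allele distributions" without stating numbers — so both are
config-exposed (`palindromic_eaf_band`, `eaf_discord_threshold`). Missing
EAF on a non-palindromic pair is tolerated (alignment proceeds on allele
identity alone); on a palindromic pair it forces a drop.

Every action, including every drop with its reason, is recorded in an
audit log emitted as a TSV next to the results.

## Instrument selection

Greedy clumping takes the remaining variant with the smallest p-value and
removes everything with r² above the threshold (default 0.01) to it,
repeating until exhausted; genome-wide significance (default p < 5×10⁻⁸)
is applied first and can be disabled (`p_threshold: null`) when the input
is already a curated panel. Equal p-values are broken lexicographically by
rsid so results cannot depend on file row order. Pairs absent from the
(sparse, symmetric) LD table count as r² = 0.

Variants missing from the outcome GWAS are replaced by their highest-r²
available proxy above r² = 0.9, using the proxy's own summary statistics
unchanged — at that correlation, rescaling effects by r² changes estimates
by less than their SEs, and using the proxy's own record is what the major
MR platforms do. Proxies must be present in both GWAS (the exposure GWAS
is the natural source of proxy candidates). Members with no usable proxy
are dropped and logged. Proxy substitution runs before harmonization, so a
proxy is harmonized exactly like any other variant. Exclusion lists
(named rsid sets per exposure) implement pleiotropy sensitivity analyses;
excluding an rsid that is not in the set warns rather than errors, because
exclusion lists are written against the full panel.

## Instrument strength and power

F = (r²/k)/((1−r²)/(n−k−1)) is the joint F statistic of the k-instrument
allele score; with the published r² values (0.001, 0.035, 0.019 for
ALT/ALP/GGT panels of 4/14/26 instruments in a GWAS of 61,089) it gives
15, 158 and 45. Variance explained, when recomputed from records, uses the
independent-instrument approximation r² = Σ 2·EAF_j(1−EAF_j)·β̂x_j²,
which assumes a unit-variance exposure. The minimum detectable effect at
two-sided level α and target power uses the approximation that a
summary-data MR analysis has the precision of the corresponding
individual-level regression on n_outcome·r² subjects:
b_min = (z_{1−α/2} + z_{power})/√(n_outcome·r²); at n = 681,275 this gives
0.11, 0.02 and 0.02 SD for the three panels. Both formulas assume
unit-variance exposure and outcome and a normal test statistic; no
binary-outcome variants are provided.

## Synthetic data

The generator draws EAF ~ U(0.05, 0.95), instrument effects
γ_j = |N(0.05, 0.02)| (positive sign convention — orientation handling is
exercised separately by `scramble_alleles`), direct effects α_j that are
zero, N(0, σ_α) or N(μ_α, σ_α), and observed betas from the working model
with SEs 1/√(2p(1−p)n) — the unit-variance-trait approximation, chosen
because it produces realistic weight heterogeneity across allele
frequencies. Default conditions: k = 50 instruments, exposure and outcome
GWAS of 100,000, θ = 0.2, 15% palindromic variants, and a small
cross-study EAF jitter (SD 0.005). All randomness flows from one seed
through named sub-streams, so studies regenerate bit-identically.

`scramble_alleles` re-codes outcome records adversarially (swaps, strand
flips, optional EAF perturbation of palindromes into the ambiguous zone)
without touching the truth; harmonization must — and, by test, does —
undo the unambiguous re-codings exactly, bit for bit.

`make_liver_enzyme_fixture` builds three liver-enzyme-like panels whose
*realized* Σ2p(1−p)β̂x² is calibrated exactly to the target r² (the
instrument-effect scale is the positive root of the induced quadratic,
solved after sampling the noise so β̂x = γ + ε still holds); this pins the
joint F statistics to 15/158/45 at the fixture sample sizes. The fixture
panels contain no palindromic variants so the grid's instrument counts are
exact; one GGT variant is absent from the outcome with an r² = 0.95 proxy
available, another is absent with no proxy (the panel shrinks from 26 to
25), and one variant is shared between the ALT and ALP panels with a
single consistent outcome record. Fixture files are generated at run time
from a fixed seed rather than shipped, and regeneration is deterministic.

What the generator does **not** emulate: LD between instruments (panels
are independent by construction, as after clumping), population
stratification, sample overlap between the two GWAS, non-normal effect
distributions, winner's-curse selection of instruments, and INDELs or
multi-allelic variants. Passing calibration tests therefore demonstrate
correctness of the estimators under the stated sampling model, not
robustness to those real-data complications.

## Calibration benchmarks and their problem sizes

The benchmark module measures, under the default conditions: IVW bias and
95% CI coverage at θ = 0.2 (1,000 replicates); IVW type-I error at θ = 0
(4,000 replicates); Q-test size at k = 20 (2,000 replicates); and the
Egger intercept test's size under balanced pleiotropy (20,000 replicates)
and power under directional pleiotropy α ~ N(0.02, 0.005) (500
replicates). Estimator calibration panels contain no palindromic variants
so each replicate keeps exactly k instruments — harmonization attrition is
benchmarked separately. The Q-test null is evaluated at θ = 0, where the
weighted Wald-ratio residuals are exactly standard normal and the test's
size isolates the Q statistic itself from weak-instrument noise in β̂x.
Rates whose true values lie near an assertion band edge (the two size
checks above; see the exact/high-precision values quoted under
"Estimators") use the larger replicate counts so that Monte-Carlo error is
small relative to their distance from the edge; the remaining checks use
1,000–2,000 replicates. The balanced-pleiotropy size check uses the same
α dispersion as the directional power check with the mean removed, so that
directionality is the only difference between the two conditions.

## Degenerate inputs and tie-breaks

* β̂x = 0: Wald ratio undefined → error for a single variant, audited drop
  during orientation.
* k = 1: IVW degenerates to the Wald ratio; heterogeneity undefined.
* k = 2: weighted median and Egger are refused (k ≥ 3 required); the
  results table simply omits those rows, mirroring the convention of
  reporting only IVW for two-variant sensitivity panels.
* Zero variance in β̂x: Egger design singular → explicit collinearity
  error.
* Q = 0: I² = 0, p = 1. I² is floored at 0 and reported as a percentage.
* Equal clumping p-values: lexicographic rsid order. Equal proxy r²:
  lexicographic rsid order.
* Duplicate rsids in a file: a validation error (duplicates signal a
  build/merge mistake), never silent de-duplication. Validation reports
  every offending row, not only the first.
* Exposure betas are treated as opaque "log-exposure units"; the optional
  `rescale` multiplier (default 1.0) lets users re-express estimates, e.g.
  per doubling of the exposure, and applies to slopes but not to the Egger
  intercept (which lives on the outcome scale).

## Limitations

Individual-level MR (two-stage least squares), multivariable MR,
bidirectional MR, mode-based and penalized/robust estimators, leave-one-out
analyses, binary-outcome power formulas, reference-panel LD computation,
VCF/bgen parsing and any remote data retrieval are out of scope. The
analytic F and power formulas accept the published r² directly; whether a
published r² was itself computed from standardized betas is outside the
package's control.
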