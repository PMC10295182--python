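# Methods

This note documents the models, conventions and numerical choices behind
`benthet`, and what its synthetic-data tests do and do not demonstrate.

## Substrate-heterogeneity classification

A video transect is reduced to a count tuple (O, F, D, V): the number of
feature classes scored occasional, frequent, dense and very dense (absent
features are not counted; at most nine features exist). The default decision
table, evaluated with first-match precedence none → low → medium and "high"
as the catch-all, is:

| class | predicate on (O, F, D, V) |
| --- | --- |
| none | V = 1, D = 0, F = 0, O ≤ 1 |
| low | V = 1, D = 0, and (F = 0 with O ≤ 3, **or** O + F ≤ 2) |
| medium | V = 1, D ≤ 1, F + D ≤ 3, O + F + D ≤ 5 |
| high | anything else (including V ≠ 1) |

Choices worth making explicit:

* **Prose over table alignment.** The published schematic table for this
  scheme is typographically ambiguous in its "or" rows (whether O is bounded
  when 1–3 features are frequent in the medium rule cannot be read off with
  certainty). The verbal definitions are treated as authoritative and
  formalized as the predicates above. The decision table is exposed as
  configuration (`heterogeneity.DEFAULT_RULES`, or `--rules` on the CLI) so
  an alternative reading can be swapped in without code changes.
* **No very-dense dominant.** The scheme presumes one dominant (≥50%
  coverage) substrate. Profiles with V = 0 or V ≥ 2 fall through to "high"
  via the catch-all and are flagged (`no_dominant` / `multiple_dominants`)
  in the output, because the lower-class rules are only defined relative to
  a dominant.
* **Counts only.** Which features occur (geogenic vs biogenic) is ignored;
  only how many occur per coverage class matters.
* The predicates are nested (every "none" tuple satisfies the low and medium
  predicates), so first-match precedence is what makes the classes ordinal.
  Totality and single-step monotonicity (escalating one feature's coverage
  never lowers the class while the dominant is preserved) are verified by
  exhaustive enumeration of all 5⁹ = 1 953 125 profiles in the test suite.

The inverse sampler (`sample_profile_for_class`) draws profiles by rejection:
one feature is made the dominant, the rest are drawn iid from a per-target
proposal over coverage classes, and draws are re-classified until they hit
the target. The proposals only shape efficiency; correctness comes from the
classifier itself. The budget (default 10 000 tries) makes pathological
proposals fail loudly rather than loop.

## Granulometry

Grain diameters are handled on the phi scale, φ = −log₂(d/1 mm). A sieve
stack becomes knots (φ of mesh, cumulative mass fraction retained on this
and coarser sieves). The summary statistics come from an **asymmetric
(Richards-type) logistic CDF** in phi,
F(φ) = [1 + exp(−(φ−µ)/s)]^(−ν), fitted by bounded least squares
(`scipy.optimize.least_squares`, start values from the empirical median and
spread, bounds µ ∈ [−20, 20], s ∈ [10⁻³, 10], ν ∈ [10⁻², 100]). The exact
s-shape function used in the original granulometric workflow is not
published; the Richards logistic is this package's declared approximation.
Sorting and skewness are *graphic* (Folk–Ward-style) measures from the
fitted percentiles — sorting = (φ84 − φ16)/2, skewness
= (φ16 + φ84 − 2φ50)/(φ84 − φ16) — because whether the original workflow
used moment or graphic measures is not stated; the `fit_method` column
records which path produced each record.

Fallbacks and edge cases:

* A fit is accepted when the optimizer converges with RMS residual < 0.05
  and at least three interior knots exist; otherwise percentiles are taken
  by monotone piecewise-linear inversion of the empirical curve
  (`fit_method="interpolation"`).
* A degenerate step curve (all mass between two adjacent meshes) has no
  invertible interior; its d50 is reported as the mesh that retained the
  mass, with sorting and skewness 0.
* Sediment classes are half-open, lower-inclusive on the coarse side:
  [0, 63) mud, [63, 250) fine, [250, 500) medium, [500, ∞) coarse. The
  boundary values 63/250/500 µm therefore go to the coarser class —
  a deterministic convention where interval wording is ambiguous.
* d50 outliers above 1500 µm are *not* truncated; the phi transform is the
  outlier mitigation before modelling.
* Laser-diffraction output for muds enters as pre-binned fractions through
  the same cumulative-curve container, with bin edges acting as
  pseudo-meshes (the synthetic generator writes such stacks with meshes down
  to 0.5 µm, the finest entry acting as the pan).

## Diversity statistics

* **Frequency** is occupancy / N stations, reported as a percentage rounded
  half-up to one decimal. **Rare species** satisfy occupancy/N < 0.02
  (strict, on the fraction — "fewer than four stations" is the N = 162
  instantiation, not the definition) *and* a maximum per-sample abundance
  ≤ 3. Tightening either criterion can only shrink the rare set.
* **Rare-record rates** count (station, rare taxon) incidences — not
  individuals — per sediment × heterogeneity cell; this interpretation is
  pinned by the arithmetic of the published table, whose total of 80 records
  equals the sum of round(rate × n) over interior cells. Margins are pooled
  sums, never averages of rates; empty cells print NA. Report rounding is
  half-up to 2 decimals (rates) and 1 decimal (frequencies); full precision
  is retained internally.
* **Rarefaction** uses the exact estimator
  E[S(k)] = Σᵢ [1 − C(N−nᵢ, k)/C(N, k)], with binomial coefficients via
  log-gamma to avoid overflow. It reduces to mean per-sample richness at
  k = 1 and total richness at k = N, and is non-decreasing and concave. The
  SD comes from a seeded permutation estimator (default 999 orderings)
  rather than an analytic variance, since the reference implementation's
  variance estimator is a package default that is not described; the
  permutation mean converges to the exact estimator and the SD is 0 at
  k = N by construction.

## Richness models

Counts are modelled with log-link GLMs through statsmodels. The negative
binomial is NB2 (variance µ + µ²/θ) with θ estimated by maximum likelihood
(a discrete-MLE pass estimates the dispersion, then a GLM at that dispersion
supplies the coefficient table and deviances; the AIC counts θ as one extra
parameter, matching `glm.nb` conventions). Quasi-Poisson reuses the Poisson
point estimates and inflates SEs by √φ with φ the Pearson moment estimate;
it has no AIC and is excluded from likelihood-based selection. Wald
statistics are labelled "statistic" (they are z-scores; published tables for
such models sometimes label the same column t).

* **Overdispersion** is diagnosed by Pearson dispersion
  Σr²ᵢ/df and by a parametric bootstrap: simulate from the fitted model,
  refit, and compare dispersion statistics (add-one-corrected p-value). The
  bootstrap replaces a full simulated-residual framework with the one
  statistic this workflow acts on.
* **GVIF** follows Fox–Monette: det(R₁₁)det(R₂₂)/det(R) on the centred
  predictor correlation matrix, adjusted as GVIF^(1/(2·Df)) and screened at
  2.2 (the VIF < 5 analogue). The adjusted value is invariant to linear
  rescaling of numeric predictors; for single-df terms GVIF equals the
  classical VIF, which the tests verify against a regression oracle.
* **Backward AIC selection** drops the single term whose removal lowers AIC
  most, never violating marginality (main effects are protected while an
  interaction containing them survives), with ties broken by term name.
  A null term is retained whenever its likelihood-ratio draw exceeds 2
  (χ²₁ > 2, ~16% of the time under the null) — an inherent property of
  AIC, not a defect; the tests assert the behavior across replicates.
* **Post-hoc contrasts** are estimated marginal means on the link scale:
  the linear predictor averaged over an equally weighted grid of the other
  factors with numeric covariates at their observed means; all pairwise
  differences use the coefficient covariance, with the studentized-range
  (Tukey) correction on the |z|√2 statistics (Holm available as an
  alternative). Degrees of freedom are taken as effectively infinite,
  consistent with Wald-z inference for these models.
* **Nonparametric suite**: Shapiro–Wilk per group, Kruskal–Wallis omnibus,
  pairwise two-sided Mann–Whitney with Holm adjustment (an adjustment the
  original description leaves unstated; the choice is recorded in the report
  metadata). The pairwise tests use the normal approximation without
  continuity correction so that the two-group case coincides with
  Kruskal–Wallis.
* Reference levels default to first-alphabetical (coarse, high, spring),
  configurable per factor. Calendar year enters as a continuous covariate
  centred at the study midpoint for numerical stability. Rows with missing
  covariates are list-wise deleted with a logged count, never imputed.

## Synthetic surveys

The generator's defaults emulate the study design the analysis chain is
meant for: 162 stations over four sediment types (53/27/53/29 for
mud/fine/medium/coarse) crossed with heterogeneity classes in the observed
unbalanced joint design (23/43/49/47 for none/low/medium/high, including
empty cells such as fine-sand/none) — the joint cell counts are used rather
than independent margins precisely to preserve the real confounding of
coarse substrate with high heterogeneity. The species pool holds 199 taxa
(79 polychaetes, 54 molluscs, 39 crustaceans, 27 other) with log-normal
occupancy weights and a 48-taxon rare tail whose weights are calibrated to
about 80/48 expected records per rare taxon; because detection is
stochastic, the *identified* rare set in any one draw is smaller (typically
30–40 taxa) — the designed tail, not the detected one, is the configured
quantity.

Richness is drawn directly from the estimand: S ~ NB(λ, θ = 3) truncated to
[1, pool size], with log λ following the same term structure the model
stage fits (heterogeneity class + sediment + season + depth + salinity +
centred year + year×sediment + season×sediment). Class, sediment, season,
year and covariate slopes use the published signs and magnitudes where a
directly interpretable value is printed (e.g. −0.62 for class "none",
−0.03/m depth, +0.04/PSU salinity, −0.15/year); the intercept (3.65) was
calibrated once so the median per-sample richness lands near the reported
survey median of 27 — the printed intercept is an uncentered-year artifact
and carries no usable information. Species identities are then sampled
without replacement with probability ∝ occupancy weight × log-normal
sediment affinity, and abundances are zero-truncated geometric (mean 6),
capped at 3 for rare-tail taxa. Depth ranges are sediment-dependent
(mud 25–40 m in the deep channel down to coarse 10–22 m on the abrasion
platform), salinity increases mildly with depth (halocline) plus noise,
years span 2012–2018 and seasons are drawn at the observed 36:126
spring:summer proportion.

What passing tests on this generator show — and do not show: parameter
recovery, label recovery (the classifier inverts the profile sampler and
granulometry inverts the sieve sampler with 100% agreement) and the
diagnostics pipeline are validated end-to-end; but the generator has no
spatial autocorrelation, no temporal pseudoreplication, no observer error
in video scoring, and richness is conditionally independent across stations
— conclusions about those aspects of real surveys are outside what the
synthetic tests can certify. Abundance totals are unconstrained by any
published value and are a pure modelling choice.

## Problem sizes in the standard runs

The test suite and acceptance script use the sizes at which the relevant
property is already decisive: exhaustive enumeration of all 5⁹ profiles for
the classifier; an N = 6 community against the C(6,k) all-subsets oracle
for rarefaction; 50 replicates at n = 500 stations for coefficient-CI
coverage; 100 trials (99 bootstrap refits each, n = 150) for the
overdispersion test's rejection rate; and the full 162-station default
survey for end-to-end label recovery.

## Known limitations

* The Richards-logistic grain-size fit is an approximation to an
  unpublished fitting function; percentile-based summaries from poorly
  sampled or multi-modal stacks fall back to interpolation and are flagged.
* Tukey adjustment uses the studentized-range correction on z statistics,
  matching large-sample practice; small-sample df refinements are not
  implemented.
* No spatial or temporal correlation structure anywhere (models or
  generator); the modelling stage deliberately omits mixed effects and
  zero-inflation.
* The pipeline's video and grab data are joined purely on station id; any
  spatial mismatch between transect and grab is invisible to the software.
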