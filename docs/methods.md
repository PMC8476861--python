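# Methods

`leptomr` implements two-sample Mendelian randomization (MR) from GWAS/EWAS
summary statistics, packaged around a complete worked analysis: the causal
effect of circulating leptin levels (exposure) on anorexia nervosa risk
(outcome, log-odds scale).  This note records the model, the estimators and
their assumptions, the numerical and design choices that were genuinely
open, and what the synthetic-data tests do and do not establish.

## Model and notation

For each of J independent biallelic instruments the inputs are the
per-allele exposure effect and SE (bx_j, sx_j) and outcome effect and SE
(by_j, sy_j), expressed for a common allele after harmonization.  The
instrumental-variable model is

    by_j = theta * gamma_j + alpha_j + e_j,      e_j ~ N(0, sy_j^2),

where gamma_j is the true exposure effect (bx_j estimates it with error
sx_j), theta is the causal effect of interest, and alpha_j is a direct
("horizontally pleiotropic") effect of the variant on the outcome.  A valid
instrument has alpha_j = 0.  The per-variant Wald ratio is
r_j = by_j / bx_j with first-order delta-method SE sy_j / |bx_j| and
inverse-variance weight w_j = bx_j^2 / sy_j^2.

## Instrument QC

* Significance: p < 5e-8 by default; an opt-in relaxed threshold
  (p < 0.05) for effect sizes re-estimated in subgroups of a discovery
  study, mirroring common practice when subgroup effects are used.
* Strength: F = (beta/se)^2 with the conventional F >= 10 cut.  The
  boundary F = 10 is retained (kept, not excluded).
* Proxy variants for instruments absent from the outcome study are ranked
  by r^2 (minimum 0.80), then distance to the lead variant, then
  non-palindromic alleles, then lexicographic id for determinism.  If the
  best proxy is itself unusable the next-ranked candidate is taken.

The F >= 10 filter is not cosmetic: the simulation tests show that
exposure-positive re-orientation of weak instruments, whose observed effect
sign can be noise-flipped, contaminates the Egger intercept; after the
filter the intercept is unbiased for the planted mean direct effect.

## Harmonization

Outcome alleles equal to the exposure's are taken as-is; swapped labels
flip the outcome effect sign; for non-palindromic variants a strand flip is
resolved by complementing before comparison.  Palindromic (A/T, C/G)
variants cannot be resolved from labels.  Policies:

* `eaf-resolve` (default): infer strand when both studies' effect-allele
  frequencies are informative (|EAF - 0.5| > 0.08); otherwise consult a
  user-supplied proxy-direction table (variant -> `same`/`flipped`,
  typically derived from effect directions of LD proxies); otherwise the
  variant is dropped with an explicit reason.  The 0.08 ambiguity band is a
  conventional safety margin; the bundled proxy table records that the LEP
  variant rs10487505 (EAF 0.50) has the same effect direction as its LD
  proxies (r^2 = 0.98) in both studies.
* `strict`: refuse all palindromic variants.
* `keep`: assume both studies report the forward strand.  The packaged
  fixture tables are printed with both studies' effects on one shared
  effect allele, so `keep` is the faithful policy for them (the outcome
  table prints no EAF, and the FTO variant rs8043757 is T/A, hence
  palindromic); `eaf-resolve` remains the default for user-supplied files.

Under the `exposure-positive` orientation (default, required by Egger)
both effects are jointly sign-flipped so bx >= 0, with alleles swapped and
EAFs complemented.  All estimators are invariant to joint sign flips of any
instrument, which the suite checks as a property.

## Estimators

* **Wald ratio** (1 variant): b = by/bx, se = sy/|bx|, normal p.
* **IVW** (>= 2): b = sum(w r)/sum(w), equal to weighted least squares of
  by on bx through the origin.  Variance model: multiplicative random
  effects with the residual scale floored at 1 — se = se_fixed * max(1,
  sqrt(Q/(J-1))) with se_fixed = 1/sqrt(sum w).  The floor means the
  reported interval never undercuts the fixed-effect one; under a
  homogeneous null the fixed-effect interval has nominal 95% coverage while
  the reported interval is conservative (~96-97% at J=50), which the suite
  asserts in that form.
* **MR-Egger** (>= 3): WLS of by on bx with intercept, weights 1/sy^2.
  The intercept estimates average directional pleiotropy; the slope is
  consistent for theta under InSIDE (instrument strength independent of
  direct effects).  Both SEs carry the same max(1, residual sd) floor;
  p-values use t with J-2 df.  A zero intercept estimate makes the slope
  equal IVW exactly.
* **Median family** (>= 3): simple (unit weights), weighted (w_j), and
  penalised weighted median of the ratio estimates, interpolating the 50th
  percentile over standardized cumulative weights
  p_j = (cumsum(w) - w_j/2)/sum(w).  The penalised kind multiplies weights
  by min(1, 20 q_j) with q_j the upper chi^2_1 tail of the variant's
  heterogeneity contribution about the weighted median (penalty constant 20
  from the originating method; with no heterogeneity it reduces to the
  weighted median exactly).  Consistent while valid instruments contribute
  > 50% of the weight.
* **Mode family** (>= 3): argmax of a weighted normal-kernel density over
  the ratios; bandwidth phi * 0.9 * min(sd, mad/0.6745) * J^(-1/5)
  (phi = 1 by default), scanned on a 512-point grid spanning
  [min - 3h, max + 3h], ties broken toward smaller magnitude.  Consistent
  under the zero-modal pleiotropy assumption.
* **RAPS** (>= 3): theta solves the profile score
  sum bx (by - theta bx) / (sy^2 + theta^2 sx^2 + tau^2) = 0, with the
  overdispersion tau^2 >= 0 estimated jointly from the moment condition
  sum (resid^2 - sigma^2)/sigma^4 = 0 and truncated at zero.  This is a
  deliberately simple member of the profile-score family: as sx -> 0 with
  overdispersion off it reduces exactly to fixed-effect IVW.  The optional
  Huber loss (k = 1.345) bounds the influence of idiosyncratic outliers,
  with the usual Fisher-consistency constants applied to the scale moment
  and the SE.  The SE is the model-based profile information
  1/sqrt(sum bx^2/sigma^2).  Implementations that add the
  derivative-of-variance term to the score will differ by ~1-2% on small
  heterogeneous instrument sets; on the four-instrument leptin set this
  estimator gives -0.915 against -0.930 from the originating software.

Median and mode SEs come from a parametric bootstrap (bx* ~ N(bx, sx),
by* ~ N(by, sy); 1000 replicates by default) with a mandatory recorded
seed; bootstrap results are bit-reproducible given (reps, seed).  All 95%
intervals are b +/- 1.96 se, which reproduces the published interval bounds
exactly from the printed point estimates.

## Diagnostics

* **Cochran's Q** about IVW (df = J-1, weights w_j) or about the Egger fit
  (df = J-2, weights 1/sy^2), with exact per-variant decomposition.
* **Egger intercept test**: intercept / SE against t with J-2 df; a
  non-significant intercept is read as no evidence of directional
  pleiotropy.
* **MR-PRESSO** (>= 4, seed mandatory).  Global test: observed
  RSS = sum_j (by_j - theta_loo_j bx_j)^2, with theta_loo_j the
  leave-one-out IVW estimate, against the same statistic on parametric
  simulations under the no-pleiotropy model (by*_j ~ N(theta_loo_j bx_j,
  sy_j), bx*_j ~ N(bx_j, sx_j)), with leave-one-out slopes re-estimated on
  each simulated dataset; empirical p = (1 + #{sim >= obs})/(n_sim + 1), so
  never 0.  Because the generation means embed estimated slopes, the global
  test is mildly conservative when J is small (noticeable at J ~ 10,
  negligible at J = 50, where the suite verifies uniformity of the null p).
  Outlier test: each observed squared residual against its exact parametric
  null — simulated residuals measured against the same leave-one-out slope
  that generated them.  Re-estimating the reference slope on the simulated
  data would let pleiotropy in the tested variant contaminate its own null
  (the contaminated slopes enter every other variant's generation mean) and
  demonstrably halves the detection margin; the fixed-slope comparison
  trades a slight per-variant anti-conservatism (it omits slope-estimation
  noise, a 1/(J-1) effect) for unbiased detection.  Flags are Bonferroni at
  0.05/J.  Distortion test: the observed shift of the IVW estimate after
  outlier removal against shifts under bootstrap resampling (with
  replacement) of the non-outlier variants, 1000 resamples.  The corrected
  estimate is the IVW on non-outliers.
* **Leave-one-out** IVW series and funnel/forest/scatter plot tables
  (data only; no figure rendering).

## Power

For a binary outcome with outcome-study size N, case fraction K,
instrumented exposure variance R^2 and alternative odds ratio OR, the
two-sided power at level alpha is

    power = Phi(z - z_{1-alpha/2}) + Phi(-z - z_{1-alpha/2}),
    z = |ln OR| * sqrt(N * R^2 * K * (1 - K)),

the standard normal approximation for an MR estimate whose information is
proportional to N R^2 K(1-K).  At OR = 1 this returns exactly alpha.  With
the anorexia study's N = 72,517, K = 16,992/72,517 and R^2 = 0.097 it gives
0.78 at OR = 1.08 and > 0.996 at OR = 1.14, matching the reported "80%" and
"100%" statements as band checks.

## Synthetic data generator

`SimConfig`/`simulate_summary_stats` emulate the structure the analysis
assumes: J independent instruments, latent exposure effects gamma_j
expressed for the exposure-increasing allele (magnitudes of N(0,
gamma_sd^2) draws), observed bx_j = gamma_j + N(0, sx^2), and
by_j = theta gamma_j + alpha_j + N(0, sy^2).  Pleiotropy modes: `none`;
`balanced` (alpha ~ N(0, alpha_sd^2)); `directional` (alpha ~ N(alpha_mean,
alpha_sd^2), independent of gamma, so InSIDE holds); `inside_violating`
(alpha correlated 0.5 with gamma, standardized against the half-normal
moments of gamma).  Directionality is only meaningful relative to the
exposure-increasing orientation — with symmetric signed effects,
re-orientation folds a constant mean direct effect into a balanced one —
which is why the generator fixes that orientation at the source.  Planted
outliers add outlier_scale * sy to alpha at recorded indices.  Alleles are
A/G with EAF ~ U(0.1, 0.9); the EAFs are not used by the estimators but
exercise the harmonization plumbing.  Everything is a deterministic
function of the seed.

Defaults mirror the scale of the leptin/anorexia data: J = 50, gamma_sd =
0.03, sx = 0.005 (leptin GWAS magnitudes), sy = 0.0136 (anorexia log-OR
SE), theta = 0.  What the generator does **not** emulate: linkage
disequilibrium between instruments (the analysis treats instruments as
independent), winner's-curse selection of instruments, allele-frequency-
dependent effect sizes, sample overlap between the two studies, and
non-linear exposure-outcome relationships.  Passing simulation tests
therefore establish correctness of the estimators under the stated
two-sample model, not robustness to those real-data complications.

## Problem sizes used in the test suite

Monte-Carlo checks use 60-500 replicates at J = 10-50 with 500-1000
parametric simulations inside PRESSO, sizes at which the asserted
quantities (coverage, intercept recovery, detection rates, null
uniformity) are stable to within the stated tolerances while the whole
suite stays fast.

## Known limitations

* No multivariable MR, contamination-mixture or CAUSE-style estimators; no
  Steiger directionality test; no LD computation (proxy candidates are
  always supplied as a table); no liftover or VCF input.
* RAPS uses the simplified profile score described above; its SE is
  model-based rather than sandwich-empirical.
* The published analyses were run from unrounded summary statistics; the
  packaged fixtures carry the printed (2-significant-figure) inputs, so
  recomputed estimates agree with the published ones to roughly 0.5-2%,
  and near-zero quantities (e.g. an Egger intercept of magnitude ~0.04
  with SE of the same order) can differ more or flip sign.
* MR-PRESSO's global p is reproducible only in distribution: the published
  run's simulation count and seed are unknown.
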