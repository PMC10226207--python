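# Methods

This note records the estimators, their assumptions, the numerical
conventions, and the design choices behind `ineqdecomp`.

## Ranking and the concentration index

Units are ordered by a continuous living-standard score (higher =
richer). With weights normalized to sum to one, the fractional rank of
unit *i* is the cumulative weight of all strictly poorer units plus half
of its own weight. Units tied on the score are pooled into one block and
share the block's midpoint rank; this makes every downstream index
invariant to row order within ties. The weighted mean of the ranks is
exactly 0.5 by construction, and ranks are invariant to any strictly
monotone transform of the score. Ranking on a continuous score is the
default because it avoids mass ties; if only a quintile variable exists
the same code ranks on it and the tie blocks are handled as above.

The concentration index is computed in covariance form,
C = 2 cov_w(H, r)/H̄, with a *population-style* covariance (divide by
total weight, no n/(n−1) correction). This choice is deliberate: it
makes the covariance form agree with the equal-weight rank-sum form
(2/(nH̄)) Σ H_i r_i − 1 to machine precision, an identity the test suite
asserts at 1e−12. `weighted=False` ignores the sampling weights
entirely — units are re-ranked with equal weights and the covariance is
unweighted — so the weighted/unweighted pair of estimates can be
reported side by side. For binary outcomes the attainable bounds
(H̄ − 1, 1 − H̄) are attached to the result. No normalization is applied
by default; `normalize="wagstaff"` divides by (1 − H̄) and
`normalize="erreygers"` multiplies by 4H̄, both defined for binary
outcomes only.

Concentration curves carry one vertex per distinct rank value. The
cumulative population and outcome shares are each normalized by their
realized totals, so both coordinates start at exactly 0, end at exactly
1, and are monotone despite floating-point accumulation. The Gini index
is the concentration index of an outcome ranked by itself and equals
1 − 2·(trapezoid area under the Lorenz curve) to 1e−9 on tie-free data.

### Standard error

The SE uses the convenient-regression device: regressing
2σ²_r (H_i/H̄) on the fractional rank by weighted least squares yields C
as the slope, and its heteroskedasticity-robust (HC1) standard error is
reported; when a cluster variable (PSU or stratum) is supplied the
variance is cluster-robust instead, falling back to HC1 with a warning
when fewer than two clusters exist. This formula treats H̄ and the ranks
as fixed, which is the standard convenient-regression approximation; a
Monte-Carlo check in the test suite confirms the SE lands within a
factor of two of the sampling SD of C over repeated draws from a known
design (n = 4000, 300 replicates). A constant outcome yields SE 0 with a
warning.

## Outcome model and decomposition

The ill-health outcome is modelled by weighted maximum-likelihood logit
(statsmodels GLM with binomial family and variance weights scaled to
mean one, so the effective sample size is the face-value n; tolerance
1e−8, at most 100 iterations). The design matrix dummy-codes every
categorical against a declared reference level, in schema order then
level order; continuous covariates pass through. Rank deficiency is an
error naming the collinear columns, and a coefficient exceeding 20 in
magnitude is treated as separation.

Average marginal effects are derivative-based for every column by
default: AME_k = β_k Σ ŵ_i p_i(1 − p_i). Applying the common factor
Σ ŵ p(1−p) uniformly to dummies and continuous regressors keeps the
decomposition linear in the regressors, which is what makes the
elasticity × concentration-index product form exact. A discrete-change
AME (average of p(x_k = 1) − p(x_k = 0)) is available as an option for
dummies; it breaks exact linearity and is provided for interpretation
only.

The decomposition computes, per regressor, the weighted mean x̄_k, the
concentration index C_k of the regressor against the *same* rank vector
and weights as the outcome (never re-ranked), the elasticity
ζ_k = AME_k x̄_k/H̄, and the contribution ζ_k C_k. The residual is
defined as the remainder C − Σ ζ_k C_k rather than computed from the
generalized concentration of the model error directly; the two are
algebraically equal in expectation, but the remainder convention
guarantees the adding-up identity exactly in every finite sample, which
is the property the output tables display and the tests assert. Percent
shares are 100 · contribution / C with signs preserved. A zero-mean
regressor (empty dummy) contributes zero with a warning.

One point deserves emphasis: because the logit mean is nonlinear, the
population value of the residual is *not* zero even when the data are
generated exactly from the fitted model family. As n grows the residual
share converges to a small nonzero constant (about 3–4% of C under the
shipped generator defaults), not to zero; only its sampling variability
shrinks. The test suite therefore checks that the share is small at
every n and stabilizes between n = 20 000 and n = 50 000.

Sampling weights are used consistently throughout — ranking, logit,
means, H̄, C, and every C_k — under the default `weighted=True`; the
unweighted switch drops them everywhere at once.

## Change decomposition

Given two decomposition tables with identical covariate sets (aligned
by label; a mismatch is an error, never a silent zero-fill), each
covariate's contribution to ΔC is split under both symmetric weightings,
and both variants are always emitted side by side — the per-covariate
totals coincide by algebra, asserted to 1e−14 over a thousand random
tables. The residual change is again the remainder ΔC − Σ totals, and
percent shares use ΔC as the denominator with signs preserved. Swapping
the waves negates every total. The grouped chart pools dummy rows to
their parent covariate (all education levels into one bar) using the
group labels carried by the design matrix, and writes the plotted values
as CSV next to the image.

## Synthetic generator

The generator emulates a DHS-style mother-level extract with known
truth. Per wave: a latent wealth score N(0, 1) plus a +0.9 shift for
urban units; weighted quintile cutpoints at 20/40/60/80%; categorical
covariates drawn from quintile-conditional probability tables (education
rising with wealth, distance problems and number of children falling);
a Poisson number of children; a Bernoulli outcome from a logit with
declared coefficients; and two strata (urban/rural) with
inverse-probability weights equal to population share over sample share,
normalized to mean one. When a target prevalence is declared the
intercept is recalibrated by root-finding so the expected weighted
prevalence hits the target. All randomness flows through one
`numpy.random.default_rng(seed)`; a fixed seed gives byte-identical
output.

The shipped two-wave defaults are illustrative, not calibrated: the
baseline wave has a mostly rural sample (10% urban), prevalence ~0.50,
and a steep wealth gradient (richest-quintile log-odds −1.47); the
follow-up wave has an urbanized sample (56%), prevalence ~0.31, and
flattened wealth, education, and distance coefficients, so the default
contrast is one of shrinking pro-poor inequality in poor utilization
(about −0.20 → −0.175 in C at n = 20 000), mirroring the kind of
between-round change seen in real national surveys. The marginals
loosely track published survey composition (education expansion,
urbanization) without attempting to match any specific survey's
estimates.

What the generator does *not* emulate: multi-stage PSU geometry (only
stratum labels are carried, so cluster-robust SEs on synthetic data are
exercised mechanically, not realistically), item nonresponse, within-
household correlation, or misreported covariates. Passing tests on
synthetic data therefore demonstrate the estimators' internal
correctness and identities, not robustness to the messiness of real
survey data.

A closed-form oracle supports the index tests: if the poorest fraction
p of the population holds all of the outcome, the concentration curve is
L(s) = min(s/p, 1) and C = p − 1 exactly; the simulated index at
n = 100 000 must land within 0.01 of it.

## Worked-example anchors

The published ANC and PNC decomposition tables shipped under
`ineqdecomp/data/` print both ζ_k and C_k for every covariate row, which
makes their arithmetic self-contained: the package recomputes every
contribution cell, the explained totals, and the full change
decomposition from those inputs and asserts agreement at printed
precision (tolerance 1.5e−4, covering the 4-decimal rounding of both the
printed cells and the printed inputs). The published source prints two
slightly different values for one wave's ANC index (−0.1871 in its
summary table, −0.1897 in its decomposition table); the shipped
reference uses −0.1897 because it is the value consistent with the
printed decomposition arithmetic. On real data the package always
reports its own computed values.

## Numerical conventions and limitations

* Display rounding is 4 decimals for CI-scale quantities and 2 for odds
  ratios and percents; JSON artifacts keep full precision, and the
  emitted tables are byte-stable under a fixed configuration (no
  timestamps).
* Complete-case analysis only; dropped-row counts are logged and can be
  written as a one-line JSON record. No imputation.
* Point estimates use the sampling weights only; strata/PSU labels
  enter solely through the cluster-robust SE option.
* No variance is attached to decomposition contributions or change
  totals (point decompositions only), and no dominance test between
  concentration curves is performed.
* Problem sizes in the default test and acceptance runs (n = 2 000 to
  50 000 units, 100 000 for the closed-form check, 300 Monte-Carlo
  replicates for the SE oracle) were chosen to make sampling noise
  negligible relative to the asserted tolerances while keeping the full
  suite fast on a single CPU.
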