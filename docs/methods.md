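# Methods

## Single-factor attributable risk

For a dichotomous exposure with population prevalence `Pe` and relative
risk `RR`, Levin's formula gives the population attributable fraction

    PAF = Pe (RR − 1) / [Pe (RR − 1) + 1].

All internal arithmetic is on the proportion scale; the percent scale
(one decimal) appears only at rendering. Rendering rounds half-up,
matching how published tables print values like `25.1 (16.3, 32.8)`;
the implementation goes through `decimal.Decimal` on the shortest
`repr` of the float so that binary representation artifacts do not flip
a half-case. Negative PAFs (protective exposures, `RR < 1`) are kept
with their sign, never clipped; `RR = 1` and `Pe = 0` return exactly
`0.0`.

The algebraic inverse, `RR = 1 + PAF / [Pe (1 − PAF)]`, is exposed
because the package's bundled study fixtures require it: the cohort
relative risks behind the published PAR table were cited but not
printed, so implied RR fixtures are back-derived from each printed PAR
point and CI bound at the printed prevalence. These fixtures are kept
at 4 decimals and carry a `derived` provenance tag everywhere they are
persisted — they are synthetic reconstructions, not measured data.
Prevalences shown only in the study's bar charts are never digitised;
the affected rows (hypertension, excess body weight, and all age-group
cells) are marked unavailable and excluded from reproduction runs.
Reproduction therefore covers the 20 cells (5 factor/stratum pairs × 4
outcomes) whose prevalences appear as numbers in the text, and on those
the one-decimal round trip is exact by construction — any mismatch
would indicate a formula or rounding bug, which is what the reproduction
test is for.

## Substitution-method confidence intervals

The substitution method treats prevalence as fixed (its sampling error
is assumed negligible relative to the RR's) and propagates only RR
uncertainty. The log-scale SE is read off the 95% CI as
`(ln U − ln L) / (2z)` with `z = 1.96` by default (configurable; the
multiplier is a convention, not an estimate). `ln RR` is sampled from
a normal distribution — i.e. RR lognormal, the natural companion of a
log-symmetric CI — and each draw is mapped through Levin's formula; the
empirical 2.5 and 97.5 percentiles over 10 000 iterations (defaults)
are the confidence limits. Percentiles use linear interpolation
between order statistics (`numpy.percentile`'s default), fixed and
documented because the percentile estimator is otherwise a silent
degree of freedom.

Two location conventions are supported and recorded in the estimate's
metadata: `point` (centre at `ln RR̂`, the default) and
`geometric-mean` (centre at the log-midpoint of the CI bounds). They
differ because printed point estimates and bounds are rounded
independently and are rarely exactly log-symmetric.

Because Levin's formula is strictly monotone in RR, the
infinite-iteration limit is available in closed form: evaluate the
formula at the exact lognormal RR quantiles. This closed-form
substitution interval serves as the deterministic oracle for the Monte
Carlo estimator; the two agree within 1e−3 (proportion scale) at 10⁶
draws over a grid of prevalences {0.1, 0.4, 0.7} and log-scale SEs
{0.05, 0.1, 0.2} — the SE grid spans the range actually present in the
derived RR fixtures (0.044–0.204). At substantially larger SEs the
Monte Carlo noise of an extreme percentile at 10⁶ draws becomes
commensurate with that tolerance, so the comparison is made where the
study's uncertainties actually live.

## Synthetic populations

No individual-level data accompany the bundled study, so multifactor
estimators are exercised on synthetic cross-sections from a
Gaussian-copula generator. Each individual draws a latent vector
`Z ~ N(0, Σ)` with Σ a correlation matrix; exposure `j` is
`1{Z_j < Φ⁻¹(p_j)}`, which calibrates every marginal prevalence exactly
while Σ controls clustering. The *latent* correlation is the
configuration parameter; the induced binary-scale correlation is
attenuated (point-biserial dichotomisation), monotone in the latent ρ,
and verified empirically in tests rather than targeted. Outcome risk
is multiplicative on the probability scale,
`risk = baseline × Π_j RR_j^{x_j}`, with `Y ~ Bernoulli(risk)`; a
configuration whose worst-case risk exceeds 1 is rejected outright
rather than truncated, because truncation would silently break the
model under which Levin's formula is exact. All randomness flows from
one seed through numbered `SeedSequence` substreams (exposures and
outcomes separately), so per-factor analyses are order-independent and
every sample is bit-reproducible.

The shipped demo scenario uses n = 200 000 individuals, marginal
prevalences (0.649, 0.330, 0.056, 0.396, 0.300) for smoking,
hypertension, diabetes, elevated cholesterol and excess body weight,
true risk ratios (1.52, 2.05, 1.78, 1.55, 1.35), baseline risk 0.05,
and a positive latent correlation (ρ = 0.3 among the four metabolic
factors, 0.1 between smoking and the rest). The smoking, diabetes and
cholesterol prevalences mirror the study's printed values; the
hypertension and excess-weight prevalences, the risk ratios, and all ρ
values are illustrative placeholders — no Indonesian between-factor
correlation targets exist — and are labelled as such in the code. What
passing tests on these populations shows is that the estimators are
correct under the stated generative model; they say nothing about
survey design effects, continuous exposures, age structure, or
non-multiplicative risk, none of which the generator emulates.

## Multifactor estimators

All elimination effects are computed on model risks (expectations), not
on the sampled binary outcomes, which makes the estimator identities
exact rather than approximate:

- joint / counterfactual PAF of a factor set `S`:
  `1 − mean(risk with exposures in S zeroed) / mean(risk)`;
- sequential PAFs for an elimination order telescope to the joint PAF
  (machine-precision identity, tested at 1e−10);
- average PAFs are Shapley values of the joint PAF, computed from the
  `2^K` subset-risk table with weights `|S|!(K−|S|−1)!/K!`; they match
  a brute-force mean over all `K!` orderings to 1e−12 for `K ≤ 4` and
  sum to the joint PAF exactly. The exact decomposition is limited to
  `K ≤ 6` (64 subset expectations); beyond that the error message
  points at sampling orderings instead.
- the case-based (Miettinen) PAF `p_c (RR − 1)/RR` uses the exposure
  prevalence among cases — the only estimator here that consumes the
  sampled outcomes — with the RR supplied externally (a crude RR
  reproduces the crude Levin PAR; an adjusted RR gives an internally
  valid attribution under confounding). Regression-model-standardised
  PAFs are deliberately out of scope.

An analytic counterpart, `expected_paf`, evaluates the same
counterfactual at infinite n by enumerating the `2^K` exposure patterns
with their copula cell probabilities (products of marginals under
independence, multivariate-normal rectangle probabilities otherwise);
with a single factor it collapses to Levin's formula exactly, which is
the package's single-factor consistency check.

The attribution report places the crude Levin PARs (empirical
prevalence × crude 2×2-table RR) beside the single-removal, case-based
and average PAFs, plus the `Σ crude − joint` gap. On the shipped
correlated scenario the crude PARs sum to roughly twice the joint PAF.
Under independence the crude Levin PAR is consistent for each factor's
own single-removal PAF; note that even then the *sum* of single-factor
PAFs exceeds the joint PAF (`1 − Π(1 − PAF_j)`) by a second-order
amount — additivity is a property of the average PAFs, not of
single-factor PAFs.

## Uncertainty scope and problem sizes

Confidence intervals are produced only for single-factor PARs (the
substitution method); sequential and average PAFs are reported as point
decompositions. Default problem sizes — 10 000 Monte Carlo iterations,
demo populations of 2 × 10⁵, convergence checks at 10⁶ draws, exact
Shapley up to K = 6 — keep every computation interactive on a laptop
while leaving percentile noise well inside the tolerances quoted above.
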