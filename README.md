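# attribfrac

Population attributable fractions for cardiovascular risk factors —
single-factor Levin PARs with substitution-method Monte Carlo confidence
intervals, plus multifactor attribution estimators (case-based,
sequential, and average/Shapley attributable fractions) that quantify
how badly summed single-factor PARs overstate the jointly removable
burden when risk factors are correlated.

## The problem

Burden-of-disease analyses routinely report, for each modifiable risk
factor, the fraction of disease that would be removed if that exposure
were eliminated. With only summary statistics available — a national
prevalence `Pe` for the exposure and a cohort relative risk `RR` — the
standard tool is Levin's formula

```
PAF = Pe (RR − 1) / [Pe (RR − 1) + 1]
```

with a 95% CI obtained by the *substitution method*: prevalence is
treated as fixed, `ln RR` is sampled from a normal distribution whose SE
is read off the log-transformed RR confidence interval, each draw is
pushed through the formula, and the empirical 2.5/97.5 percentiles over
10 000 Monte Carlo iterations are the confidence limits.

Computed one factor at a time, these PAFs silently assume the risk
factors act independently. Vascular risk factors (smoking,
hypertension, diabetes, elevated total cholesterol, excess body weight)
cluster strongly, so the single-factor PAFs neither sum to anything
meaningful nor match the joint counterfactual burden. Proper
multifactor accounting needs individual-level data and one of:

- **case-based (Miettinen) PAF** `p_c (RR − 1)/RR`, with `p_c` the
  exposure prevalence among cases — internally valid under confounding
  when an adjusted RR is supplied;
- **sequential attributable fractions** — the burden removed by each
  factor under a specified elimination order; they telescope exactly to
  the joint PAF;
- **average attributable fractions** (Eide–Gefeller) — each factor's
  sequential fraction averaged over all `K!` elimination orders, i.e.
  the Shapley value of the joint PAF; computed here exactly from the
  `2^K` subset-risk table, never by enumerating permutations.

The package bundles, as worked fixtures, a published analysis of the
Indonesian adult population (Riskesdas 2013 prevalences × Asia-Pacific
cohort relative risks). The cohort RRs behind that table were never
printed, so the package back-derives implied RR fixtures from the
published PAR cells with the algebraic inverse of Levin's formula and
demonstrates an exact one-decimal round trip on every cell whose
prevalence is printed in the text. Because the survey microdata are
unavailable, a Gaussian-copula generator produces synthetic
cross-sections with correlated binary exposures and a multiplicative
risk outcome, on which all estimators are exercised.

## Worked example

```python
import attribfrac as af
from attribfrac import fixtures

# Single-factor PARs from the published summary statistics
model = af.LevinPARModel(fixtures.load_prevalence_fixture(),
                         fixtures.derive_implied_rr_table())
res = model.fit(n_iterations=10_000, seed=1, location="geometric-mean")
print(res.summary())
```

```
Levin PAR estimates (substitution-method Monte Carlo CIs)
iterations per factor: 10000   percentiles: (2.5, 97.5)   location: geometric-mean

factor                      outcome               stratum               PAR % (95% CI)
smoking                     CHD                   men                25.1 (16.5, 32.9)
smoking                     CHD                   women                 1.4 (0.7, 2.3)
elevated total cholesterol  CHD                   women               17.8 (7.1, 27.1)
diabetes                    CHD                   men                   4.2 (2.3, 6.2)
diabetes                    CHD                   women               10.7 (5.1, 17.4)
...
```

The point estimates reproduce the published table exactly (25.1% of male
CHD attributable to smoking, etc.); the Monte Carlo limits wobble around
the published ones (16.3, 32.8) by a fraction of a percentage point, as
any finite percentile estimate must.

```python
# Multifactor attribution on a correlated synthetic population
results = af.AttributionModel(af.demo_scenario(n_individuals=200_000,
                                               seed=20160178)).fit()
print(results.summary())
```

```
Attribution report (proportions of total burden)

                    factor  prevalence_hat  rr_hat  crude_levin_par  case_based_paf  single_removal_paf  average_paf
                   smoking          0.6486  1.6640           0.3010          0.3010              0.2594       0.1861
              hypertension          0.3280  2.5017           0.3300          0.3300              0.2834       0.1986
                  diabetes          0.0557  2.6482           0.0841          0.0841              0.0583       0.0340
elevated total cholesterol          0.3962  2.0379           0.2914          0.2914              0.2022       0.1353
        excess body weight          0.2987  1.8087           0.1946          0.1946              0.1137       0.0715

joint PAF (all factors removed):   0.6255
sum of crude Levin PARs:           1.2010
sum of average (Shapley) PAFs:     0.6255
overestimation gap (crude - joint): +0.5755
```

Reading: eliminating all five factors would remove 62.6% of the burden
in this scenario, and the average (Shapley) PAFs decompose that total
additively. The crude single-factor Levin PARs — the only thing
computable from summary statistics — sum to 120%, nearly double the
joint counterfactual: the overestimation that correlated risk factors
induce.

A command-line interface mirrors the three workflows:

```
attribfrac reproduce-table1            # round-trip the published table
attribfrac simulate --seed 1 --out out/
attribfrac attribution-report --seed 1
```

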