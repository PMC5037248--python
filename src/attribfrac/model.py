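"""Model / results surface for attributable-burden estimation.

Two estimation problems, each with a statsmodels-flavoured pairing of a
model object (holds the data) and a results object (holds estimates,
uncertainty and a ``summary()`` table):

* :class:`LevinPARModel` — single-factor PARs from summary statistics
  (prevalence + relative-risk estimates), with substitution-method
  Monte Carlo confidence intervals.
* :class:`AttributionModel` — multifactor attribution from an
  individual-level sample, decomposing the joint counterfactual burden
  into sequential / average fractions and quantifying how far summed
  single-factor PARs overshoot it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .levin import ExposurePrevalence, RelativeRiskEstimate, levin_par, percent
from .montecarlo import (
    DEFAULT_ITERATIONS,
    DEFAULT_PERCENTILES,
    monte_carlo_par_ci,
    substitution_ci_closed_form,
)
from .multifactor import AttributionReport, build_attribution_report
from .simulate import PopulationSample, ScenarioConfig, generate_population

__all__ = ["LevinPARModel", "LevinPARResults", "AttributionModel", "AttributionResults"]


class LevinPARModel:
    """Single-factor population-attributable-risk model.

    Built from paired summary statistics: for each risk factor (within
    an outcome/stratum cell) an exposure prevalence and a relative-risk
    estimate with its 95% CI.  ``fit`` computes the Levin PAR point
    estimate for every pair and a Monte Carlo substitution-method CI.

    Parameters
    ----------
    prevalences : sequence of ExposurePrevalence
    rr_estimates : sequence of RelativeRiskEstimate
        Matched to prevalences by (factor, stratum).
    """

    def __init__(self, prevalences, rr_estimates):
        self.prevalences = {(p.factor, p.stratum): p for p in prevalences}
        self.rr_estimates = list(rr_estimates)
        missing = [
            (e.factor, e.stratum)
            for e in self.rr_estimates
            if (e.factor, e.stratum) not in self.prevalences
        ]
        if missing:
            raise ValueError(f"no prevalence for {sorted(set(missing))}")

    @classmethod
    def from_dataframe(cls, prevalence_df: pd.DataFrame, rr_df: pd.DataFrame):
        """Construct from tidy frames.

        ``prevalence_df`` needs columns factor, stratum, value;
        ``rr_df`` needs factor, outcome, stratum, rr, ci_lower, ci_upper.
        """
        prevalences = [
            ExposurePrevalence(r.factor, r.stratum, r.value)
            for r in prevalence_df.itertuples(index=False)
        ]
        rrs = [
            RelativeRiskEstimate(
                factor=r.factor, outcome=r.outcome, stratum=r.stratum,
                rr=r.rr, ci_lower=r.ci_lower, ci_upper=r.ci_upper,
            )
            for r in rr_df.itertuples(index=False)
        ]
        return cls(prevalences, rrs)

    def fit(
        self,
        n_iterations: int = DEFAULT_ITERATIONS,
        seed: int = 0,
        percentiles=DEFAULT_PERCENTILES,
        location: str = "point",
    ) -> "LevinPARResults":
        """Levin PAR + Monte Carlo percentile CI for every factor cell."""
        estimates = []
        for i, rr_est in enumerate(self.rr_estimates):
            pe = self.prevalences[(rr_est.factor, rr_est.stratum)].value
            estimates.append(
                monte_carlo_par_ci(
                    pe, rr_est,
                    n_iterations=n_iterations,
                    seed=int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] % 2**31),
                    percentiles=percentiles,
                    location=location,
                )
            )
        return LevinPARResults(self, estimates, n_iterations, seed, percentiles, location)


class LevinPARResults:
    """Fitted single-factor PARs with empirical percentile CIs."""

    def __init__(self, model, estimates, n_iterations, seed, percentiles, location):
        self.model = model
        self.estimates = estimates
        self.n_iterations = n_iterations
        self.seed = seed
        self.percentiles = percentiles
        self.location = location

    @property
    def frame(self) -> pd.DataFrame:
        """Estimates on the percent scale (one-decimal half-up rendering
        is applied only in ``summary``)."""
        rows = []
        for est, rr_est in zip(self.estimates, self.model.rr_estimates):
            pe = self.model.prevalences[(est.factor, est.stratum)].value
            rows.append(
                {
                    "factor": est.factor,
                    "outcome": est.outcome,
                    "stratum": est.stratum,
                    "pe": pe,
                    "rr": rr_est.rr,
                    "par": est.par,
                    "ci_lower": est.ci_lower,
                    "ci_upper": est.ci_upper,
                }
            )
        return pd.DataFrame(rows)

    def closed_form_intervals(self) -> pd.DataFrame:
        """Deterministic substitution intervals (the MC oracle)."""
        rows = []
        for rr_est in self.model.rr_estimates:
            pe = self.model.prevalences[(rr_est.factor, rr_est.stratum)].value
            lo, hi = substitution_ci_closed_form(
                pe, rr_est, percentiles=self.percentiles, location=self.location
            )
            rows.append(
                {"factor": rr_est.factor, "outcome": rr_est.outcome,
                 "stratum": rr_est.stratum, "ci_lower": lo, "ci_upper": hi}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Levin PAR estimates (substitution-method Monte Carlo CIs)",
            f"iterations per factor: {self.n_iterations}   "
            f"percentiles: {self.percentiles}   location: {self.location}",
            "",
            f"{'factor':<28}{'outcome':<22}{'stratum':<12}{'PAR % (95% CI)':>24}",
        ]
        for est in self.estimates:
            lines.append(
                f"{est.factor:<28}{est.outcome:<22}{est.stratum:<12}{est.render():>24}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Horizontal point-interval plot of the PAR estimates (percent)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.5 * len(self.estimates) + 1.5))
        labels, points, lows, highs = [], [], [], []
        for est in self.estimates:
            labels.append(f"{est.factor} / {est.outcome} / {est.stratum}")
            points.append(percent(est.par))
            lows.append(percent(est.par) - percent(est.ci_lower))
            highs.append(percent(est.ci_upper) - percent(est.par))
        y = np.arange(len(labels))
        ax.errorbar(points, y, xerr=[lows, highs], fmt="o", capsize=3)
        ax.set_yticks(y, labels)
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("population attributable risk (%)")
        ax.invert_yaxis()
        return ax


class AttributionModel:
    """Multifactor attribution model over an individual-level sample.

    Accepts either an existing :class:`PopulationSample` or a
    :class:`ScenarioConfig` (in which case the population is generated
    at fit time).
    """

    def __init__(self, data):
        if isinstance(data, PopulationSample):
            self.sample = data
            self.config = data.config
        elif isinstance(data, ScenarioConfig):
            self.sample = None
            self.config = data
        else:
            raise TypeError("data must be a PopulationSample or ScenarioConfig")

    @classmethod
    def from_config(cls, config: ScenarioConfig) -> "AttributionModel":
        return cls(config)

    def fit(self) -> "AttributionResults":
        sample = self.sample or generate_population(self.config)
        return AttributionResults(self, build_attribution_report(sample), sample)


class AttributionResults:
    """Fitted multifactor attribution decomposition."""

    def __init__(self, model, report: AttributionReport, sample: PopulationSample):
        self.model = model
        self.report = report
        self.sample = sample

    @property
    def frame(self) -> pd.DataFrame:
        return self.report.table

    @property
    def joint_paf(self) -> float:
        return self.report.joint_paf

    @property
    def overestimation_gap(self) -> float:
        return self.report.overestimation_gap

    def summary(self) -> str:
        return self.report.to_text()

    def plot(self, ax=None):
        """Grouped bars: crude Levin vs average PAF per factor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = self.report.table
        x = np.arange(len(t))
        ax.bar(x - 0.2, 100 * t["crude_levin_par"], width=0.4, label="crude Levin PAR")
        ax.bar(x + 0.2, 100 * t["average_paf"], width=0.4, label="average (Shapley) PAF")
        ax.axhline(100 * self.joint_paf, color="k", ls="--", lw=0.8,
                   label="joint PAF (all factors)")
        ax.set_xticks(x, t["factor"], rotation=20, ha="right")
        ax.set_ylabel("attributable fraction (%)")
        ax.legend()
        return ax
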