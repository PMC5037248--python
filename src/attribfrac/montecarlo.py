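"""Substitution-method confidence intervals for the Levin PAR.

The substitution method treats the exposure prevalence as fixed (its
sampling variability is assumed negligible next to that of the relative
risk) and propagates RR uncertainty through Levin's formula.  Two
routes are provided:

* :func:`monte_carlo_par_ci` — the empirical route: draw ``ln RR`` from
  a normal distribution (i.e. RR lognormal, consistent with a CI that
  is symmetric on the log scale), push each draw through Levin's
  formula, and take empirical percentiles.
* :func:`substitution_ci_closed_form` — the deterministic oracle: since
  Levin's formula is monotone in RR, the PAR percentiles are exactly
  the transformed lognormal RR quantiles.

Percentiles are computed by linear interpolation between order
statistics (``numpy.percentile`` default), which is fixed and
documented here because the percentile estimator is otherwise a silent
degree of freedom.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .levin import ParEstimate, RelativeRiskEstimate, levin_par, par_at_rr_bound

__all__ = [
    "DEFAULT_ITERATIONS",
    "DEFAULT_PERCENTILES",
    "monte_carlo_par_ci",
    "substitution_ci_closed_form",
]

DEFAULT_ITERATIONS = 10_000
DEFAULT_PERCENTILES = (2.5, 97.5)


def _location_log_rr(rr_est: RelativeRiskEstimate, location: str) -> float:
    if location == "point":
        return math.log(rr_est.rr)
    if location == "geometric-mean":
        return math.log(rr_est.geometric_mean_rr)
    raise ValueError(f"unknown location mode {location!r}")


def monte_carlo_par_ci(
    pe: float,
    rr_est: RelativeRiskEstimate,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES,
    location: str = "point",
) -> ParEstimate:
    """Monte Carlo percentile CI for the PAR of one risk factor.

    Draws ``n_iterations`` values of ``ln RR`` from
    ``Normal(location, log_se)``, maps each through Levin's formula at
    fixed prevalence ``pe``, and reports the empirical ``percentiles``
    as confidence limits alongside the point PAR at ``rr_est.rr``.

    Parameters
    ----------
    location : {"point", "geometric-mean"}
        Centre of the log-RR sampling distribution: the log of the
        point estimate (default) or the log-midpoint of the CI bounds.

    Returns
    -------
    ParEstimate
        Reproducible for a fixed ``seed``; the location mode is
        recorded in the estimate's metadata.
    """
    if n_iterations < 2:
        raise ValueError("need at least 2 Monte Carlo iterations")
    if rr_est.log_se is None:
        raise ValueError(
            "relative risk has no CI and no explicit log-scale SE; "
            "cannot propagate uncertainty"
        )
    mu = _location_log_rr(rr_est, location)
    rng = np.random.default_rng(seed)
    log_rr = rng.normal(loc=mu, scale=rr_est.log_se, size=n_iterations)
    par_draws = levin_par(np.full(n_iterations, pe), np.exp(log_rr))
    lo, hi = np.percentile(par_draws, percentiles)
    return ParEstimate(
        factor=rr_est.factor,
        outcome=rr_est.outcome,
        stratum=rr_est.stratum,
        par=levin_par(pe, rr_est.rr),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_iterations=n_iterations,
        seed=seed,
        location=location,
    )


def substitution_ci_closed_form(
    pe: float,
    rr_est: RelativeRiskEstimate,
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES,
    location: str = "point",
) -> tuple[float, float]:
    """Deterministic substitution-method interval for the PAR.

    Evaluates Levin's formula at the exact lognormal RR quantiles
    corresponding to ``percentiles``; by monotonicity this is the
    infinite-iteration limit of :func:`monte_carlo_par_ci`.
    """
    if rr_est.log_se is None:
        raise ValueError("relative risk has no log-scale SE")
    mu = _location_log_rr(rr_est, location)
    z_lo, z_hi = (stats.norm.ppf(p / 100.0) for p in percentiles)
    rr_lo = math.exp(mu + z_lo * rr_est.log_se)
    rr_hi = math.exp(mu + z_hi * rr_est.log_se)
    return (par_at_rr_bound(pe, rr_lo), par_at_rr_bound(pe, rr_hi))
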