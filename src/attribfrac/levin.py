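"""Levin population attributable risk arithmetic.

The population attributable risk proportion (PAR, also PAF) for a
dichotomous exposure is Levin's formula

    PAR = Pe * (RR - 1) / (Pe * (RR - 1) + 1)

where ``Pe`` is the exposure prevalence in the general population and
``RR`` the relative risk of disease in the exposed relative to the
unexposed.  The formula is exact for a single exposure under a
two-group risk model and is the workhorse of comparative risk
assessment.

All quantities in this module live on the proportion scale ``[0, 1)``;
conversion to the percent scale (one decimal, half-up) happens only at
rendering time via :func:`percent` / :func:`format_percent`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "DEFAULT_Z",
    "ExposurePrevalence",
    "RelativeRiskEstimate",
    "ParEstimate",
    "levin_par",
    "invert_rr",
    "log_se_from_ci",
    "par_at_rr_bound",
    "percent",
    "format_percent",
]

#: Normal multiplier for two-sided 95% confidence intervals.
DEFAULT_Z = 1.96


def levin_par(pe, rr):
    """Levin PAR for prevalence ``pe`` and relative risk ``rr``.

    Parameters
    ----------
    pe : float or ndarray
        Exposure prevalence, in ``[0, 1]``.
    rr : float or ndarray
        Relative risk, strictly positive.

    Returns
    -------
    float or ndarray
        ``pe*(rr-1) / (pe*(rr-1) + 1)``, on the proportion scale.
        Negative when ``rr < 1`` (protective exposures are never
        truncated to zero); exactly ``0.0`` when ``rr == 1`` or
        ``pe == 0``.

    Raises
    ------
    ValueError
        If ``pe`` is outside ``[0, 1]``, ``rr`` is non-positive, or the
        denominator ``pe*(rr-1)+1`` is non-positive (reachable only at
        ``pe = 1, rr = 0``).
    """
    pe_arr = np.asarray(pe, dtype=float)
    rr_arr = np.asarray(rr, dtype=float)
    if np.any(pe_arr < 0) or np.any(pe_arr > 1):
        raise ValueError("prevalence must lie in [0, 1]")
    if np.any(rr_arr <= 0):
        raise ValueError("relative risk must be strictly positive")
    excess = pe_arr * (rr_arr - 1.0)
    denom = excess + 1.0
    if np.any(denom <= 0):
        raise ValueError("degenerate denominator: pe*(rr-1)+1 <= 0")
    out = excess / denom
    if out.ndim == 0:
        return float(out)
    return out


def invert_rr(par, pe):
    """Relative risk implied by a PAR at a given prevalence.

    Algebraic inverse of :func:`levin_par` in ``rr``:
    ``rr = 1 + par / (pe * (1 - par))``.  Used to back-derive relative
    risks from published PAR tables when the source cohort estimates
    are not printed.

    Raises
    ------
    ValueError
        If ``par >= 1``, ``pe <= 0``, or the implied ``rr`` would be
        non-positive.
    """
    par_arr = np.asarray(par, dtype=float)
    pe_arr = np.asarray(pe, dtype=float)
    if np.any(par_arr >= 1):
        raise ValueError("PAR must be < 1 on the proportion scale")
    if np.any(pe_arr <= 0) or np.any(pe_arr > 1):
        raise ValueError("prevalence must lie in (0, 1]")
    rr = 1.0 + par_arr / (pe_arr * (1.0 - par_arr))
    if np.any(rr <= 0):
        raise ValueError("implied relative risk is non-positive")
    if rr.ndim == 0:
        return float(rr)
    return rr


def log_se_from_ci(ci_lower, ci_upper, z=DEFAULT_Z):
    """Log-scale standard error extracted from a relative-risk CI.

    Assumes the interval is symmetric on the log scale:
    ``SE = (ln(ci_upper) - ln(ci_lower)) / (2 z)``.

    Raises
    ------
    ValueError
        For non-positive or inverted bounds, or non-positive ``z``.
    """
    if ci_lower <= 0 or ci_upper <= 0:
        raise ValueError("CI bounds must be strictly positive")
    if ci_upper < ci_lower:
        raise ValueError("CI bounds are inverted")
    if z <= 0:
        raise ValueError("normal multiplier z must be positive")
    return (math.log(ci_upper) - math.log(ci_lower)) / (2.0 * z)


def par_at_rr_bound(pe, rr_bound):
    """Levin PAR evaluated at a relative-risk confidence bound.

    Because Levin's formula is strictly monotone in ``RR`` for fixed
    ``pe > 0``, evaluating it at the RR confidence limits yields the
    substitution-method confidence limits for the PAR.  The contract is
    identical to :func:`levin_par`.
    """
    return levin_par(pe, rr_bound)


def percent(value, decimals=1):
    """Render a proportion as a percent, rounded half-up.

    >>> percent(0.25095)
    25.1
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(
        Decimal(repr(float(value) * 100.0)).quantize(quantum, rounding=ROUND_HALF_UP)
    )


def format_percent(value, decimals=1):
    """Proportion -> percent string with a fixed number of decimals."""
    return f"{percent(value, decimals):.{decimals}f}"


@dataclass(frozen=True)
class ExposurePrevalence:
    """Prevalence of one risk factor within one stratum (proportion)."""

    factor: str
    stratum: str
    value: float

    def __post_init__(self):
        if not self.factor or not self.stratum:
            raise ValueError("factor and stratum labels must be non-empty")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"prevalence {self.value!r} outside [0, 1]")


@dataclass(frozen=True)
class RelativeRiskEstimate:
    """Relative risk with a 95% CI and the implied log-scale SE.

    ``log_se`` is derived from the CI on construction when bounds are
    supplied; pass ``log_se`` explicitly when no CI exists.
    """

    factor: str
    outcome: str
    stratum: str
    rr: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    z: float = DEFAULT_Z
    log_se: float | None = field(default=None)

    def __post_init__(self):
        if self.rr <= 0:
            raise ValueError("relative risk must be positive")
        if (self.ci_lower is None) != (self.ci_upper is None):
            raise ValueError("supply both CI bounds or neither")
        if self.ci_lower is not None:
            if not (0 < self.ci_lower <= self.rr <= self.ci_upper):
                raise ValueError(
                    "require 0 < ci_lower <= rr <= ci_upper, got "
                    f"({self.ci_lower}, {self.rr}, {self.ci_upper})"
                )
            if self.log_se is None:
                object.__setattr__(
                    self, "log_se", log_se_from_ci(self.ci_lower, self.ci_upper, self.z)
                )
        if self.log_se is not None and self.log_se < 0:
            raise ValueError("log-scale SE must be non-negative")

    @property
    def geometric_mean_rr(self):
        """Geometric mean of the CI bounds (log-scale midpoint).

        Printed point estimates and CI bounds are independently rounded,
        so the point estimate is rarely the exact log-midpoint; this is
        the alternative Monte Carlo location.
        """
        if self.ci_lower is None:
            return self.rr
        return math.sqrt(self.ci_lower * self.ci_upper)


@dataclass(frozen=True)
class ParEstimate:
    """PAR point estimate with an (optional) empirical percentile CI."""

    factor: str
    outcome: str
    stratum: str
    par: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_iterations: int | None = None
    seed: int | None = None
    location: str = "point"

    def __post_init__(self):
        if self.par >= 1:
            raise ValueError("PAR must be < 1 on the proportion scale")
        if (self.ci_lower is None) != (self.ci_upper is None):
            raise ValueError("supply both CI bounds or neither")
        if self.ci_lower is not None and not (
            self.ci_lower <= self.par <= self.ci_upper
        ):
            raise ValueError(
                f"CI ({self.ci_lower}, {self.ci_upper}) does not bracket PAR {self.par}"
            )

    def render(self):
        """Table-style percent rendering, e.g. ``'25.1 (16.3, 32.8)'``."""
        point = format_percent(self.par)
        if self.ci_lower is None:
            return point
        return f"{point} ({format_percent(self.ci_lower)}, {format_percent(self.ci_upper)})"
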