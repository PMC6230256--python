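"""Population distribution of polygenic relative risk.

Breast-cancer relative risk (RR) implied by common genetic and epidemiological
risk factors is modelled as log-normal across the population: ``ln RR ~
Normal(mu, sigma^2)``.  The package normalizes ``mu = -sigma^2/2`` so that the
population-average relative risk is exactly 1, which is the only convention
under which stratum-specific rates can be obtained by multiplying the
population rates by the stratum mean RR.

Cases are distributed as the population density tilted by RR (a woman's
probability of becoming a case is proportional to her RR), which for a
log-normal base gives another log-normal with the log-mean shifted by
``+sigma^2``.  All tail fractions and truncated means below are closed forms
in the normal CDF; an adaptive-quadrature oracle cross-checks them in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "RiskModel",
    "RiskGroupSummary",
    "rr_at_percentile",
    "fraction_population_above",
    "fraction_cases_above",
    "group_summary",
    "absolute_risk_from_rr",
    "risk_table",
]


@dataclass(frozen=True)
class RiskModel:
    """Log-normal relative-risk distribution plus the baseline absolute risk.

    Parameters
    ----------
    variance_log_rr
        Variance sigma^2 of log relative risk.  Default 0.43: the combined
        variance of the known susceptibility loci and epidemiological risk
        factors (also the midpoint between known-loci and all-common-variant
        estimates).
    baseline_10yr_risk
        Population-average 10-year absolute risk of breast cancer at age 50
        (UK: 2.85%).
    """

    variance_log_rr: float = 0.43
    baseline_10yr_risk: float = 0.0285
    mu_log_rr: float = field(init=False)

    def __post_init__(self) -> None:
        if self.variance_log_rr < 0:
            raise ValueError("variance_log_rr must be >= 0")
        if not 0.0 < self.baseline_10yr_risk < 1.0:
            raise ValueError("baseline_10yr_risk must be in (0, 1)")
        object.__setattr__(self, "mu_log_rr", -self.variance_log_rr / 2.0)

    @property
    def sigma(self) -> float:
        return math.sqrt(self.variance_log_rr)

    @property
    def baseline_10yr_cum_hazard(self) -> float:
        """-ln(1 - baseline_10yr_risk); hazard scale for RR multiplication."""
        return -math.log1p(-self.baseline_10yr_risk)


@dataclass(frozen=True)
class RiskGroupSummary:
    """Quantities defining the two strata split at a risk-score percentile."""

    percentile_threshold: float
    threshold_rr: float
    threshold_absolute_risk: float
    fraction_population_above: float
    fraction_cases_above: float
    mean_rr_above: float
    mean_rr_below: float


def rr_at_percentile(model: RiskModel, p: float) -> float:
    """Relative risk at the p-th percentile of the population distribution.

    ``exp(mu + sigma * Phi^-1(p/100))``; strictly increasing in p.
    """
    if not 0.0 < p < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {p}")
    if model.variance_log_rr == 0.0:
        return 1.0
    return math.exp(model.mu_log_rr + model.sigma * norm.ppf(p / 100.0))


def fraction_population_above(model: RiskModel, threshold_rr: float) -> float:
    """Fraction of the population with RR above ``threshold_rr``.

    Inverse of :func:`rr_at_percentile`: ``1 - Phi((ln t - mu)/sigma)``.
    """
    if threshold_rr <= 0.0:
        raise ValueError("threshold_rr must be > 0")
    if model.variance_log_rr == 0.0:
        return 1.0 if threshold_rr < 1.0 else 0.0
    z = (math.log(threshold_rr) - model.mu_log_rr) / model.sigma
    return float(norm.sf(z))


def fraction_cases_above(model: RiskModel, threshold_rr: float) -> float:
    """Fraction of cases arising among women with RR above ``threshold_rr``.

    The case density is the population density tilted by RR; with the mean-1
    normalization this is ``1 - Phi((ln t - mu - sigma^2)/sigma)``.
    """
    if threshold_rr <= 0.0:
        raise ValueError("threshold_rr must be > 0")
    if model.variance_log_rr == 0.0:
        return 1.0 if threshold_rr < 1.0 else 0.0
    z = (math.log(threshold_rr) - model.mu_log_rr - model.variance_log_rr) / model.sigma
    return float(norm.sf(z))


def group_summary(model: RiskModel, p: float) -> RiskGroupSummary:
    """Split the population at the p-th percentile of risk.

    The mean RR in the upper group is the case fraction over the population
    fraction (and analogously below), so the population-mean RR of 1 is
    conserved: ``q_above * mean_above + q_below * mean_below = 1``.
    """
    t = rr_at_percentile(model, p)
    # exact tail probability by construction, keeping the round trip exact
    q_above = 1.0 - p / 100.0
    if model.variance_log_rr == 0.0:
        # degenerate distribution: every woman has RR 1, cases split like
        # the population
        c_above = q_above
    else:
        c_above = fraction_cases_above(model, t)
    mean_above = c_above / q_above if q_above > 0 else float("nan")
    mean_below = (1.0 - c_above) / (1.0 - q_above) if q_above < 1 else float("nan")
    return RiskGroupSummary(
        percentile_threshold=p,
        threshold_rr=t,
        threshold_absolute_risk=absolute_risk_from_rr(model, t),
        fraction_population_above=q_above,
        fraction_cases_above=c_above,
        mean_rr_above=mean_above,
        mean_rr_below=mean_below,
    )


def absolute_risk_from_rr(model: RiskModel, rr: float) -> float:
    """10-year absolute risk for a woman with relative risk ``rr``.

    Hazard transform ``1 - exp(-rr * Lambda10)`` with Lambda10 the baseline
    10-year cumulative hazard, so probabilities stay below 1 for any rr.
    """
    if rr < 0.0:
        raise ValueError("rr must be >= 0")
    return -math.expm1(-rr * model.baseline_10yr_cum_hazard)


def risk_table(model: RiskModel, percentiles=None) -> "pandas.DataFrame":
    """Tabulate the stratification quantities over a percentile grid."""
    import pandas as pd

    if percentiles is None:
        percentiles = np.arange(1, 100)
    rows = []
    for p in percentiles:
        g = group_summary(model, float(p))
        rows.append(
            {
                "percentile": p,
                "threshold_rr": g.threshold_rr,
                "threshold_absolute_risk": g.threshold_absolute_risk,
                "frac_pop_above": g.fraction_population_above,
                "frac_cases_above": g.fraction_cases_above,
                "mean_rr_above": g.mean_rr_above,
                "mean_rr_below": g.mean_rr_below,
            }
        )
    return pd.DataFrame(rows)
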