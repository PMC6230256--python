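"""Screening strategies and their comparative outcomes.

Three strategy families are modelled for a cohort of 50-year-old women
followed to age 85:

* ``none`` — no screening;
* ``age_based`` — every woman offered triennial mammography at ages
  50, 53, ..., 68 (the standard programme);
* ``risk_stratified`` — polygenic risk is assessed for the whole cohort at
  age 50 (incurring the risk-assessment cost for everyone); only women above
  a chosen percentile of the risk distribution are offered the standard
  screening schedule, the rest are not screened.

A risk-stratified cohort is simulated as two homogeneous strata whose sizes
and mean relative risks come from the truncated log-normal risk
distribution, so the population-mean relative risk of 1 is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import economics as econ_mod
from .life_table import DEFAULT_SCREEN_AGES, CohortTrajectory, run_stratum
from .params import ParameterSet
from .risk_model import group_summary

__all__ = [
    "StrategySpec",
    "StrategyResult",
    "run_strategy",
    "compare",
    "harm_benefit_ratio",
    "sweep",
    "optimal_strategy",
]

MODES = ("none", "age_based", "risk_stratified")


@dataclass(frozen=True)
class StrategySpec:
    """Which women are screened, on what schedule, with what adherence."""

    name: str
    mode: str
    percentile_threshold: Optional[float] = None
    screen_ages: Sequence[int] = DEFAULT_SCREEN_AGES
    adherence: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "risk_stratified":
            if self.percentile_threshold is None:
                raise ValueError("risk_stratified requires percentile_threshold")
            if not 0.0 <= self.percentile_threshold <= 100.0:
                raise ValueError("percentile_threshold must be in [0, 100]")
        elif self.percentile_threshold is not None:
            raise ValueError(f"percentile_threshold is only valid for risk_stratified mode")
        if not 0.0 <= self.adherence <= 1.0:
            raise ValueError("adherence must be in [0, 1]")


@dataclass
class StrategyResult:
    """Aggregated outcomes of one strategy over the full follow-up."""

    spec: StrategySpec
    cohort_size: float
    diagnoses: float
    overdiagnoses: float
    bc_deaths: float
    other_deaths: float
    person_years: float
    qalys: float
    qalys_discounted: float
    cost: float
    cost_discounted: float
    trajectory: Optional[CohortTrajectory] = None

    _COUNT_FIELDS = (
        "diagnoses", "overdiagnoses", "bc_deaths", "other_deaths",
        "person_years", "qalys", "qalys_discounted", "cost", "cost_discounted",
    )

    def per_10000(self, value: float) -> float:
        """Rescale a cohort total to a 10 000-woman cohort."""
        return value * 10_000.0 / self.cohort_size


def run_strategy(params: ParameterSet, spec: StrategySpec) -> StrategyResult:
    """Simulate one strategy on the full cohort.

    ``risk_stratified`` accepts percentile thresholds 0 and 100 as limiting
    cases: at 0 every woman is screened (age-based screening plus the
    cohort-wide risk-assessment cost), at 100 nobody is (no screening plus
    that cost).
    """
    n = params.cohort_size
    epi, econ = params.epidemiology, params.economics
    adherence = spec.adherence
    risk_assessment_cost = 0.0

    if spec.mode == "none":
        traj = run_stratum(epi, econ, n, 1.0, screened=False, adherence=adherence,
                           screen_ages=spec.screen_ages)
    elif spec.mode == "age_based":
        traj = run_stratum(epi, econ, n, 1.0, screened=True, adherence=adherence,
                           screen_ages=spec.screen_ages)
    else:  # risk_stratified
        risk_assessment_cost = n * econ.cost_risk_assessment  # age 50, undiscounted
        p = spec.percentile_threshold
        if p <= 0.0:
            traj = run_stratum(epi, econ, n, 1.0, screened=True, adherence=adherence,
                               screen_ages=spec.screen_ages)
        elif p >= 100.0:
            traj = run_stratum(epi, econ, n, 1.0, screened=False, adherence=adherence,
                               screen_ages=spec.screen_ages)
        else:
            g = group_summary(params.risk, p)
            upper = run_stratum(
                epi, econ, n * g.fraction_population_above, g.mean_rr_above,
                screened=True, adherence=adherence, screen_ages=spec.screen_ages)
            lower = run_stratum(
                epi, econ, n * (1.0 - g.fraction_population_above), g.mean_rr_below,
                screened=False, adherence=adherence, screen_ages=spec.screen_ages)
            traj = upper + lower

    return StrategyResult(
        spec=spec,
        cohort_size=n,
        diagnoses=traj.total_diagnoses,
        overdiagnoses=traj.total_overdiagnoses,
        bc_deaths=traj.total_bc_deaths,
        other_deaths=traj.total_other_deaths,
        person_years=traj.total_person_years,
        qalys=traj.total_qalys,
        qalys_discounted=traj.total_qalys_discounted,
        cost=traj.total_cost + risk_assessment_cost,
        cost_discounted=traj.total_cost_discounted + risk_assessment_cost,
        trajectory=traj,
    )


def compare(a: StrategyResult, b: StrategyResult) -> Dict[str, float]:
    """Element-wise differences of A versus comparator B (A minus B).

    Percent differences use the comparator as denominator.  ``deaths_averted``
    is the comparator's breast-cancer deaths minus A's (positive when A
    prevents deaths relative to B).
    """
    if not math.isclose(a.cohort_size, b.cohort_size):
        raise ValueError("cannot compare strategies run on different cohort sizes")
    out: Dict[str, float] = {}
    for name in StrategyResult._COUNT_FIELDS:
        va, vb = getattr(a, name), getattr(b, name)
        out[f"delta_{name}"] = va - vb
        out[f"pct_{name}"] = 100.0 * (va - vb) / vb if vb != 0 else float("nan")
    out["deaths_averted"] = b.bc_deaths - a.bc_deaths
    out["excess_overdiagnoses"] = a.overdiagnoses - b.overdiagnoses
    out["delta_qaly"] = a.qalys_discounted - b.qalys_discounted
    out["delta_cost"] = a.cost_discounted - b.cost_discounted
    out["icer"] = econ_mod.icer(a.cost_discounted, a.qalys_discounted,
                                b.cost_discounted, b.qalys_discounted)
    out["harm_benefit_ratio"] = harm_benefit_ratio(
        out["excess_overdiagnoses"], out["deaths_averted"])
    return out


def harm_benefit_ratio(overdiagnoses: float, deaths_averted: float) -> float:
    """Overdiagnosed cases per breast-cancer death averted.

    Undefined (NaN) when no deaths are averted, except that zero
    overdiagnoses with zero-or-negative deaths averted is reported as 0.
    """
    if deaths_averted <= 0.0:
        return 0.0 if overdiagnoses == 0.0 else float("nan")
    return overdiagnoses / deaths_averted


def _strategy_specs(params: ParameterSet, percentiles: Iterable[float]):
    adherence = params.adherence
    yield StrategySpec(name="none", mode="none", adherence=adherence)
    yield StrategySpec(name="age_based", mode="age_based", adherence=adherence)
    for p in percentiles:
        yield StrategySpec(
            name=f"risk_p{p:g}", mode="risk_stratified",
            percentile_threshold=float(p), adherence=adherence)


def sweep(
    params: ParameterSet,
    percentiles: Sequence[float] = tuple(range(1, 100)),
    keep_trajectories: bool = False,
) -> pd.DataFrame:
    """Run no screening, age-based screening and every percentile threshold.

    Returns one row per strategy with cohort totals, per-10 000 rescalings
    and comparisons against both the unscreened and the age-based cohorts
    (the curves behind the benefit-harm and incremental cost/QALY figures).
    """
    results = [run_strategy(params, s) for s in _strategy_specs(params, percentiles)]
    none = next(r for r in results if r.spec.mode == "none")
    aged = next(r for r in results if r.spec.mode == "age_based")
    rows = []
    for r in results:
        if not keep_trajectories:
            r.trajectory = None
        p = r.spec.percentile_threshold
        row = {
            "strategy": r.spec.name,
            "mode": r.spec.mode,
            "percentile": p if p is not None else np.nan,
            "fraction_screened": (
                1.0 - p / 100.0 if r.spec.mode == "risk_stratified"
                else (1.0 if r.spec.mode == "age_based" else 0.0)
            ),
            "diagnoses": r.diagnoses,
            "overdiagnoses": r.overdiagnoses,
            "bc_deaths": r.bc_deaths,
            "other_deaths": r.other_deaths,
            "person_years": r.person_years,
            "qalys_discounted": r.qalys_discounted,
            "cost_discounted": r.cost_discounted,
        }
        for key in ("diagnoses", "overdiagnoses", "bc_deaths", "qalys_discounted",
                    "cost_discounted"):
            row[f"{key}_per_10000"] = r.per_10000(row[key])
        vs_none = compare(r, none)
        row["deaths_averted_vs_none"] = vs_none["deaths_averted"]
        row["delta_cost_vs_none"] = vs_none["delta_cost"]
        row["delta_qaly_vs_none"] = vs_none["delta_qaly"]
        row["icer_vs_none"] = (
            vs_none["icer"] if isinstance(vs_none["icer"], float) else np.nan)
        row["icer_vs_none_flag"] = (
            "" if isinstance(vs_none["icer"], float) else vs_none["icer"])
        row["harm_benefit_vs_none"] = vs_none["harm_benefit_ratio"]
        vs_aged = compare(r, aged)
        row["delta_cost_vs_age_based"] = vs_aged["delta_cost"]
        row["delta_qaly_vs_age_based"] = vs_aged["delta_qaly"]
        row["delta_overdiagnoses_vs_age_based"] = vs_aged["excess_overdiagnoses"]
        row["deaths_averted_vs_age_based"] = vs_aged["deaths_averted"]
        for w in params.economics.wtp_grid:
            row[f"nmb_wtp_{w:g}"] = econ_mod.nmb(r.qalys_discounted, r.cost_discounted, w)
        rows.append(row)
    return pd.DataFrame(rows)


def optimal_strategy(results: pd.DataFrame, wtp: float) -> pd.Series:
    """Row with the highest net monetary benefit at the given WTP.

    Ties break toward lower total cost, then toward a higher percentile
    threshold (fewer women screened).
    """
    if len(results) == 0:
        raise ValueError("optimal_strategy requires at least one result")
    nmb = results["qalys_discounted"] * wtp - results["cost_discounted"]
    df = results.assign(_nmb=nmb)
    df = df.sort_values(
        by=["_nmb", "cost_discounted", "percentile"],
        ascending=[False, True, False],
        na_position="last",
    )
    return df.iloc[0].drop(labels="_nmb")
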