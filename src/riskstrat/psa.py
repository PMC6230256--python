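"""Probabilistic and univariate deterministic sensitivity analysis.

The probabilistic sensitivity analysis (PSA) samples every uncertain
parameter independently from its distribution, reruns every strategy on
each draw and summarizes the per-draw outcome matrix: means, equal-tailed
95% percentile intervals, cost-effectiveness acceptability curves (CEACs)
and the probability each strategy has the highest net monetary benefit at
each willingness-to-pay value.  Common random numbers are used across
strategies within a draw, so incremental NMB distributions are paired —
which is what the CEAC definition (fraction of draws with positive
incremental NMB) requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import ceac, nmb
from .params import PARAMETER_NAMES, DistributionSpec, ParameterSet, apply_overrides
from .strategies import StrategySpec, StrategyResult, compare, run_strategy

__all__ = ["PSAResult", "sample_parameters", "run_psa", "univariate_sweep"]

_OUTCOMES = ("qalys_discounted", "cost_discounted", "bc_deaths", "overdiagnoses", "diagnoses")


@dataclass
class PSAResult:
    """Per-draw outcome matrices plus summaries."""

    strategies: List[StrategySpec]
    draws: pd.DataFrame  # columns: draw, strategy, and one column per outcome
    parameter_draws: pd.DataFrame
    wtp_grid: Sequence[float]
    comparator: str

    def matrix(self, outcome: str) -> pd.DataFrame:
        """Draws x strategies matrix for one outcome."""
        return self.draws.pivot(index="draw", columns="strategy", values=outcome)

    def summary(self) -> pd.DataFrame:
        """Mean and equal-tailed 95% interval per strategy and outcome."""
        rows = []
        for spec in self.strategies:
            sub = self.draws[self.draws["strategy"] == spec.name]
            row = {"strategy": spec.name}
            for out in _OUTCOMES:
                v = sub[out].to_numpy()
                row[f"{out}_mean"] = v.mean()
                row[f"{out}_lo95"] = np.quantile(v, 0.025)
                row[f"{out}_hi95"] = np.quantile(v, 0.975)
            rows.append(row)
        return pd.DataFrame(rows)

    def incremental_nmb(self, strategy: str, wtp: float) -> np.ndarray:
        """Paired per-draw incremental NMB of a strategy vs the comparator."""
        q = self.matrix("qalys_discounted")
        c = self.matrix("cost_discounted")
        dq = q[strategy] - q[self.comparator]
        dc = c[strategy] - c[self.comparator]
        return (dq * wtp - dc).to_numpy()

    def ceac_table(self, wtp_grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
        """Probability cost-effective vs the comparator, per strategy and WTP."""
        grid = list(wtp_grid if wtp_grid is not None else self.wtp_grid)
        rows = []
        for spec in self.strategies:
            if spec.name == self.comparator:
                continue
            row = {"strategy": spec.name}
            for w in grid:
                row[f"prob_ce_wtp_{w:g}"] = ceac(self.incremental_nmb(spec.name, w))
            rows.append(row)
        return pd.DataFrame(rows)

    def prob_optimal(self, wtp: float) -> pd.Series:
        """Fraction of draws in which each strategy has the highest NMB."""
        q = self.matrix("qalys_discounted")
        c = self.matrix("cost_discounted")
        nmb_matrix = q * wtp - c
        winners = nmb_matrix.idxmax(axis=1)
        counts = winners.value_counts(normalize=True)
        return counts.reindex([s.name for s in self.strategies], fill_value=0.0)

    def mean_icer(self, strategy: str):
        """ICER from PSA means (difference of mean costs over mean QALYs)."""
        from .economics import icer

        s = self.summary().set_index("strategy")
        return icer(
            s.loc[strategy, "cost_discounted_mean"],
            s.loc[strategy, "qalys_discounted_mean"],
            s.loc[self.comparator, "cost_discounted_mean"],
            s.loc[self.comparator, "qalys_discounted_mean"],
        )


def sample_parameters(
    params: ParameterSet,
    rng: np.random.Generator,
    specs: Optional[Dict[str, DistributionSpec]] = None,
):
    """Draw one ParameterSet from the uncertainty distributions.

    Draws are applied through :func:`riskstrat.params.apply_overrides`;
    ``fixed`` families return the point estimate.  Returns ``(draw, values)``
    where ``values`` maps parameter names to the sampled numbers.
    """
    specs = specs if specs is not None else params.psa_specs
    # sample in sorted name order so results depend only on the rng state,
    # not on dict insertion order
    values = {name: float(specs[name].sample(rng)) for name in sorted(specs)}
    return apply_overrides(params, values), values


def run_psa(
    params: ParameterSet,
    strategy_specs: Sequence[StrategySpec],
    n_draws: int = 2000,
    seed: int = 0,
    wtp_grid: Optional[Sequence[float]] = None,
    comparator: Optional[str] = None,
) -> PSAResult:
    """Rerun every strategy on each of ``n_draws`` parameter draws.

    The same drawn ParameterSet is used for every strategy within a draw
    (common random numbers), so comparisons are paired.  Identical seeds
    yield identical results.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    strategy_specs = list(strategy_specs)
    if comparator is None:
        comparator = next(
            (s.name for s in strategy_specs if s.mode == "none"), strategy_specs[0].name)
    rng = np.random.default_rng(seed)
    rows = []
    param_rows = []
    for d in range(n_draws):
        drawn, values = sample_parameters(params, rng)
        param_rows.append({"draw": d, **values})
        for spec in strategy_specs:
            r = run_strategy(drawn, spec)
            rows.append({
                "draw": d,
                "strategy": spec.name,
                **{out: getattr(r, out) for out in _OUTCOMES},
            })
    grid = list(wtp_grid if wtp_grid is not None else params.economics.wtp_grid)
    return PSAResult(
        strategies=strategy_specs,
        draws=pd.DataFrame(rows),
        parameter_draws=pd.DataFrame(param_rows),
        wtp_grid=grid,
        comparator=comparator,
    )


def univariate_sweep(
    params: ParameterSet,
    parameter_name: str,
    grid: Sequence[float],
    percentile: float = 70.0,
) -> pd.DataFrame:
    """Deterministic one-at-a-time sweep of a named parameter.

    At each grid value the no-screening, age-based and risk-stratified
    (given percentile) strategies are rerun with everything else at its
    point estimate.  Valid names are listed in
    :data:`riskstrat.params.PARAMETER_NAMES`.
    """
    if parameter_name not in PARAMETER_NAMES:
        raise KeyError(
            f"unknown parameter {parameter_name!r}; valid names: {list(PARAMETER_NAMES)}")
    rows = []
    for value in grid:
        p = apply_overrides(params, {parameter_name: float(value)})
        specs = [
            StrategySpec(name="none", mode="none", adherence=p.adherence),
            StrategySpec(name="age_based", mode="age_based", adherence=p.adherence),
            StrategySpec(
                name=f"risk_p{percentile:g}", mode="risk_stratified",
                percentile_threshold=percentile, adherence=p.adherence),
        ]
        results = {s.name: run_strategy(p, s) for s in specs}
        none = results["none"]
        for name, r in results.items():
            vs_none = compare(r, none) if name != "none" else None
            row = {
                "parameter": parameter_name,
                "value": value,
                "strategy": name,
                "diagnoses": r.diagnoses,
                "overdiagnoses": r.overdiagnoses,
                "bc_deaths": r.bc_deaths,
                "qalys_discounted": r.qalys_discounted,
                "cost_discounted": r.cost_discounted,
            }
            if vs_none is not None:
                row["deaths_averted_vs_none"] = vs_none["deaths_averted"]
                row["delta_cost_vs_none"] = vs_none["delta_cost"]
                row["delta_qaly_vs_none"] = vs_none["delta_qaly"]
                row["harm_benefit_vs_none"] = vs_none["harm_benefit_ratio"]
            rows.append(row)
    return pd.DataFrame(rows)
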