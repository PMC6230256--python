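#!/usr/bin/env python
"""Sweep all 99 risk-threshold scenarios plus the two comparators.

Writes results/threshold_sweep.csv (the curves behind the benefit-harm
figure and the incremental cost/QALY figure) and prints the qualitative
story: harm-benefit ratio rising as screening extends to lower-risk women,
the ICER-minimising threshold, and the net-monetary-benefit optimum at
£20 000 and £30 000 per QALY.
"""

from pathlib import Path

from riskstrat.params import default_parameters
from riskstrat.strategies import optimal_strategy, sweep

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = default_parameters()
    grid = sweep(params)
    OUT.mkdir(exist_ok=True)
    grid.to_csv(OUT / "threshold_sweep.csv", index=False)

    rs = grid[grid["mode"] == "risk_stratified"]
    for pct in (99, 71, 50, 25, 1):
        row = rs[rs["percentile"] == pct].iloc[0]
        print(f"  {pct:>2}th percentile ({100 - pct:>2}% screened): "
              f"overdiagnoses/10k {row['overdiagnoses_per_10000']:6.1f}, "
              f"deaths averted/10k {row['deaths_averted_vs_none'] * 10_000 / params.cohort_size:5.1f}, "
              f"harm-benefit {row['harm_benefit_vs_none']:5.2f}, "
              f"ICER £{row['icer_vs_none']:,.0f}")
    imin = rs["icer_vs_none"].idxmin()
    print(f"ICER minimised at the {rs.loc[imin, 'percentile']:.0f}th percentile "
          f"(£{rs.loc[imin, 'icer_vs_none']:,.0f}/QALY)")
    for wtp in (20_000.0, 30_000.0):
        best = optimal_strategy(grid, wtp)
        print(f"highest NMB at £{wtp:,.0f}/QALY: {best['strategy']}")
    print(f"wrote {OUT / 'threshold_sweep.csv'} ({len(grid)} strategies)")


if __name__ == "__main__":
    main()
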