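"""Comparative health economics: ICER, net monetary benefit, CEAC.

Conventions follow standard practice: the incremental cost-effectiveness
ratio (ICER) is only a meaningful number in the north-east / south-west
quadrants of the cost-effectiveness plane; when one strategy is both cheaper
and more effective a dominance flag replaces the ratio.  Net monetary
benefit NMB = QALYs x WTP - cost converts everything to currency at a given
willingness to pay, and the cost-effectiveness acceptability curve (CEAC) is
the fraction of probabilistic-sensitivity-analysis draws in which the
incremental NMB is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = ["EconomicParams", "CEAResult", "icer", "nmb", "ceac", "compare_cea"]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"

_N_AGES = 35  # annual cycles, ages 50..84


def _age_array(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(_N_AGES, float(arr))
    if arr.shape != (_N_AGES,):
        raise ValueError(f"{name} must be scalar or one value per age 50..84")
    return arr


@dataclass(frozen=True)
class EconomicParams:
    """Unit costs (pounds sterling), utility weights and discounting.

    ``utility_healthy`` / ``utility_post_diagnosis`` may be scalars or
    age-indexed arrays (ages 50..84); the post-diagnosis weight applies to
    every woman living with a breast-cancer diagnosis regardless of stage.
    """

    cost_per_screen: float
    cost_per_invitation: float
    cost_risk_assessment: float
    cost_treatment_per_case: float
    utility_healthy: np.ndarray
    utility_post_diagnosis: np.ndarray
    discount_rate: float = 0.035
    wtp_grid: tuple = (20_000.0, 30_000.0)

    def __post_init__(self) -> None:
        for name in ("cost_per_screen", "cost_per_invitation",
                     "cost_risk_assessment", "cost_treatment_per_case"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        uh = _age_array(self.utility_healthy, "utility_healthy")
        up = _age_array(self.utility_post_diagnosis, "utility_post_diagnosis")
        if np.any(uh > 1.0) or np.any(up < 0.0) or np.any(up > uh):
            raise ValueError("require 0 <= utility_post_diagnosis <= utility_healthy <= 1")
        object.__setattr__(self, "utility_healthy", uh)
        object.__setattr__(self, "utility_post_diagnosis", up)
        object.__setattr__(self, "wtp_grid", tuple(float(w) for w in self.wtp_grid))


@dataclass
class CEAResult:
    """Pairwise economic comparison of strategy A versus comparator B."""

    delta_cost: float
    delta_qaly: float
    icer: Union[float, str]
    nmb_by_wtp: dict = field(default_factory=dict)
    prob_cost_effective_by_wtp: dict = field(default_factory=dict)


def icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float) -> Union[float, str]:
    """ICER of A versus B, or a dominance flag.

    Returns ``"dominant"`` when A is cheaper and at least as effective,
    ``"dominated"`` when A is dearer and less effective, and ``"undefined"``
    when QALYs are tied but costs differ.
    """
    for v in (cost_a, qaly_a, cost_b, qaly_b):
        if not np.isfinite(v):
            raise ValueError("icer() requires finite inputs")
    dc = cost_a - cost_b
    dq = qaly_a - qaly_b
    if dq == 0.0:
        return 0.0 if dc == 0.0 else UNDEFINED
    if dc < 0.0 and dq > 0.0:
        return DOMINANT
    if dc > 0.0 and dq < 0.0:
        return DOMINATED
    return dc / dq


def nmb(qaly: float, cost: float, wtp: float) -> float:
    """Net monetary benefit: qaly * wtp - cost."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return qaly * wtp - cost


def ceac(incremental_nmb_samples) -> float:
    """Fraction of PSA draws with strictly positive incremental NMB."""
    samples = np.asarray(incremental_nmb_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("ceac() requires at least one sample")
    return float(np.mean(samples > 0.0))


def compare_cea(
    cost_a: float,
    qaly_a: float,
    cost_b: float,
    qaly_b: float,
    wtp_grid=(20_000.0, 30_000.0),
    incremental_nmb_samples_by_wtp=None,
) -> CEAResult:
    """Full pairwise comparison: deltas, ICER, NMB per WTP, optional CEAC."""
    dc = cost_a - cost_b
    dq = qaly_a - qaly_b
    result = CEAResult(delta_cost=dc, delta_qaly=dq, icer=icer(cost_a, qaly_a, cost_b, qaly_b))
    for w in wtp_grid:
        result.nmb_by_wtp[w] = nmb(dq, dc, w)
    if incremental_nmb_samples_by_wtp is not None:
        for w, samples in incremental_nmb_samples_by_wtp.items():
            result.prob_cost_effective_by_wtp[w] = ceac(samples)
    return result
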