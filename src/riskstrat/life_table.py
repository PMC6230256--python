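"""Deterministic life-table simulation of one cohort stratum.

A stratum is a group of women sharing a relative-risk multiplier and a
screening status, followed in discrete annual cycles from age 50 to 85
(35 cycles).  Four states are tracked: alive without breast cancer, alive
with breast cancer (split internally into clinically arising and
overdiagnosed cases), dead of breast cancer, dead of other causes.

Cycle order (no half-cycle correction): screening costs are charged at
screen ages, then incident diagnoses occur, then breast-cancer deaths
(from the clinically diagnosed pool), then other-cause deaths (all alive
states).  Person-years and QALYs are credited to end-of-cycle survivors.

Rate conventions
----------------
* ``bc_incidence`` is an annual probability of diagnosis for a cancer-free
  woman; within a stratum it is multiplied by the stratum relative risk.
* ``bc_mortality_unscreened`` is the population-level breast-cancer death
  rate per woman-year (not a case fatality conditional on diagnosis).  It
  too is multiplied by the stratum relative risk, so both stratum rates are
  the overall rates scaled by the stratum mean RR.  For state accounting the
  resulting deaths are drawn from the clinically diagnosed pool (capped at
  its size).
* For screened attenders the breast-cancer death rate is multiplied by
  ``bc_mortality_rr_screened`` (< 1), the program-level mortality reduction
  of mammography screening, from the first screen onward (optionally only
  during the screening period).
* Overdiagnosis is risk-independent: during the screening period attending
  cancer-free women acquire an additional screen-detected-only diagnosis
  hazard of ``overdiagnosis_fraction x baseline (RR-unmultiplied) incidence``.
  Overdiagnosed cases count as diagnoses, incur treatment cost and the
  post-diagnosis utility decrement, and never die of breast cancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AGE_START",
    "AGE_END",
    "DEFAULT_SCREEN_AGES",
    "EpidemiologyParams",
    "CohortTrajectory",
    "run_stratum",
    "overdiagnoses",
    "discounted_sum",
]

AGE_START = 50
AGE_END = 85  # exclusive upper bound of the last cycle (cycles cover 50..84)
DEFAULT_SCREEN_AGES = tuple(range(50, 69, 3))  # 50, 53, ..., 68


@dataclass(frozen=True)
class EpidemiologyParams:
    """Age-specific rates and screening effect sizes for the life table.

    All age-indexed arrays cover ages 50..84 inclusive (one value per annual
    cycle, 35 values).
    """

    bc_incidence: np.ndarray
    bc_mortality_unscreened: np.ndarray
    other_cause_mortality: np.ndarray
    bc_mortality_rr_screened: float
    overdiagnosis_fraction: float
    screen_start_age: int = 50
    screen_end_age: int = 69
    # if False, the screening mortality reduction applies only at ages within
    # the screening period rather than for the remainder of follow-up
    mortality_reduction_lifelong: bool = True

    def __post_init__(self) -> None:
        n = AGE_END - AGE_START
        for name in ("bc_incidence", "bc_mortality_unscreened", "other_cause_mortality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(
                    f"{name} must have one value per age 50..84 ({n}), got shape {arr.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)
        if not 0.0 < self.bc_mortality_rr_screened <= 1.0:
            raise ValueError("bc_mortality_rr_screened must be in (0, 1]")
        if not 0.0 <= self.overdiagnosis_fraction < 1.0:
            raise ValueError("overdiagnosis_fraction must be in [0, 1)")
        if not AGE_START <= self.screen_start_age < self.screen_end_age <= 69:
            raise ValueError("screening period must satisfy 50 <= start < end <= 69")


@dataclass
class CohortTrajectory:
    """Year-by-year state occupancy, events, person-years, QALYs and costs.

    State arrays hold end-of-cycle counts; event arrays hold within-cycle
    flows.  ``qalys``/``costs`` are undiscounted; the ``*_discounted``
    companions apply the annual discount factor of the year the amount
    accrues (age 50 undiscounted).
    """

    ages: np.ndarray
    alive_no_bc: np.ndarray
    alive_with_bc: np.ndarray
    dead_bc: np.ndarray
    dead_other: np.ndarray
    new_diagnoses: np.ndarray
    new_overdiagnoses: np.ndarray
    bc_deaths: np.ndarray
    other_deaths: np.ndarray
    person_years: np.ndarray
    qalys: np.ndarray
    qalys_discounted: np.ndarray
    costs: np.ndarray
    costs_discounted: np.ndarray
    initial_size: float
    screened: bool

    def __add__(self, other: "CohortTrajectory") -> "CohortTrajectory":
        if not np.array_equal(self.ages, other.ages):
            raise ValueError("cannot add trajectories over different age grids")
        kwargs = {"ages": self.ages, "screened": self.screened or other.screened}
        for name in (
            "alive_no_bc", "alive_with_bc", "dead_bc", "dead_other",
            "new_diagnoses", "new_overdiagnoses", "bc_deaths", "other_deaths",
            "person_years", "qalys", "qalys_discounted", "costs", "costs_discounted",
        ):
            kwargs[name] = getattr(self, name) + getattr(other, name)
        kwargs["initial_size"] = self.initial_size + other.initial_size
        return CohortTrajectory(**kwargs)

    # cumulative totals -------------------------------------------------
    @property
    def total_diagnoses(self) -> float:
        return float(self.new_diagnoses.sum())

    @property
    def total_overdiagnoses(self) -> float:
        return float(self.new_overdiagnoses.sum())

    @property
    def total_bc_deaths(self) -> float:
        return float(self.bc_deaths.sum())

    @property
    def total_other_deaths(self) -> float:
        return float(self.other_deaths.sum())

    @property
    def total_person_years(self) -> float:
        return float(self.person_years.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qalys.sum())

    @property
    def total_qalys_discounted(self) -> float:
        return float(self.qalys_discounted.sum())

    @property
    def total_cost(self) -> float:
        return float(self.costs.sum())

    @property
    def total_cost_discounted(self) -> float:
        return float(self.costs_discounted.sum())

    def to_frame(self) -> "pandas.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "age": self.ages,
                "alive_no_bc": self.alive_no_bc,
                "alive_with_bc": self.alive_with_bc,
                "dead_bc": self.dead_bc,
                "dead_other": self.dead_other,
                "new_diagnoses": self.new_diagnoses,
                "new_overdiagnoses": self.new_overdiagnoses,
                "bc_deaths": self.bc_deaths,
                "other_deaths": self.other_deaths,
                "person_years": self.person_years,
                "qalys": self.qalys,
                "qalys_discounted": self.qalys_discounted,
                "costs": self.costs,
                "costs_discounted": self.costs_discounted,
            }
        )


def _run_homogeneous(
    epi: EpidemiologyParams,
    econ,
    size: float,
    stratum_rr: float,
    screened: bool,
    invited: bool,
    screen_ages: Sequence[int],
) -> CohortTrajectory:
    """Run one homogeneous group (uniform attendance behaviour)."""
    n = AGE_END - AGE_START
    ages = np.arange(AGE_START, AGE_END)
    out = {
        name: np.zeros(n)
        for name in (
            "alive_no_bc", "alive_with_bc", "dead_bc", "dead_other",
            "new_diagnoses", "new_overdiagnoses", "bc_deaths", "other_deaths",
            "person_years", "qalys", "qalys_discounted", "costs", "costs_discounted",
        )
    }
    screen_ages = set(screen_ages)
    dr = econ.discount_rate
    no_bc = float(size)
    with_bc_clin = 0.0
    with_bc_od = 0.0
    dead_bc = 0.0
    dead_other = 0.0
    first_screen = min(screen_ages) if screen_ages else None

    for i in range(n):
        age = AGE_START + i
        df = 1.0 / (1.0 + dr) ** i
        cost = 0.0

        # screening invitations and attended screens (cancer-free women only)
        if invited and age in screen_ages:
            cost += no_bc * econ.cost_per_invitation
            if screened:
                cost += no_bc * econ.cost_per_screen

        # incident diagnoses
        q_inc = min(epi.bc_incidence[i] * stratum_rr, 1.0)
        dx_clin = no_bc * q_inc
        dx_od = 0.0
        if screened and epi.screen_start_age <= age < epi.screen_end_age:
            q_od = epi.overdiagnosis_fraction * epi.bc_incidence[i]
            dx_od = no_bc * min(q_od, max(1.0 - q_inc, 0.0))
        no_bc -= dx_clin + dx_od
        with_bc_clin += dx_clin
        with_bc_od += dx_od
        cost += (dx_clin + dx_od) * econ.cost_treatment_per_case

        # breast-cancer deaths: population-level rate x stratum RR, drawn
        # from the clinically diagnosed pool (overdiagnosed cases immune)
        q_bc = epi.bc_mortality_unscreened[i] * stratum_rr
        if screened and (
            epi.mortality_reduction_lifelong or age < epi.screen_end_age
        ) and (first_screen is None or age >= first_screen):
            q_bc *= epi.bc_mortality_rr_screened
        d_bc = min((no_bc + with_bc_clin + with_bc_od) * q_bc, with_bc_clin)
        with_bc_clin -= d_bc
        dead_bc += d_bc

        # other-cause deaths (all alive states, same rate)
        q_oth = epi.other_cause_mortality[i]
        d_oth = (no_bc + with_bc_clin + with_bc_od) * q_oth
        no_bc *= 1.0 - q_oth
        with_bc_clin *= 1.0 - q_oth
        with_bc_od *= 1.0 - q_oth
        dead_other += d_oth

        with_bc = with_bc_clin + with_bc_od
        py = no_bc + with_bc
        qaly = no_bc * econ.utility_healthy[i] + with_bc * econ.utility_post_diagnosis[i]

        out["alive_no_bc"][i] = no_bc
        out["alive_with_bc"][i] = with_bc
        out["dead_bc"][i] = dead_bc
        out["dead_other"][i] = dead_other
        out["new_diagnoses"][i] = dx_clin + dx_od
        out["new_overdiagnoses"][i] = dx_od
        out["bc_deaths"][i] = d_bc
        out["other_deaths"][i] = d_oth
        out["person_years"][i] = py
        out["qalys"][i] = qaly
        out["qalys_discounted"][i] = qaly * df
        out["costs"][i] = cost
        out["costs_discounted"][i] = cost * df

    return CohortTrajectory(ages=ages, initial_size=float(size), screened=screened, **out)


def run_stratum(
    epi: EpidemiologyParams,
    econ,
    stratum_size: float,
    stratum_rr: float,
    screened: bool,
    adherence: float = 1.0,
    screen_ages: Sequence[int] = DEFAULT_SCREEN_AGES,
) -> CohortTrajectory:
    """Simulate one stratum age 50 -> 85.

    If the stratum is offered screening, a fraction ``adherence`` attends
    (receives the mortality reduction, contributes overdiagnoses, incurs
    screen costs); the remainder are invited but follow unscreened rates.
    """
    if stratum_size < 0:
        raise ValueError("stratum_size must be >= 0")
    if stratum_rr <= 0:
        raise ValueError("stratum_rr must be > 0")
    if not 0.0 <= adherence <= 1.0:
        raise ValueError("adherence must be in [0, 1]")
    if not screened:
        return _run_homogeneous(
            epi, econ, stratum_size, stratum_rr, screened=False, invited=False,
            screen_ages=screen_ages,
        )
    attending = _run_homogeneous(
        epi, econ, stratum_size * adherence, stratum_rr, screened=True,
        invited=True, screen_ages=screen_ages,
    )
    if adherence == 1.0:
        return attending
    non_attending = _run_homogeneous(
        epi, econ, stratum_size * (1.0 - adherence), stratum_rr, screened=False,
        invited=True, screen_ages=screen_ages,
    )
    traj = attending + non_attending
    traj.screened = True
    return traj


def overdiagnoses(
    traj: CohortTrajectory,
    screen_start_age: int = 50,
    screen_end_age: int = 69,
    strict: bool = True,
) -> float:
    """Overdiagnosed cases occurring within the screening period.

    Overdiagnoses only arise in screened trajectories; calling this on an
    unscreened trajectory is a logic error (returns 0 with a warning when
    ``strict`` is False).
    """
    if not 50 <= screen_start_age < screen_end_age <= 69:
        raise ValueError("require 50 <= start < end <= 69")
    if not traj.screened:
        if strict:
            raise ValueError("overdiagnoses() called on an unscreened trajectory")
        import warnings

        warnings.warn("unscreened trajectory has no overdiagnoses", stacklevel=2)
        return 0.0
    mask = (traj.ages >= screen_start_age) & (traj.ages < screen_end_age)
    return float(traj.new_overdiagnoses[mask].sum())


def discounted_sum(stream, rate: float, base_year: int = 0) -> float:
    """Present value of a per-year stream: sum of stream[y]/(1+rate)^(y-base)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    stream = np.asarray(stream, dtype=float)
    if stream.size == 0:
        return 0.0
    years = np.arange(stream.size)
    return float(np.sum(stream / (1.0 + rate) ** (years - base_year)))
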