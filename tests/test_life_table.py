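"""Life-table mechanics: conservation, the hand-computed toy oracle,
screening effects and discounting."""

import numpy as np
import pytest
from dataclasses import replace

from riskstrat.life_table import discounted_sum, overdiagnoses, run_stratum
from riskstrat.params import apply_overrides, toy_parameters
from riskstrat.risk_model import group_summary


def run_toy(toy_params, **kw):
    args = dict(stratum_size=1000.0, stratum_rr=1.0, screened=False, adherence=1.0)
    args.update(kw)
    return run_stratum(toy_params.epidemiology, toy_params.economics, **args)


class TestToyHandOracle:
    """3-cycle spreadsheet oracle for the flat-rate miniature.

    Recurrence per cycle (size 1000, incidence 0.01, population BC death
    rate 0.005, other-cause mortality 0.02):
        dx      = no_bc * 0.01
        d_bc    = min((no_bc + with_bc) * 0.005, with_bc)   [after dx moves]
        d_other = (no_bc + with_bc) * 0.02
    Hand-computed values below (exact to the recurrence).
    """

    # per-cycle expectations: (dx, d_bc, d_other, no_bc_end, with_bc_end)
    EXPECT = [
        (10.0, 5.0, 19.9, 970.2, 4.9),
        (9.702, 4.8755, 19.40449, 941.28804, 9.53197),
        (9.4128804, 4.75410005, 18.921318199, 913.2376564079999, 13.906935343),
    ]

    def test_first_three_cycles_match_hand_calculation(self, toy_params):
        traj = run_toy(toy_params)
        for i, (dx, dbc, doth, nobc, wbc) in enumerate(self.EXPECT):
            assert traj.new_diagnoses[i] == pytest.approx(dx, abs=1e-9)
            assert traj.bc_deaths[i] == pytest.approx(dbc, abs=1e-9)
            assert traj.other_deaths[i] == pytest.approx(doth, abs=1e-9)
            assert traj.alive_no_bc[i] == pytest.approx(nobc, abs=1e-9)
            assert traj.alive_with_bc[i] == pytest.approx(wbc, abs=1e-9)

    def test_cumulative_three_cycle_totals(self, toy_params):
        traj = run_toy(toy_params)
        assert traj.new_diagnoses[:3].sum() == pytest.approx(29.1148804, abs=1e-7)
        assert traj.bc_deaths[:3].sum() == pytest.approx(14.62960005, abs=1e-8)
        assert traj.person_years[:3].sum() == pytest.approx(2853.064601751, abs=1e-7)

    def test_screened_first_cycle_overdiagnoses(self, toy_params):
        # od hazard = fraction 0.2 x baseline incidence 0.01 applied to the
        # 1000 cancer-free women: 2.0 overdiagnoses in cycle 1
        traj = run_toy(toy_params, screened=True)
        assert traj.new_overdiagnoses[0] == pytest.approx(2.0, abs=1e-12)
        assert traj.new_diagnoses[0] == pytest.approx(12.0, abs=1e-12)


class TestConservation:
    @pytest.mark.parametrize("screened", [False, True])
    @pytest.mark.parametrize("rr", [0.3, 1.0, 2.5])
    def test_states_sum_to_initial_size_every_cycle(self, toy_params, screened, rr):
        traj = run_toy(toy_params, screened=screened, stratum_rr=rr)
        total = traj.alive_no_bc + traj.alive_with_bc + traj.dead_bc + traj.dead_other
        assert np.allclose(total, 1000.0, atol=1e-6)

    def test_conservation_on_default_parameters(self, default_params):
        epi, econ = default_params.epidemiology, default_params.economics
        traj = run_stratum(epi, econ, 364_500.0, 1.0, screened=True, adherence=0.8)
        total = traj.alive_no_bc + traj.alive_with_bc + traj.dead_bc + traj.dead_other
        assert np.allclose(total, 364_500.0, atol=1e-6)

    def test_dead_states_non_decreasing(self, default_params):
        epi, econ = default_params.epidemiology, default_params.economics
        traj = run_stratum(epi, econ, 1000.0, 1.4, screened=True)
        assert np.all(np.diff(traj.dead_bc) >= 0)
        assert np.all(np.diff(traj.dead_other) >= 0)


class TestScreeningEffects:
    def test_zero_incidence_gives_pure_survival_curve(self, toy_params):
        epi = replace(toy_params.epidemiology, bc_incidence=np.zeros(35))
        traj = run_stratum(epi, toy_params.economics, 1000.0, 1.0, screened=False)
        assert traj.total_diagnoses == 0
        assert traj.total_bc_deaths == 0
        expected_alive = 1000.0 * 0.98 ** np.arange(1, 36)
        assert np.allclose(traj.alive_no_bc, expected_alive, rtol=1e-12)

    def test_null_screening_effect_equals_unscreened(self, toy_params):
        epi = replace(toy_params.epidemiology,
                      bc_mortality_rr_screened=1.0, overdiagnosis_fraction=0.0)
        unscreened = run_stratum(epi, toy_params.economics, 1000.0, 1.0, screened=False)
        screened = run_stratum(epi, toy_params.economics, 1000.0, 1.0, screened=True)
        assert screened.total_diagnoses == pytest.approx(unscreened.total_diagnoses)
        assert screened.total_bc_deaths == pytest.approx(unscreened.total_bc_deaths)
        assert screened.total_person_years == pytest.approx(unscreened.total_person_years)
        # only screening costs differ
        assert screened.total_cost > unscreened.total_cost

    def test_higher_rr_increases_diagnoses_and_bc_deaths(self, default_params):
        epi, econ = default_params.epidemiology, default_params.economics
        runs = [run_stratum(epi, econ, 1000.0, rr, screened=False)
                for rr in (0.5, 1.0, 1.8, 3.0)]
        dx = [t.total_diagnoses for t in runs]
        deaths = [t.total_bc_deaths for t in runs]
        assert all(b > a for a, b in zip(dx, dx[1:]))
        assert all(b > a for a, b in zip(deaths, deaths[1:]))

    def test_stronger_mortality_reduction_averts_more_deaths(self, default_params):
        epi, econ = default_params.epidemiology, default_params.economics
        deaths = []
        for r in (1.0, 0.9, 0.8, 0.7):
            e = replace(epi, bc_mortality_rr_screened=r)
            deaths.append(run_stratum(e, econ, 1000.0, 1.0, screened=True).total_bc_deaths)
        assert all(b < a for a, b in zip(deaths, deaths[1:]))

    def test_adherence_interpolates_between_arms(self, default_params):
        epi, econ = default_params.epidemiology, default_params.economics
        full = run_stratum(epi, econ, 1000.0, 1.0, screened=True, adherence=1.0)
        none = run_stratum(epi, econ, 1000.0, 1.0, screened=False)
        half = run_stratum(epi, econ, 1000.0, 1.0, screened=True, adherence=0.5)
        assert none.total_bc_deaths > half.total_bc_deaths > full.total_bc_deaths
        assert half.total_overdiagnoses == pytest.approx(full.total_overdiagnoses * 0.5,
                                                         rel=1e-9)

    def test_splitting_two_strata_approximates_single_average_stratum(self, default_params):
        """A (30% high-risk, 70% low-risk) split with conservation-respecting
        mean RRs reproduces the rr=1 run.  Exact only in the low-rate linear
        regime; at the packaged rates pool depletion makes diagnosis-linked
        counts agree to ~2%, and at one-fifth the rates to 0.5%."""
        g = group_summary(default_params.risk, 70)
        for scale, tol in ((1.0, 0.02), (0.2, 0.005)):
            ps = apply_overrides(default_params, {"incidence_scale": scale,
                                                  "bc_mortality_scale": scale})
            epi, econ = ps.epidemiology, ps.economics
            single = run_stratum(epi, econ, 10_000.0, 1.0, screened=True)
            hi = run_stratum(epi, econ, 10_000.0 * g.fraction_population_above,
                             g.mean_rr_above, screened=True)
            lo = run_stratum(epi, econ, 10_000.0 * (1 - g.fraction_population_above),
                             g.mean_rr_below, screened=True)
            combined = hi + lo
            for attr in ("total_diagnoses", "total_bc_deaths", "total_person_years",
                         "total_overdiagnoses"):
                assert getattr(combined, attr) == pytest.approx(
                    getattr(single, attr), rel=tol)


class TestOverdiagnoses:
    def test_zero_fraction_gives_zero(self, toy_params):
        epi = replace(toy_params.epidemiology, overdiagnosis_fraction=0.0)
        traj = run_stratum(epi, toy_params.economics, 1000.0, 1.0, screened=True)
        assert overdiagnoses(traj) == 0.0

    def test_window_restricts_to_screening_period(self, toy_params):
        traj = run_toy(toy_params, screened=True)
        full = overdiagnoses(traj, 50, 69)
        assert full == pytest.approx(traj.new_overdiagnoses.sum(), rel=1e-12)
        early = overdiagnoses(traj, 50, 53)
        assert early == pytest.approx(traj.new_overdiagnoses[:3].sum(), rel=1e-12)
        assert early < full

    def test_unscreened_trajectory_is_a_logic_error(self, toy_params):
        traj = run_toy(toy_params, screened=False)
        with pytest.raises(ValueError):
            overdiagnoses(traj)
        with pytest.warns(UserWarning):
            assert overdiagnoses(traj, strict=False) == 0.0

    def test_invalid_window_rejected(self, toy_params):
        traj = run_toy(toy_params, screened=True)
        with pytest.raises(ValueError):
            overdiagnoses(traj, 45, 69)
        with pytest.raises(ValueError):
            overdiagnoses(traj, 60, 60)


class TestQalysAndDiscounting:
    def test_qalys_equal_person_years_when_utilities_one(self, toy_params):
        traj = run_toy(toy_params)
        assert traj.total_qalys == pytest.approx(traj.total_person_years, rel=1e-12)
        # toy discount rate is 0, so discounted QALYs also equal person-years
        assert traj.total_qalys_discounted == pytest.approx(traj.total_person_years,
                                                            rel=1e-12)

    def test_discounted_sum_examples(self):
        assert discounted_sum([100.0, 100.0], 0.035) == pytest.approx(100 + 100 / 1.035)
        assert discounted_sum([1.0, 2.0, 3.0], 0.0) == 6.0
        assert discounted_sum([], 0.035) == 0.0

    def test_discounted_sum_base_year_shift(self):
        assert discounted_sum([0.0, 103.5], 0.035, base_year=1) == pytest.approx(103.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discounted_sum([1.0], -0.01)


def test_rate_arrays_must_cover_all_ages(toy_params):
    from riskstrat.life_table import EpidemiologyParams

    with pytest.raises(ValueError):
        EpidemiologyParams(
            bc_incidence=np.full(20, 0.01),
            bc_mortality_unscreened=np.full(35, 0.005),
            other_cause_mortality=np.full(35, 0.02),
            bc_mortality_rr_screened=0.8,
            overdiagnosis_fraction=0.2,
        )
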