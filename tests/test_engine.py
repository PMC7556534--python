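"""Markov engine: cycle accounting, conservation, discounting, oracle."""
import numpy as np
import pytest

import mapcea as m
from mapcea.engine import DEFAULT_PHASE_IN, phase_in_fraction

from conftest import make_toy_params


class TestPhaseIn:
    @pytest.mark.parametrize("t,f", [(1, 0.0), (2, 0.25), (3, 0.5), (4, 0.75), (5, 1.0), (40, 1.0)])
    def test_schedule(self, t, f):
        assert phase_in_fraction(t, DEFAULT_PHASE_IN) == f

    def test_zero_cycle_rejected(self):
        with pytest.raises(ValueError):
            phase_in_fraction(0)


class TestDiscount:
    def test_end_of_cycle_convention(self):
        assert m.discount(100, 1, 0.03) == pytest.approx(97.0874, abs=1e-4)
        assert m.discount(100, 2, 0.03) == pytest.approx(94.2596, abs=1e-4)

    def test_zero_rate_identity(self):
        assert m.discount(123.45, 17, 0.0) == 123.45


class TestCycleStep:
    def test_uniform_rr_one(self, params):
        p = make_toy_params(params, q=0.001, rrs={s.value: 1.0 for s in m.LIVING_STATES})
        start = m.CohortDistribution([200, 200, 200, 200, 200])
        nxt, deaths = m.cycle_step(start, 40, p)
        assert deaths.sum() == pytest.approx(1000 * 0.001)
        assert np.allclose(nxt.counts / nxt.total, start.counts / start.total)

    def test_hand_arithmetic_with_published_rrs(self, params):
        # deaths = 0.00139 * (122*2.05 + 311*2.51 + 568*2.76) ~ 3.61
        p = make_toy_params(
            params, q=0.00139, rrs={"moderate": 2.05, "severe": 2.51, "extreme": 2.76}
        )
        start = m.CohortDistribution([0, 0, 122, 311, 568])
        _, deaths = m.cycle_step(start, 40, p)
        assert deaths.sum() == pytest.approx(3.6118, abs=1e-3)

    def test_progression_moves_six_percent(self, params):
        p = make_toy_params(params, q=1e-12)
        start = m.CohortDistribution([0, 0, 100, 0, 0])
        scenario = m.Scenario(p_progression=0.06, start_cycle=1)
        nxt, _ = m.cycle_step(start, 40, p, arm="map", scenario=scenario, cycle=1)
        assert nxt["moderate"] == pytest.approx(94, abs=1e-6)
        assert nxt["severe"] == pytest.approx(6, abs=1e-6)

    def test_progression_inactive_before_start_cycle(self, params):
        p = make_toy_params(params, q=1e-12)
        start = m.CohortDistribution([0, 0, 100, 0, 0])
        scenario = m.Scenario(p_progression=0.06, start_cycle=5)
        nxt, _ = m.cycle_step(start, 40, p, arm="map", scenario=scenario, cycle=4)
        assert nxt["moderate"] == pytest.approx(100, abs=1e-6)

    def test_overflowing_hazard_clamped(self, params, caplog):
        p = make_toy_params(params, q=0.9, rrs={"extreme": 2.0})
        start = m.CohortDistribution([0, 0, 0, 0, 10])
        with caplog.at_level("WARNING"):
            nxt, deaths = m.cycle_step(start, 40, p)
        assert deaths.sum() == pytest.approx(10.0)
        assert nxt.total == pytest.approx(0.0)
        assert "clamping" in caplog.text


def spreadsheet_oracle(start, utilities, costs, rrs, q, r, horizon, upfront=0.0, half=True):
    """Independent plain-Python ledger: per-state deaths, person-years,
    costs and QALYs, end-of-cycle discounting. Survivors keep their
    state; costs are priced at actual states (control-arm convention)."""
    occ = [float(x) for x in start]
    rows = []
    cum_cost, cum_q, cum_d = upfront, 0.0, 0.0
    for t in range(1, horizon + 1):
        deaths = [o * min(1.0, q * rr) for o, rr in zip(occ, rrs)]
        py = [o - (0.5 if half else 1.0) * d for o, d in zip(occ, deaths)]
        cost = sum(p * c for p, c in zip(py, costs))
        qaly = sum(p * u for p, u in zip(py, utilities))
        disc = (1 + r) ** -t
        cum_cost += cost * disc
        cum_q += qaly * disc
        cum_d += sum(deaths)
        rows.append((cum_cost, cum_q, cum_d))
        occ = [o - d for o, d in zip(occ, deaths)]
    return rows


class TestRunCohort:
    def test_two_state_toy_matches_spreadsheet_oracle(self, params):
        utilities = {"asymptomatic": 1.0, "severe": 0.5}
        costs = {"asymptomatic": 0.0, "severe": 100.0}
        rrs = {"severe": 2.0}
        p = make_toy_params(params, q=0.01, utilities=utilities, costs=costs, rrs=rrs, r=0.0)
        start = m.CohortDistribution([600, 0, 0, 400, 0])
        traj = m.run_cohort(p, "control", horizon=3, start=start)
        u = p.utilities()
        c = p.annual_costs()
        rr = p.mortality_rrs()
        expected = spreadsheet_oracle(start.counts, u, c, rr, q=0.01, r=0.0, horizon=3)
        for t, (cost, q_, d) in enumerate(expected, start=1):
            assert traj.cumulative_discounted_cost(t) == pytest.approx(cost, abs=1e-9)
            assert traj.cumulative_discounted_qalys(t) == pytest.approx(q_, abs=1e-9)
            assert traj.cumulative_deaths(t) == pytest.approx(d, abs=1e-9)

    def test_oracle_with_discounting_and_zero_credit(self, params):
        p = make_toy_params(
            params, q=0.02, rrs={"severe": 1.5}, r=0.05, half_cycle_credit=False
        )
        start = m.CohortDistribution([100, 50, 25, 12, 6])
        traj = m.run_cohort(p, "control", horizon=5, start=start)
        expected = spreadsheet_oracle(
            start.counts, p.utilities(), p.annual_costs(), p.mortality_rrs(),
            q=0.02, r=0.05, horizon=5, half=False,
        )
        assert traj.cumulative_discounted_cost(5) == pytest.approx(expected[-1][0], abs=1e-9)
        assert traj.cumulative_discounted_qalys(5) == pytest.approx(expected[-1][1], abs=1e-9)

    def test_person_conservation_each_cycle(self, base_run):
        _, traj_map, traj_control = base_run
        for traj in (traj_map, traj_control):
            for prev, cur in zip(traj.cycles, traj.cycles[1:]):
                assert cur.occupancy.total + prev.deaths == pytest.approx(
                    prev.occupancy.total, abs=1e-9
                )

    def test_qaly_conservation_without_mortality_or_discounting(self, params):
        p = make_toy_params(
            params, q=1e-15, utilities={s.value: 1.0 for s in m.LIVING_STATES}, r=0.0
        )
        traj = m.run_cohort(p, "control", horizon=7)
        assert traj.cumulative_discounted_qalys(7) == pytest.approx(7 * 1000, abs=1e-6)

    def test_everyone_dies_eventually(self, params):
        # long-horizon absorption into death on a synthetic schedule
        import dataclasses

        table = m.synthetic_gompertz_table(q_ref=0.00139, ref_age=40, slope=0.085, max_age=110)
        p = dataclasses.replace(params, life_table=table)
        traj = m.run_cohort(p, "control", horizon=200)
        assert traj.cumulative_deaths(200) == pytest.approx(1000, abs=1.0)

    def test_discounted_totals_monotone_in_rate(self, params):
        totals = []
        for r in (0.0, 0.01, 0.03, 0.08, 0.15):
            p = params.with_overrides({"discount_rate": r})
            traj = m.run_cohort(p, "control", horizon=30)
            totals.append(
                (traj.cumulative_discounted_cost(30), traj.cumulative_discounted_qalys(30))
            )
        costs, qalys = zip(*totals)
        assert np.all(np.diff(costs) < 0)
        assert np.all(np.diff(qalys) < 0)

    def test_base_case_patients_never_change_severity(self, base_run):
        """No transitions between living states: each state's occupancy
        declines exactly by its own deaths (survivors stay put)."""
        _, traj_map, traj_control = base_run
        for traj in (traj_map, traj_control):
            for prev, cur in zip(traj.cycles, traj.cycles[1:]):
                np.testing.assert_allclose(
                    cur.occupancy.counts,
                    prev.occupancy.counts - prev.deaths_by_state,
                    atol=1e-12,
                )

    def test_map_arm_gains_qalys_under_dominating_followup(self, base_run):
        _, traj_map, traj_control = base_run
        for h in (1, 5, 10, 30):
            assert traj_map.cumulative_discounted_qalys(h) > traj_control.cumulative_discounted_qalys(h)

    def test_map_year_one_cost_priced_at_intake_mix(self, params):
        """With zero phase-in the treated arm's year-1 medical bill uses
        the pre-treatment cost mix (only survivorship differs)."""
        traj_map = m.run_cohort(params, "map", horizon=1)
        traj_control = m.run_cohort(params, "control", horizon=1)
        map_medical = traj_map.cumulative_discounted_cost(1) - traj_map.upfront_cost
        ctrl_medical = traj_control.cumulative_discounted_cost(1)
        # more treated survivors -> slightly larger bill at the same mix
        assert map_medical > ctrl_medical
        assert map_medical == pytest.approx(ctrl_medical, rel=2e-3)

    def test_invalid_arm_rejected(self, params):
        with pytest.raises(ValueError, match="arm"):
            m.run_cohort(params, "placebo", horizon=1)

    def test_trajectory_export_columns(self, base_run):
        _, traj_map, traj_control = base_run
        df = m.engine.trajectories_to_frame(traj_map, traj_control)
        assert set(df["arm"]) == {"map", "control"}
        assert len(df) == 60
        for col in ("cycle", "deaths", "medical_cost_disc", "qalys_disc", "cum_cost_disc"):
            assert col in df.columns
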