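"""Cohort engine: initialization, stepping, accumulation, arm comparison."""

import numpy as np
import pytest

from ohcm.mortality import LifeTable
from ohcm.parameters import (
    DAYS_PER_YEAR,
    NYHA,
    ByClass,
    CycleSchedule,
    annual_prob_to_cycle,
    apply_param,
    default_params,
)
from ohcm.pathway_engine import (
    CohortState,
    CohortTrace,
    Line,
    accumulate,
    build_context,
    compare_arms,
    initialize,
    run_trace,
    step,
)


from helpers import identity_schedule, inert_params


class TestInitialize:
    def test_baseline_distribution_per_arm(self, params):
        t = initialize(params, "treatment")
        c = initialize(params, "control")
        assert t.occupancy[Line.MAVACAMTEN, NYHA.II] == 0.7654
        assert t.occupancy[Line.MAVACAMTEN, NYHA.III] == 0.2346
        assert c.occupancy[Line.BBCCB, NYHA.II] == 0.7654
        assert c.occupancy[Line.BBCCB, NYHA.III] == 0.2346
        for st in (t, c):
            assert st.occupancy.sum() + st.dead == pytest.approx(1.0, abs=1e-15)


class TestStep:
    def test_fixed_point_with_inert_dynamics(self, zero_life_table):
        p = inert_params()
        ctx = build_context(
            p, "treatment", life_table=zero_life_table, treatment_matrices=identity_schedule()
        )
        state = initialize(p, "treatment")
        for k in range(15):  # spans trial, week-30 boundary, maintenance
            nxt = step(state, k, ctx)
            np.testing.assert_allclose(nxt.occupancy, state.occupancy, atol=1e-15)
            assert nxt.dead == 0.0
            state = nxt

    def test_srt_tunnel_single_cycle_surgical_effect(self, zero_life_table):
        p = inert_params()
        ctx = build_context(p, "treatment", life_table=zero_life_table)
        k = ctx.final_trial_cycle + 2  # a post-trial cycle
        occ = np.zeros((4, 4))
        occ[Line.SRT_TUNNEL, NYHA.III] = 1.0
        state = CohortState(occupancy=occ, dead=0.0, t_days=ctx.schedule.start_days[k])
        nxt = step(state, k, ctx)
        assert nxt.occupancy[Line.POST_SRT, NYHA.II] == pytest.approx(0.3871)
        assert nxt.occupancy[Line.POST_SRT, NYHA.III] == pytest.approx(0.6129)
        assert nxt.occupancy[Line.SRT_TUNNEL].sum() == 0.0  # tunnel is one cycle only

    def test_maintenance_phase_no_worsening_means_no_discontinuation(self, zero_life_table):
        # week 30-106 matrix has no II→III entry, so the worsening flow is zero
        p = inert_params()
        ctx = build_context(p, "treatment", life_table=zero_life_table)
        k = ctx.final_trial_cycle + 1
        occ = np.zeros((4, 4))
        occ[Line.MAVACAMTEN, NYHA.II] = 1.0
        state = CohortState(occupancy=occ, dead=0.0, t_days=ctx.schedule.start_days[k])
        nxt = step(state, k, ctx)
        assert nxt.occupancy[Line.BBCCB].sum() == 0.0
        assert nxt.occupancy[Line.MAVACAMTEN].sum() == pytest.approx(1.0)

    def test_week30_nonresponders_switch_to_bbccb(self, zero_life_table):
        p = inert_params(
            week30_nonresponse_discontinuation={"I": 0.0, "II": 0.0, "III": 1.0, "IV": 1.0}
        )
        ctx = build_context(p, "treatment", life_table=zero_life_table)
        state = initialize(p, "treatment")
        for k in range(ctx.final_trial_cycle + 1):
            state = step(state, k, ctx)
        # everyone still in NYHA III at week 30 has moved off the drug
        assert state.occupancy[Line.MAVACAMTEN, NYHA.III] == 0.0
        assert state.occupancy[Line.BBCCB, NYHA.III] > 0.0

    def test_sae_flow_rate(self, zero_life_table):
        p = inert_params(sae_discontinuation_annual=0.05)
        ctx = build_context(p, "treatment", life_table=zero_life_table)
        k = ctx.final_trial_cycle + 1
        occ = np.zeros((4, 4))
        occ[Line.MAVACAMTEN, NYHA.I] = 1.0  # NYHA I cannot worsen under maintenance
        state = CohortState(occupancy=occ, dead=0.0, t_days=ctx.schedule.start_days[k])
        nxt = step(state, k, ctx)
        expected = annual_prob_to_cycle(0.05, p.cycle_days)
        assert nxt.occupancy[Line.BBCCB, NYHA.I] == pytest.approx(expected, abs=1e-12)


class TestRunTrace:
    def test_single_cycle_horizon(self, zero_life_table):
        p = inert_params()
        p = apply_param(p, "horizon_age", p.start_age + 28 / DAYS_PER_YEAR)
        trace = run_trace(p, "control", life_table=zero_life_table)
        assert len(trace.states) == 2

    def test_certain_death_empties_cohort(self):
        lethal = LifeTable(age_min=0, qx_male=np.ones(101), qx_female=np.ones(101))
        trace = run_trace(default_params(), "control", life_table=lethal)
        assert trace.states[1].dead == pytest.approx(1.0, abs=1e-12)
        assert trace.n_cycles_run == 1  # early stop once everyone is dead

    def test_mass_conservation_and_monotone_dead(self, params, life_table):
        for arm in ("treatment", "control"):
            trace = run_trace(params, arm, life_table=life_table)
            dead_prev = 0.0
            for st in trace.states:
                assert abs(st.occupancy.sum() + st.dead - 1.0) < 1e-10
                assert (st.occupancy >= -1e-10).all()
                assert st.dead >= dead_prev - 1e-15
                dead_prev = st.dead

    def test_control_arm_cannot_improve_after_week_30(self, params, life_table):
        # without SRT escalation (the only route to improvement), NYHA class
        # can only stay or worsen once the trial phase ends
        p = params.model_copy(
            update={
                "srt_switch_annual": ByClass(I=0.0, II=0.0, III=0.0, IV=0.0),
            }
        )
        trace = run_trace(p, "control", life_table=life_table)
        k30 = trace.schedule.n_trial_cycles
        # cumulative best-achievable aggregate: mass at or better than class c
        # can only shrink when no improving transitions exist
        prev = None
        for st in trace.states[k30:]:
            alive = st.alive
            if alive < 1e-12:
                break
            cum = np.cumsum(st.by_class())  # mass in classes <= c
            if prev is not None:
                assert (cum <= prev + 1e-10).all()
            prev = cum


class TestAccumulate:
    def _flat_trace(self, starts, ends, nyha_class, arm="treatment"):
        sched = CycleSchedule(tuple(starts), tuple(ends), tuple(["long_term"] * len(starts)))
        states = []
        for t in list(starts) + [ends[-1]]:
            occ = np.zeros((4, 4))
            occ[Line.MAVACAMTEN, nyha_class] = 1.0
            states.append(CohortState(occupancy=occ, dead=0.0, t_days=t))
        return CohortTrace(states=states, schedule=sched, arm=arm)

    def test_one_year_in_nyha_i(self, params):
        trace = self._flat_trace([0.0, DAYS_PER_YEAR / 2], [DAYS_PER_YEAR / 2, DAYS_PER_YEAR], NYHA.I)
        p = apply_param(params, "discount_rate_annual", 0.0)
        out = accumulate(trace, p)
        assert out.ly == pytest.approx(1.0, abs=1e-12)
        assert out.qaly == pytest.approx(0.905, abs=1e-12)

    def test_discount_applied_at_cycle_start(self, params):
        # a single cycle starting at t=0 is undiscounted regardless of r
        trace = self._flat_trace([0.0], [DAYS_PER_YEAR], NYHA.I)
        out = accumulate(trace, params)  # r = 0.05
        assert out.ly == pytest.approx(1.0, abs=1e-12)

    def test_empty_trace_gives_zeros(self, params):
        sched = CycleSchedule((0.0,), (28.0,), ("long_term",))
        occ = np.zeros((4, 4))
        occ[Line.MAVACAMTEN, NYHA.II] = 1.0
        trace = CohortTrace(
            states=[CohortState(occupancy=occ, dead=0.0, t_days=0.0)],
            schedule=sched,
            arm="treatment",
        )
        out = accumulate(trace, params)
        assert out.ly == 0.0 and out.qaly == 0.0

    def test_by_class_sums_to_totals(self, params, life_table):
        trace = run_trace(params, "treatment", life_table=life_table)
        out = accumulate(trace, params)
        assert out.ly_by_class.sum() == pytest.approx(out.ly, abs=1e-9)
        assert out.qaly_by_class.sum() == pytest.approx(out.qaly, abs=1e-9)
        assert out.qaly <= out.ly * params.utilities.as_array().max() + 1e-12

    def test_half_cycle_correction_reduces_ly_under_mortality(self, life_table):
        p = inert_params()
        base = accumulate(run_trace(p, "control", life_table=life_table), p)
        phc = inert_params(half_cycle_correction=True)
        hc = accumulate(run_trace(phc, "control", life_table=life_table), phc)
        assert hc.ly < base.ly


class TestAnalyticLimit:
    def test_cohort_ly_equals_life_table_expectancy(self, life_table):
        """Identity transitions, HR 1, no switching, r = 0: the cohort engine
        must reproduce the discrete life expectancy computed directly from the
        life table over the same cycle grid."""
        p = inert_params(mortality_hr={"I": 1.0, "II": 1.0, "III": 1.0, "IV": 1.0})
        trace = run_trace(
            p, "treatment", life_table=life_table, treatment_matrices=identity_schedule()
        )
        out = accumulate(trace, p)

        # independent survivorship summation over the cycle schedule
        sched = CycleSchedule.build(p)
        surv, ly = 1.0, 0.0
        for s, e in zip(sched.start_days, sched.end_days):
            age = min(int(np.floor(p.start_age + s / DAYS_PER_YEAR)), life_table.age_max)
            q = p.male_fraction * life_table.qx(age, "male") + (
                1 - p.male_fraction
            ) * life_table.qx(age, "female")
            dt = (e - s) / DAYS_PER_YEAR
            ly += surv * dt
            surv *= (1 - q) ** dt
            if surv < 1e-9:
                break
        assert abs(out.ly - ly) < 1e-9


class TestCompareArms:
    def test_identical_dynamics_give_zero_increments(self, zero_life_table):
        p = inert_params()
        out = compare_arms(
            p,
            life_table=zero_life_table,
            treatment_matrices=identity_schedule("treatment"),
            control_matrices=identity_schedule("control"),
        )
        assert out.incremental_ly == pytest.approx(0.0, abs=1e-12)
        assert out.incremental_qaly == pytest.approx(0.0, abs=1e-12)

    def test_default_increments_positive(self, params, life_table):
        out = compare_arms(params, life_table=life_table)
        assert out.incremental_ly > 0
        assert out.incremental_qaly > 0

    def test_monotone_in_utility_and_hazard(self, params, life_table):
        base = compare_arms(params, life_table=life_table)
        up = compare_arms(apply_param(params, "utilities.III", 0.75), life_table=life_table)
        assert up.treatment.qaly >= base.treatment.qaly
        assert up.control.qaly >= base.control.qaly
        worse = compare_arms(apply_param(params, "mortality_hr.IV", 14.35), life_table=life_table)
        assert worse.treatment.ly <= base.treatment.ly
        assert worse.control.ly <= base.control.ly

    def test_discounting_strictly_reduces_totals(self, params, life_table):
        undisc = compare_arms(apply_param(params, "discount_rate_annual", 0.0), life_table=life_table)
        disc = compare_arms(params, life_table=life_table)
        assert disc.treatment.ly < undisc.treatment.ly
        assert disc.treatment.qaly < undisc.treatment.qaly

    def test_outcome_frame_layout(self, params, life_table):
        df = compare_arms(params, life_table=life_table).to_frame()
        assert list(df.columns) == ["Overall", "NYHA I", "NYHA II", "NYHA III", "NYHA IV"]
        assert len(df) == 6
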