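"""Cohort trace over the expanded (treatment line × NYHA) state space.

The living state space is the product of a treatment line — active drug
(mavacamten ± BB/CCB), BB/CCB monotherapy, the one-cycle SRT surgical
tunnel, and post-SRT — with the four NYHA classes, plus an absorbing dead
state. Each cycle applies, in order:

1. death (life-table background hazard × NYHA hazard ratio; the tunnel adds
   the independent peri-operative risk),
2. NYHA transitions of survivors via the line- and time-appropriate matrix,
3. switching flows that set next-cycle lines: tunnel → post-SRT; BB/CCB
   (and, optionally, post-SRT) → tunnel at the per-cycle SRT escalation
   probability of the *post-transition* class; active drug → BB/CCB for the
   serious-adverse-event flow, for the sub-mass whose NYHA class worsened
   this cycle, and — at the week-30 boundary only — for the trial
   non-responder proportions.

During the first 30 weeks all patients remain on their initial line.
Life-years and QALYs accrue from start-of-cycle occupancy over the full
cycle (no half-cycle correction by default), discounted at the cycle-start
time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .mortality import LifeTable, cycle_death_prob, srt_cycle_death_prob, weighted_annual_qx
from .nyha_transitions import (
    MatrixScheduleEntry,
    MatrixSet,
    TransitionMatrix,
    assert_no_flagged_mass,
    matrix_for,
)
from .parameters import DAYS_PER_YEAR, NYHA, CycleSchedule, ModelParams

MASS_TOL = 1e-10
ALIVE_EPS = 1e-9


class Line(enum.IntEnum):
    """Treatment lines of the escalation pathway."""

    MAVACAMTEN = 0
    BBCCB = 1
    SRT_TUNNEL = 2
    POST_SRT = 3


N_LINES = len(Line)


@dataclass
class CohortState:
    """Occupancy mass over (line × NYHA) plus the dead state, at a time point."""

    occupancy: np.ndarray  # (N_LINES, 4)
    dead: float
    t_days: float

    def validate(self) -> None:
        if (self.occupancy < -MASS_TOL).any() or self.dead < -MASS_TOL:
            raise RuntimeError("negative occupancy mass")
        total = self.occupancy.sum() + self.dead
        if abs(total - 1.0) > MASS_TOL:
            raise RuntimeError(f"mass leak: total occupancy {total}")

    @property
    def alive(self) -> float:
        return float(self.occupancy.sum())

    def by_class(self) -> np.ndarray:
        """Alive occupancy aggregated over lines, per NYHA class."""
        return self.occupancy.sum(axis=0)


@dataclass
class CohortTrace:
    """CohortStates at every cycle boundary, plus the schedule that drove them."""

    states: list[CohortState]
    schedule: CycleSchedule
    arm: str

    @property
    def n_cycles_run(self) -> int:
        return len(self.states) - 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, st in enumerate(self.states):
            for line in Line:
                for c in NYHA:
                    rows.append(
                        {
                            "cycle": k,
                            "t_days": st.t_days,
                            "line": line.name.lower(),
                            "nyha": c.name,
                            "mass": st.occupancy[line, c],
                        }
                    )
            rows.append(
                {"cycle": k, "t_days": st.t_days, "line": "dead", "nyha": "", "mass": st.dead}
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EngineContext:
    """Per-cycle quantities precomputed once per trace.

    Shared verbatim with the patient-level microsimulation oracle so that
    both engines draw from identical per-cycle probabilities.
    """

    params: ModelParams
    arm: str
    schedule: CycleSchedule
    mats: MatrixSet
    p_death: np.ndarray       # (n_cycles, 4) background × HR, by NYHA class
    p_death_tunnel: np.ndarray  # (n_cycles, 4) with peri-operative excess folded in
    p_srt: np.ndarray         # (n_cycles, 4) BB/CCB→SRT per-cycle switch prob
    p_sae: np.ndarray         # (n_cycles,) active-drug SAE discontinuation prob
    matrices: list            # per cycle: list of TransitionMatrix|None per line
    dt_years: np.ndarray
    discount: np.ndarray      # factor at cycle start
    w30: np.ndarray           # week-30 non-response discontinuation, by class
    final_trial_cycle: int


def build_context(
    params: ModelParams,
    arm: str,
    life_table: LifeTable | None = None,
    control_matrices: Sequence[MatrixScheduleEntry] | None = None,
    treatment_matrices: Sequence[MatrixScheduleEntry] | None = None,
    srt_matrix: TransitionMatrix | None = None,
) -> EngineContext:
    if life_table is None:
        life_table = _default_life_table()
    schedule = CycleSchedule.build(params)
    mats = MatrixSet.build(
        arm,
        params,
        control_matrices=control_matrices,
        treatment_matrices=treatment_matrices,
        srt_matrix=srt_matrix,
    )
    n = len(schedule)
    hr = params.mortality_hr.as_array()
    starts = np.asarray(schedule.start_days)
    dts = np.asarray(schedule.lengths_days())
    p_death = np.empty((n, 4))
    p_death_tunnel = np.empty((n, 4))
    p_srt = np.empty((n, 4))
    p_sae = np.empty(n)
    matrices: list[list[TransitionMatrix | None]] = []
    srt_annual = params.srt_switch_annual.as_array()
    sae_annual = params.sae_discontinuation_annual
    final_trial = max(k for k in range(n) if schedule.phases[k] == "trial")
    for k in range(n):
        age = int(math.floor(params.start_age + starts[k] / DAYS_PER_YEAR))
        age = min(age, life_table.age_max)
        q = weighted_annual_qx(life_table, age, params.male_fraction)
        for c in range(4):
            p_death[k, c] = cycle_death_prob(q, hr[c], dts[k])
            p_death_tunnel[k, c] = srt_cycle_death_prob(
                p_death[k, c], params.srt_perioperative_mortality
            )
        trial = schedule.phases[k] == "trial"
        if trial:
            p_srt[k] = 0.0
            p_sae[k] = 0.0
        else:
            frac = dts[k] / DAYS_PER_YEAR
            p_srt[k] = 1.0 - (1.0 - srt_annual) ** frac
            p_sae[k] = 1.0 - (1.0 - sae_annual) ** frac
        per_line: list[TransitionMatrix | None] = [None] * N_LINES
        for line in Line:
            if line is Line.MAVACAMTEN and arm != "treatment":
                continue
            if line is Line.BBCCB and arm == "treatment" and trial:
                continue  # unreachable before week 30 in the treatment arm
            per_line[line] = matrix_for(mats, int(line), starts[k])
        matrices.append(per_line)
    return EngineContext(
        params=params,
        arm=arm,
        schedule=schedule,
        mats=mats,
        p_death=p_death,
        p_death_tunnel=p_death_tunnel,
        p_srt=p_srt,
        p_sae=p_sae,
        matrices=matrices,
        dt_years=dts / DAYS_PER_YEAR,
        discount=(1.0 + params.discount_rate_annual) ** (-starts / DAYS_PER_YEAR),
        w30=params.week30_nonresponse_discontinuation.as_array(),
        final_trial_cycle=final_trial,
    )


@lru_cache(maxsize=1)
def _default_life_table() -> LifeTable:
    from .synthetic_data import synthetic_life_table

    return synthetic_life_table()


def initialize(params: ModelParams, arm: str) -> CohortState:
    """Baseline cohort: the trial's NYHA II/III split, all on the initial line."""
    occ = np.zeros((N_LINES, 4))
    line = Line.MAVACAMTEN if arm == "treatment" else Line.BBCCB
    occ[line] = params.baseline_nyha.as_array()
    state = CohortState(occupancy=occ, dead=0.0, t_days=0.0)
    state.validate()
    return state


def step(state: CohortState, k: int, ctx: EngineContext) -> CohortState:
    """Advance one cycle: death → NYHA transition → switching flows."""
    params = ctx.params
    trial = ctx.schedule.phases[k] == "trial"
    O = state.occupancy

    # 1. death
    deaths = O * ctx.p_death[k][None, :]
    deaths[Line.SRT_TUNNEL] = O[Line.SRT_TUNNEL] * ctx.p_death_tunnel[k]
    S = O - deaths
    dead = state.dead + deaths.sum()

    # 2. NYHA transitions of survivors (flow matrices, from-class × to-class)
    flows = np.zeros((N_LINES, 4, 4))
    for line in Line:
        if S[line].sum() <= 0.0:
            continue
        M = ctx.matrices[k][line]
        if M is None:
            raise RuntimeError(f"mass present on line {line.name} with no matrix at cycle {k}")
        if trial:
            assert_no_flagged_mass(M, S[line], tol=MASS_TOL)
        flows[line] = S[line][:, None] * M.probs

    # 3. switching flows decide next-cycle lines
    new = np.zeros((N_LINES, 4))
    arrived = flows.sum(axis=1)  # (line, to-class)

    # tunnel is occupiable for exactly one cycle
    new[Line.POST_SRT] += arrived[Line.SRT_TUNNEL]

    mav = arrived[Line.MAVACAMTEN]
    if trial:
        if k == ctx.final_trial_cycle:
            # week-30 boundary: trial non-responders stop the active drug
            leave = mav * ctx.w30
            new[Line.BBCCB] += leave
            new[Line.MAVACAMTEN] += mav - leave
        else:
            new[Line.MAVACAMTEN] += mav
        new[Line.BBCCB] += arrived[Line.BBCCB]
        new[Line.POST_SRT] += arrived[Line.POST_SRT]
    else:
        # active drug: worsened sub-mass discontinues; remainder faces SAE risk
        f = flows[Line.MAVACAMTEN]
        worsened = np.triu(f, k=1).sum(axis=0)  # to-class mass that worsened
        not_worsened = f.sum(axis=0) - worsened
        sae = not_worsened * ctx.p_sae[k]
        new[Line.BBCCB] += worsened + sae
        new[Line.MAVACAMTEN] += not_worsened - sae

        # BB/CCB (and post-SRT, if repeat surgery allowed) escalate to SRT
        to_srt = arrived[Line.BBCCB] * ctx.p_srt[k]
        new[Line.SRT_TUNNEL] += to_srt
        new[Line.BBCCB] += arrived[Line.BBCCB] - to_srt
        if params.repeat_srt_allowed:
            ps_to_srt = arrived[Line.POST_SRT] * ctx.p_srt[k]
            new[Line.SRT_TUNNEL] += ps_to_srt
            new[Line.POST_SRT] += arrived[Line.POST_SRT] - ps_to_srt
        else:
            new[Line.POST_SRT] += arrived[Line.POST_SRT]

    nxt = CohortState(occupancy=new, dead=dead, t_days=ctx.schedule.end_days[k])
    nxt.validate()
    return nxt


def run_trace(
    params: ModelParams,
    arm: str,
    life_table: LifeTable | None = None,
    control_matrices: Sequence[MatrixScheduleEntry] | None = None,
    treatment_matrices: Sequence[MatrixScheduleEntry] | None = None,
    srt_matrix: TransitionMatrix | None = None,
    context: EngineContext | None = None,
) -> CohortTrace:
    """Run the cohort from baseline to the horizon (or cohort extinction)."""
    ctx = context or build_context(
        params,
        arm,
        life_table=life_table,
        control_matrices=control_matrices,
        treatment_matrices=treatment_matrices,
        srt_matrix=srt_matrix,
    )
    state = initialize(params, arm)
    states = [state]
    for k in range(len(ctx.schedule)):
        if state.alive < ALIVE_EPS:
            break
        state = step(state, k, ctx)
        states.append(state)
    return CohortTrace(states=states, schedule=ctx.schedule, arm=arm)


@dataclass(frozen=True)
class ArmOutcomes:
    """Accumulated (quality-adjusted) life-years for one arm."""

    ly: float
    qaly: float
    ly_by_class: np.ndarray
    qaly_by_class: np.ndarray
    ly_undiscounted: float
    qaly_undiscounted: float


def accumulate(trace: CohortTrace, params: ModelParams) -> ArmOutcomes:
    """Integrate person-time (utility-weighted and not) over the trace.

    Start-of-cycle occupancy accrues the full cycle, discounted at the
    cycle-start time; person-time is attributed to the NYHA class occupied
    during the cycle. With ``half_cycle_correction`` the mean of start- and
    end-of-cycle occupancy accrues instead.
    """
    util = params.utilities.as_array()
    r = params.discount_rate_annual
    ly_c = np.zeros(4)
    qaly_c = np.zeros(4)
    ly_u = qaly_u = 0.0
    for k in range(trace.n_cycles_run):
        st = trace.states[k]
        occ = st.by_class()
        if params.half_cycle_correction:
            occ = 0.5 * (occ + trace.states[k + 1].by_class())
        dt = (trace.schedule.end_days[k] - trace.schedule.start_days[k]) / DAYS_PER_YEAR
        disc = (1.0 + r) ** (-trace.schedule.start_days[k] / DAYS_PER_YEAR)
        ly_c += occ * dt * disc
        qaly_c += occ * util * dt * disc
        ly_u += occ.sum() * dt
        qaly_u += (occ * util).sum() * dt
    return ArmOutcomes(
        ly=float(ly_c.sum()),
        qaly=float(qaly_c.sum()),
        ly_by_class=ly_c,
        qaly_by_class=qaly_c,
        ly_undiscounted=float(ly_u),
        qaly_undiscounted=float(qaly_u),
    )


@dataclass(frozen=True)
class OutcomeTable:
    """Per-arm and incremental LY/QALY results."""

    treatment: ArmOutcomes
    control: ArmOutcomes

    @property
    def incremental_ly(self) -> float:
        return self.treatment.ly - self.control.ly

    @property
    def incremental_qaly(self) -> float:
        return self.treatment.qaly - self.control.qaly

    def to_frame(self) -> pd.DataFrame:
        cols = ["Overall", "NYHA I", "NYHA II", "NYHA III", "NYHA IV"]
        rows = {}
        for metric in ("ly", "qaly"):
            t = getattr(self.treatment, metric)
            c = getattr(self.control, metric)
            tb = getattr(self.treatment, f"{metric}_by_class")
            cb = getattr(self.control, f"{metric}_by_class")
            label = metric.upper() + "s"
            rows[(label, "Treatment group")] = [t, *tb]
            rows[(label, "Control group")] = [c, *cb]
            rows[(label, "Difference")] = [t - c, *(tb - cb)]
        df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        df.index = pd.MultiIndex.from_tuples(df.index, names=["metric", "arm"])
        return df


def compare_arms(
    params: ModelParams,
    life_table: LifeTable | None = None,
    control_matrices: Sequence[MatrixScheduleEntry] | None = None,
    treatment_matrices: Sequence[MatrixScheduleEntry] | None = None,
    srt_matrix: TransitionMatrix | None = None,
) -> OutcomeTable:
    """Run both arms on identical schedule and mortality inputs."""
    if life_table is None:
        life_table = _default_life_table()
    out = {}
    for arm in ("treatment", "control"):
        trace = run_trace(
            params,
            arm,
            life_table=life_table,
            control_matrices=control_matrices,
            treatment_matrices=treatment_matrices,
            srt_matrix=srt_matrix,
        )
        out[arm] = accumulate(trace, params)
    return OutcomeTable(treatment=out["treatment"], control=out["control"])
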