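"""Synthetic stand-ins for unpublished inputs, plus the microsimulation oracle.

Two of the model's inputs were never published and are generated here as
clearly-labelled synthetic placeholders:

* a **Gompertz–Makeham life table** emulating a modern Chinese national life
  table (calibrated so that life expectancy at birth is ≈80 years for women
  and ≈75 for men);
* **control-arm trial-phase matrices**, structured after the trial
  observation that the placebo + BB/CCB group could not sustain the NYHA
  improvements seen before week 18: modest improvement entries before the
  plateau week, stay/worsen-only rows after it.

The module also provides a **patient-level microsimulation oracle** that
implements the treatment-pathway rules literally, with per-patient memory
(previous NYHA class, one-cycle surgical tunnel, week-30 boundary), for
validating the cohort engine's flow-level bookkeeping, and a generator of
random-but-valid parameter sets for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mortality import LifeTable
from .nyha_transitions import MatrixScheduleEntry, TransitionMatrix
from .parameters import (
    TRIAL_WEEKS,
    ByClass,
    ModelParams,
    annual_prob_to_cycle,
)


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard h(age) = makeham + gompertz_scale · sex_hr · exp(shape · age).

    Units: hazards per year; ``sex_hazard_ratio`` multiplies the Gompertz
    (senescent) term for males. Defaults are calibrated so the implied life
    expectancy at birth is ≈80 years (female) and ≈75 years (male).
    """

    makeham: float = 8.0e-4
    gompertz_scale: float = 2.1336e-5
    gompertz_shape: float = 0.095
    sex_hazard_ratio: float = 1.681
    max_age: int = 100

    def __post_init__(self) -> None:
        if min(self.makeham, self.gompertz_scale, self.gompertz_shape, self.sex_hazard_ratio) <= 0:
            raise ValueError("all hazard parameters must be > 0")


def synthetic_life_table(gm: GompertzMakehamParams | None = None) -> LifeTable:
    """Generate a synthetic two-sex life table on ages 0..max_age.

    ``qx = 1 − exp(−h(age))`` capped at 1, with the terminal age forced to
    ``qx = 1`` so the table closes out.
    """
    gm = gm or GompertzMakehamParams()
    ages = np.arange(0, gm.max_age + 1)
    cols = {}
    for sex, hr in (("female", 1.0), ("male", gm.sex_hazard_ratio)):
        hazard = gm.makeham + gm.gompertz_scale * hr * np.exp(gm.gompertz_shape * ages)
        qx = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
        qx[-1] = 1.0
        cols[sex] = qx
    return LifeTable(age_min=0, qx_male=cols["male"], qx_female=cols["female"])


def synthetic_control_matrices(
    seed: int = 0, plateau_week: int = 18
) -> list[MatrixScheduleEntry]:
    """Placeholder control-arm matrices for the ten trial intervals.

    SYNTHETIC: the true control-arm short-term matrices were never
    published. Intervals ending at or before ``plateau_week`` allow modest
    NYHA improvement; later intervals are stay/worsen only. All four rows
    are observed (NYHA I near-stay, NYHA IV absorbing), rows are exactly
    row-stochastic, and output is deterministic for a fixed seed.
    """
    if not 0 < plateau_week <= 30:
        raise ValueError("plateau_week must lie in (0, 30]")
    rng = np.random.default_rng(seed)
    entries = []
    for w0, w1 in zip(TRIAL_WEEKS[:-1], TRIAL_WEEKS[1:]):
        improving = w1 <= plateau_week
        p_imp = rng.uniform(0.03, 0.10, size=2) if improving else np.zeros(2)
        p_wor = rng.uniform(0.0, 0.03, size=3)
        rows = [
            [1.0 - p_wor[0], p_wor[0], 0.0, 0.0],
            [p_imp[0], 1.0 - p_imp[0] - p_wor[1], p_wor[1], 0.0],
            [0.0, p_imp[1], 1.0 - p_imp[1] - p_wor[2], p_wor[2]],
            [0.0, 0.0, 0.0, 1.0],
        ]
        entries.append(
            MatrixScheduleEntry(w0, w1, "control", TransitionMatrix.from_rows(rows))
        )
    return entries


def random_params(seed: int) -> ModelParams:
    """A random but invariant-respecting parameter set for property tests."""
    rng = np.random.default_rng(seed)
    start_age = float(rng.uniform(35, 55))
    horizon = float(min(100.0, start_age + rng.uniform(20, 50)))
    b2 = float(rng.uniform(0.3, 0.9))
    utils = np.sort(rng.uniform(0.3, 1.0, size=3))[::-1]
    hrs = np.sort(rng.uniform(1.0, 15.0, size=3))
    progression_annual = float(rng.uniform(0.0, 0.2))
    return ModelParams(
        start_age=start_age,
        male_fraction=float(rng.uniform(0.0, 1.0)),
        baseline_nyha=ByClass(I=0.0, II=b2, III=1.0 - b2, IV=0.0),
        discount_rate_annual=float(rng.uniform(0.0, 0.08)),
        sae_discontinuation_annual=float(rng.uniform(0.0, 0.2)),
        srt_switch_annual=ByClass(
            **{c: float(rng.uniform(0.0, 0.5)) for c in ("I", "II", "III", "IV")}
        ),
        srt_perioperative_mortality=float(rng.uniform(0.0, 0.1)),
        natural_progression_annual=progression_annual,
        natural_progression_per_cycle=annual_prob_to_cycle(progression_annual, 28.0),
        utilities=ByClass(I=float(utils[0]), II=float(utils[1]),
                          III=float(utils[2]), IV=float(utils[2])),
        mortality_hr=ByClass(I=1.0, II=float(hrs[0]), III=float(hrs[1]), IV=float(hrs[2])),
        week30_nonresponse_discontinuation=ByClass(
            I=0.0, II=0.0, III=float(rng.uniform(0.0, 1.0)), IV=float(rng.uniform(0.0, 1.0))
        ),
        horizon_age=horizon,
        cycle_days=28.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass(frozen=True)
class MicrosimArmResult:
    """Monte-Carlo estimates for one arm: means and standard errors."""

    ly_mean: float
    ly_se: float
    qaly_mean: float
    qaly_se: float
    n_patients: int


@dataclass(frozen=True)
class MicrosimResult:
    treatment: MicrosimArmResult
    control: MicrosimArmResult

    @property
    def incremental_ly(self) -> float:
        return self.treatment.ly_mean - self.control.ly_mean

    @property
    def incremental_qaly(self) -> float:
        return self.treatment.qaly_mean - self.control.qaly_mean


def microsim_arm(
    params: ModelParams,
    arm: str,
    n_patients: int,
    seed: int,
    life_table: LifeTable | None = None,
    context=None,
) -> MicrosimArmResult:
    """Simulate individual patients through the full pathway, literally.

    Each patient carries explicit memory: NYHA class before this cycle's
    transition (worsening-triggered discontinuation), a one-cycle surgical
    tunnel, and the week-30 boundary rules. Per-cycle probabilities are the
    same precomputed quantities the cohort engine uses; the pathway
    bookkeeping is deliberately independent of the engine's flow algebra.
    """
    from .pathway_engine import Line, build_context

    if n_patients < 1:
        raise ValueError("n_patients must be ≥ 1")
    ctx = context or build_context(params, arm, life_table=life_table)
    rng = np.random.default_rng(seed)
    util = params.utilities.as_array()
    baseline = params.baseline_nyha.as_array()
    cum_base = np.cumsum(baseline)

    n = n_patients
    ly = np.zeros(n)
    qaly = np.zeros(n)
    idx = np.arange(n)  # indices of patients still alive
    nyha = np.searchsorted(cum_base, rng.random(n), side="right").astype(np.int64)
    nyha = np.minimum(nyha, 3)
    line = np.full(n, Line.MAVACAMTEN if arm == "treatment" else Line.BBCCB, dtype=np.int64)

    cum_matrices = [
        [None if M is None else np.cumsum(M.probs, axis=1) for M in per_line]
        for per_line in ctx.matrices
    ]

    for k in range(len(ctx.schedule)):
        if idx.size == 0:
            break
        dt, disc = ctx.dt_years[k], ctx.discount[k]
        ly[idx] += dt * disc
        qaly[idx] += util[nyha] * dt * disc

        # 1. death
        p = ctx.p_death[k][nyha]
        in_tunnel = line == Line.SRT_TUNNEL
        if in_tunnel.any():
            p = np.where(in_tunnel, ctx.p_death_tunnel[k][nyha], p)
        survive = rng.random(idx.size) >= p
        idx, nyha, line = idx[survive], nyha[survive], line[survive]
        if idx.size == 0:
            break

        # 2. NYHA transition
        prev = nyha.copy()
        new_nyha = nyha.copy()
        for ln in Line:
            mask = line == ln
            if not mask.any():
                continue
            cum = cum_matrices[k][ln]
            if cum is None:
                raise RuntimeError(f"patients on line {Line(ln).name} with no matrix at cycle {k}")
            r = rng.random(int(mask.sum()))
            new_nyha[mask] = np.minimum(
                (r[:, None] >= cum[prev[mask], :-1]).sum(axis=1), 3
            )
        nyha = new_nyha

        # 3. switching, decided from the line held *before* any switch
        trial = ctx.schedule.phases[k] == "trial"
        line_before = line.copy()
        # tunnel is one cycle only
        line[line_before == Line.SRT_TUNNEL] = Line.POST_SRT
        if trial:
            if k == ctx.final_trial_cycle:
                on_drug = line_before == Line.MAVACAMTEN
                stop = on_drug & (rng.random(idx.size) < ctx.w30[nyha])
                line[stop] = Line.BBCCB
        else:
            on_drug = line_before == Line.MAVACAMTEN
            worsened = on_drug & (nyha > prev)
            line[worsened] = Line.BBCCB
            sae = on_drug & ~worsened & (rng.random(idx.size) < ctx.p_sae[k])
            line[sae] = Line.BBCCB
            eligible = line_before == Line.BBCCB
            if params.repeat_srt_allowed:
                eligible |= line_before == Line.POST_SRT
            to_srt = eligible & (rng.random(idx.size) < ctx.p_srt[k][nyha])
            line[to_srt] = Line.SRT_TUNNEL

    def _stats(x: np.ndarray) -> tuple[float, float]:
        se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return float(x.mean()), se

    ly_mean, ly_se = _stats(ly)
    qaly_mean, qaly_se = _stats(qaly)
    return MicrosimArmResult(ly_mean, ly_se, qaly_mean, qaly_se, n)


def microsim_oracle(
    params: ModelParams,
    n_patients: int,
    seed: int,
    life_table: LifeTable | None = None,
) -> MicrosimResult:
    """Run the patient-level oracle for both arms on a common life table."""
    from .pathway_engine import _default_life_table

    lt = life_table or _default_life_table()
    return MicrosimResult(
        treatment=microsim_arm(params, "treatment", n_patients, seed, life_table=lt),
        control=microsim_arm(params, "control", n_patients, seed + 1, life_table=lt),
    )
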