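"""NYHA-class transition matrices and time-dependent dispatch.

Four matrix families drive the living states of the model:

* the ten **trial-phase** matrices of the active-treatment arm, one per
  clinical-assessment interval between weeks 0 and 30 (published values);
* the **maintenance** matrix applied every 4-week cycle from week 30 to week
  106 — a carry-forward of the final (week 26→30) trial matrix with the
  NYHA IV row made absorbing;
* the **natural-progression** matrix applied when treatment-specific
  transitions cease (active arm beyond week 106; BB/CCB and post-SRT lines
  beyond week 30): stay with probability 1−p, worsen one class with p,
  NYHA IV absorbing;
* the single-cycle **SRT efficacy** matrix applied in the surgical tunnel
  state.

Trial states that held no patients are published as "NA" rows; these are
represented as identity rows carrying an ``observed=False`` flag, and the
cohort engine asserts that no mass is routed through a flagged row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    MAINTENANCE_END_WEEK,
    TRIAL_END_WEEK,
    NYHA,
    ModelParams,
)

Arm = Literal["treatment", "control"]

ROW_LABELS = ["NYHA_I", "NYHA_II", "NYHA_III", "NYHA_IV"]

#: Printed rows may carry rounding so that a row sums to 1 ± a few 1e-4;
#: rows are renormalised at construction and deviations beyond this rejected.
_ROUNDING_TOL = 5e-4


class MissingInputError(ValueError):
    """A required model input (e.g. control-arm matrices) was not supplied."""


class DispatchError(KeyError):
    """No transition matrix is defined for the requested arm/line/time."""


@dataclass(frozen=True)
class TransitionMatrix:
    """4×4 row-stochastic NYHA transition matrix, conditional on survival.

    ``observed[i]`` is False for rows published as NA (no occupants in the
    source data); such rows are identity placeholders and must never receive
    mass during the phase in which they are unobserved.
    """

    probs: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {p.shape}")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = p.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-12:
            raise ValueError(f"rows must sum to 1 (sums: {sums})")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "observed", np.asarray(self.observed, dtype=bool))

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[float] | None]) -> "TransitionMatrix":
        """Build from four rows; ``None`` marks an unobserved (NA) row.

        Observed rows are renormalised to absorb printed rounding (tolerance
        ``5e-4`` on the row sum).
        """
        probs = np.eye(4)
        observed = np.zeros(4, dtype=bool)
        for i, row in enumerate(rows):
            if row is None:
                continue
            r = np.asarray(row, dtype=float)
            s = r.sum()
            if abs(s - 1.0) > _ROUNDING_TOL:
                raise ValueError(f"row {i} sums to {s}, beyond rounding tolerance")
            probs[i] = r / s
            observed[i] = True
        return cls(probs, observed)

    def __getitem__(self, key: tuple[NYHA | int, NYHA | int]) -> float:
        i, j = key
        return float(self.probs[int(i), int(j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=ROW_LABELS, columns=ROW_LABELS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="from")

    @classmethod
    def read_csv(cls, path: str | Path) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != ROW_LABELS or list(df.columns) != ROW_LABELS:
            raise ValueError(f"{path}: expected rows/columns {ROW_LABELS}")
        return cls.from_rows(df.to_numpy().tolist())


@dataclass(frozen=True)
class MatrixScheduleEntry:
    """A trial-phase matrix together with the week interval it covers."""

    start_week: int
    end_week: int
    arm: Arm
    matrix: TransitionMatrix


def _identity_row() -> list[float]:
    return [1.0, 0.0, 0.0, 0.0]


# Published short-term transition probabilities, active-treatment arm.
# Rows: NYHA I..IV (None = NA, no occupants observed).
_TREATMENT_TRIAL_ROWS: dict[tuple[int, int], list[list[float] | None]] = {
    (0, 4): [
        None,
        [0.0227, 0.9773, 0.0000, 0.0000],
        [0.0000, 0.3000, 0.7000, 0.0000],
        None,
    ],
    (4, 6): [
        [1.0000, 0.0000, 0.0000, 0.0000],
        [0.0000, 1.0000, 0.0000, 0.0000],
        [0.0000, 0.1429, 0.8571, 0.0000],
        None,
    ],
    (6, 8): [
        [1.0000, 0.0000, 0.0000, 0.0000],
        [0.0426, 0.9362, 0.0213, 0.0000],
        [0.0000, 0.1667, 0.8333, 0.0000],
        None,
    ],
    (8, 12): [
        [1.0000, 0.0000, 0.0000, 0.0000],
        [0.0667, 0.9333, 0.0000, 0.0000],
        [0.0000, 0.3333, 0.6667, 0.0000],
        None,
    ],
    (12, 14): [
        [1.0000, 0.0000, 0.0000, 0.0000],
        [0.0227, 0.9318, 0.0455, 0.0000],
        [0.0000, 0.0000, 1.0000, 0.0000],
        None,
    ],
    (14, 18): [
        [1.0000, 0.0000, 0.0000, 0.0000],
        [0.0244, 0.9756, 0.0000, 0.0000],
        [0.0000, 0.3333, 0.6667, 0.0000],
        None,
    ],
    (18, 20): [
        [1.0000, 0.0000, 0.0000, 0.0000],
        [0.0000, 1.0000, 0.0000, 0.0000],
        [0.0000, 0.0000, 1.0000, 0.0000],
        None,
    ],
    (20, 24): [
        [1.0000, 0.0000, 0.0000, 0.0000],
        [0.0952, 0.8810, 0.0238, 0.0000],
        [0.0000, 0.0000, 1.0000, 0.0000],
        None,
    ],
    (24, 26): [
        [1.0000, 0.0000, 0.0000, 0.0000],
        [0.0000, 1.0000, 0.0000, 0.0000],
        [0.0000, 0.0000, 1.0000, 0.0000],
        None,
    ],
    (26, 30): [
        [1.0000, 0.0000, 0.0000, 0.0000],
        [0.3243, 0.6757, 0.0000, 0.0000],
        [0.0000, 0.4000, 0.6000, 0.0000],
        None,
    ],
}

# Published surgical-efficacy matrix (single SRT tunnel cycle).
_SRT_EFFICACY_ROWS: list[list[float]] = [
    [1.0000, 0.0000, 0.0000, 0.0000],
    [0.0000, 1.0000, 0.0000, 0.0000],
    [0.0000, 0.3871, 0.6129, 0.0000],
    [0.0000, 0.0000, 0.3548, 0.6452],
]


def trial_phase_matrices(
    arm: Arm,
    control_matrices: Sequence[MatrixScheduleEntry] | None = None,
    synthesize: bool = True,
    seed: int | None = None,
) -> list[MatrixScheduleEntry]:
    """The schedule of short-term (weeks 0–30) matrices for an arm.

    The treatment arm returns the ten published matrices. The control arm's
    matrices were never published: supply them explicitly, or (default) let
    :func:`ohcm.synthetic_data.synthetic_control_matrices` generate a
    clearly-synthetic placeholder set.
    """
    if arm == "treatment":
        return [
            MatrixScheduleEntry(w0, w1, "treatment", TransitionMatrix.from_rows(rows))
            for (w0, w1), rows in _TREATMENT_TRIAL_ROWS.items()
        ]
    if arm == "control":
        if control_matrices is not None:
            return list(control_matrices)
        if not synthesize:
            raise MissingInputError(
                "control-arm short-term matrices were not published; supply them "
                "via config or enable synthesis"
            )
        from .synthetic_data import synthetic_control_matrices

        return synthetic_control_matrices(seed=seed if seed is not None else 0)
    raise DispatchError(f"unknown arm {arm!r}")


def build_maintenance_matrix(trial: Sequence[MatrixScheduleEntry]) -> TransitionMatrix:
    """Carry the final trial-phase matrix forward over weeks 30–106.

    The week 26→30 matrix is reused verbatim on its observed rows, and the
    (unobserved) NYHA IV row is made absorbing — the published 30–106-week
    matrix.
    """
    final = max(trial, key=lambda e: e.end_week)
    if final.end_week != TRIAL_END_WEEK:
        raise ValueError("trial schedule lacks the final (week 26-30) matrix")
    probs = final.matrix.probs.copy()
    probs[NYHA.IV] = [0.0, 0.0, 0.0, 1.0]
    return TransitionMatrix(probs, np.ones(4, dtype=bool))


def natural_progression_matrix(p_cycle: float) -> TransitionMatrix:
    """Per-cycle one-class worsening with probability ``p_cycle``; IV absorbing."""
    if not 0.0 <= p_cycle <= 1.0:
        raise ValueError(f"p_cycle = {p_cycle} outside [0, 1]")
    probs = np.diag([1.0 - p_cycle] * 3 + [1.0]).astype(float)
    for i in range(3):
        probs[i, i + 1] = p_cycle
    return TransitionMatrix(probs, np.ones(4, dtype=bool))


def srt_efficacy_matrix() -> TransitionMatrix:
    """Published single-cycle NYHA response to septal reduction therapy."""
    return TransitionMatrix.from_rows(_SRT_EFFICACY_ROWS)


@dataclass(frozen=True)
class MatrixSet:
    """All matrices needed to run one arm, resolved once per trace."""

    arm: Arm
    trial: tuple[MatrixScheduleEntry, ...]
    maintenance: TransitionMatrix
    progression: TransitionMatrix
    srt: TransitionMatrix

    @classmethod
    def build(
        cls,
        arm: Arm,
        params: ModelParams,
        control_matrices: Sequence[MatrixScheduleEntry] | None = None,
        treatment_matrices: Sequence[MatrixScheduleEntry] | None = None,
        srt_matrix: TransitionMatrix | None = None,
    ) -> "MatrixSet":
        if arm == "treatment":
            trial = (
                list(treatment_matrices)
                if treatment_matrices is not None
                else trial_phase_matrices("treatment")
            )
        else:
            trial = trial_phase_matrices(
                "control", control_matrices=control_matrices, seed=params.seed
            )
        return cls(
            arm=arm,
            trial=tuple(sorted(trial, key=lambda e: e.start_week)),
            maintenance=build_maintenance_matrix(trial),
            progression=natural_progression_matrix(params.natural_progression_per_cycle),
            srt=srt_matrix if srt_matrix is not None else srt_efficacy_matrix(),
        )


def matrix_for(
    mats: MatrixSet,
    line: "str | int",
    t_days: float,
) -> TransitionMatrix:
    """Dispatch the matrix governing a treatment line at model time ``t_days``.

    Piecewise-constant in time with breakpoints only at the trial assessment
    weeks, week 30, and week 106:

    * SRT tunnel: the surgical-efficacy matrix, at any time;
    * active (mavacamten) line: trial schedule → maintenance (weeks 30–106)
      → natural progression (beyond week 106);
    * BB/CCB line: the arm's trial matrices during weeks 0–30 (control arm
      only), natural progression afterwards — treatment-specific transitions
      cease, leaving only disease progression (no improvement possible);
    * post-SRT line: natural progression (the published per-cycle post-SRT
      matrix equals it).
    """
    from .pathway_engine import Line  # local import to avoid a cycle

    line = Line(line) if not isinstance(line, str) else Line[line.upper()]
    trial_end = TRIAL_END_WEEK * 7.0
    maint_end = MAINTENANCE_END_WEEK * 7.0

    if line is Line.SRT_TUNNEL:
        return mats.srt
    if line is Line.MAVACAMTEN:
        if mats.arm != "treatment":
            raise DispatchError("mavacamten line exists only in the treatment arm")
        if t_days < trial_end:
            return _trial_lookup(mats.trial, t_days)
        if t_days < maint_end:
            return mats.maintenance
        return mats.progression
    if line is Line.BBCCB:
        if t_days < trial_end:
            if mats.arm != "control":
                raise DispatchError(
                    "no trial-phase matrices for the BB/CCB line in the treatment arm"
                )
            return _trial_lookup(mats.trial, t_days)
        return mats.progression
    if line is Line.POST_SRT:
        return mats.progression
    raise DispatchError(f"unknown treatment line {line!r}")


def _trial_lookup(trial: Sequence[MatrixScheduleEntry], t_days: float) -> TransitionMatrix:
    w = t_days / 7.0
    for entry in trial:
        if entry.start_week <= w < entry.end_week:
            return entry.matrix
    raise DispatchError(f"no trial-phase matrix covers week {w:.2f}")


def assert_no_flagged_mass(matrix: TransitionMatrix, occupancy: np.ndarray, tol: float = 1e-12) -> None:
    """Fail if mass occupies a state whose transition row is unobserved."""
    bad = (~matrix.observed) & (np.asarray(occupancy) > tol)
    if bad.any():
        classes = [NYHA(i).name for i in np.flatnonzero(bad)]
        raise RuntimeError(f"mass routed through unobserved NYHA rows: {classes}")
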