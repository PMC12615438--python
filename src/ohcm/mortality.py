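"""Background and excess mortality.

Per-cycle death probabilities combine (1) an age- and sex-specific life
table, weighted by the cohort's fixed male fraction, (2) NYHA-class hazard
ratios applied on the hazard scale (NYHA I is the general-population
reference), and (3), in the surgical tunnel cycle only, an independent
peri-operative excess risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import DAYS_PER_YEAR, ByClass

SEXES = ("male", "female")


@dataclass(frozen=True)
class LifeTable:
    """Age- and sex-indexed annual death probabilities ``qx``.

    Stored as dense arrays over a contiguous integer age range, one column
    per sex, for O(1) lookup inside the cohort loop.
    """

    age_min: int
    qx_male: np.ndarray
    qx_female: np.ndarray

    @property
    def age_max(self) -> int:
        return self.age_min + len(self.qx_male) - 1

    def qx(self, age: int, sex: str) -> float:
        if not self.age_min <= age <= self.age_max:
            raise ValueError(f"age {age} outside life table range [{self.age_min}, {self.age_max}]")
        col = self.qx_male if sex == "male" else self.qx_female
        return float(col[age - self.age_min])

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.age_min, self.age_max + 1)
        rows = [
            {"age": a, "sex": s, "qx": self.qx(a, s)} for a in ages for s in SEXES
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_life_table(path: str | Path) -> LifeTable:
    """Read and validate a ``age,sex,qx`` CSV.

    Both sexes must cover the same contiguous age range with no duplicates,
    and every ``qx`` must lie in [0, 1].
    """
    df = pd.read_csv(path)
    required = {"age", "sex", "qx"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    bad = df[(df.qx < 0) | (df.qx > 1) | df.qx.isna()]
    if len(bad):
        raise ValueError(f"{path}: qx outside [0, 1] in rows:\n{bad.to_string()}")
    unknown = set(df.sex.unique()) - set(SEXES)
    if unknown:
        raise ValueError(f"{path}: unknown sex labels {sorted(unknown)}")
    cols = {}
    ranges = {}
    for sex in SEXES:
        sub = df[df.sex == sex].sort_values("age")
        if sub.empty:
            raise ValueError(f"{path}: no rows for sex={sex}")
        ages = sub.age.to_numpy()
        if len(np.unique(ages)) != len(ages):
            dup = ages[pd.Series(ages).duplicated()].tolist()
            raise ValueError(f"{path}: duplicate ages for sex={sex}: {dup}")
        expected = np.arange(ages[0], ages[-1] + 1)
        if len(ages) != len(expected) or (ages != expected).any():
            missing = sorted(set(expected) - set(ages))
            raise ValueError(f"{path}: non-contiguous ages for sex={sex}; missing {missing}")
        cols[sex] = sub.qx.to_numpy(dtype=float)
        ranges[sex] = (int(ages[0]), int(ages[-1]))
    if ranges["male"] != ranges["female"]:
        raise ValueError(f"{path}: sexes cover different age ranges {ranges}")
    return LifeTable(age_min=ranges["male"][0], qx_male=cols["male"], qx_female=cols["female"])


@dataclass(frozen=True)
class MortalitySpec:
    """Everything needed to compute a per-cycle death probability."""

    life_table: LifeTable
    male_fraction: float
    hr: ByClass
    srt_mortality: float

    def __post_init__(self) -> None:
        if self.hr.I != 1.0:
            raise ValueError("NYHA I hazard ratio must be 1 (general-population reference)")


def weighted_annual_qx(lt: LifeTable, age: int, male_fraction: float) -> float:
    """Sex-weighted annual death probability at a completed integer age."""
    return male_fraction * lt.qx(age, "male") + (1.0 - male_fraction) * lt.qx(age, "female")


def cycle_death_prob(q_annual: float, hr: float, cycle_days: float) -> float:
    """Annual death probability → per-cycle probability under a hazard-scale HR.

    ``1 − exp(−(−ln(1−q)) · hr · cycle_days/365.25)``. Applying the hazard
    ratio on the hazard (not probability) scale keeps the result in [0, 1]
    even for large ratios at old ages.
    """
    if not 0.0 <= q_annual <= 1.0:
        raise ValueError(f"q_annual = {q_annual} outside [0, 1]")
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    if q_annual == 1.0:
        return 1.0
    hazard = -math.log(1.0 - q_annual)
    return 1.0 - math.exp(-hazard * hr * cycle_days / DAYS_PER_YEAR)


def srt_cycle_death_prob(base_cycle_p: float, srt_p: float) -> float:
    """Combine background and peri-operative risks as independent events."""
    if not 0.0 <= base_cycle_p <= 1.0 or not 0.0 <= srt_p <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return 1.0 - (1.0 - base_cycle_p) * (1.0 - srt_p)


def annual_life_expectancy(lt: LifeTable, from_age: int, male_fraction: float) -> float:
    """Discrete life expectancy Σ_k Π_{j<k}(1−q_j) on whole-year steps.

    Each year survived to its start accrues one full year (the same
    start-of-interval accrual convention the cohort engine uses).
    """
    e = 0.0
    surv = 1.0
    for age in range(from_age, lt.age_max + 1):
        e += surv
        surv *= 1.0 - weighted_annual_qx(lt, age, male_fraction)
    return e
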