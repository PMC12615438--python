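"""Model parameters, configuration loading, and time-scale conversions.

Every printed model input ships here as a typed default: the baseline cohort
(age 42, 71.60% male, NYHA II/III split 76.54/23.46), the physician-reported
annual BB/CCB→SRT escalation proportions by NYHA class, the NYHA-class
hazard ratios for excess mortality, the mapped EQ-5D-5L utility weights, and
the in-text scalars (5%/yr SAE discontinuation, ~1.80% peri-operative SRT
mortality, 4.55%/yr natural progression, 5%/yr discounting).

Probabilities quoted on an annual scale are converted to per-cycle
probabilities under a constant-hazard assumption with 365.25 days/year.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

DAYS_PER_YEAR = 365.25

#: Clinical assessment weeks of the trial phase; consecutive pairs delimit the
#: ten unequal trial cycles (4,2,2,4,2,4,2,4,2,4 weeks).
TRIAL_WEEKS: tuple[int, ...] = (0, 4, 6, 8, 12, 14, 18, 20, 24, 26, 30)

TRIAL_END_WEEK = TRIAL_WEEKS[-1]
MAINTENANCE_END_WEEK = 106  # carry-forward horizon, 108wk trial follow-up on a 4-week grid


class NYHA(enum.IntEnum):
    """New York Heart Association functional class, ordered I (best) to IV."""

    I = 0
    II = 1
    III = 2
    IV = 3

    @classmethod
    def from_label(cls, label: str) -> "NYHA":
        return cls[label.removeprefix("NYHA_").removeprefix("NYHA ")]


class ByClass(BaseModel):
    """A value per NYHA class, addressable by label or as an ordered array."""

    model_config = ConfigDict(extra="forbid")

    I: float
    II: float
    III: float
    IV: float

    def __getitem__(self, c: "NYHA | str") -> float:
        if isinstance(c, str):
            c = NYHA.from_label(c)
        return getattr(self, NYHA(c).name)

    def as_array(self):
        import numpy as np

        return np.array([self.I, self.II, self.III, self.IV], dtype=float)

    @model_validator(mode="before")
    @classmethod
    def _normalize_keys(cls, data):
        if isinstance(data, dict):
            return {str(k).removeprefix("NYHA_").removeprefix("NYHA "): v for k, v in data.items()}
        return data


def _unit_interval(m: ByClass, name: str) -> None:
    for c in NYHA:
        v = m[c]
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}.{c.name} = {v} outside [0, 1]")


class ModelParams(BaseModel):
    """The complete scalar parameter set of the cohort model.

    Transition matrices and the life table are separate inputs (see
    :mod:`ohcm.nyha_transitions`, :mod:`ohcm.mortality`); everything here is a
    scalar or a per-NYHA-class map.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    start_age: float = Field(gt=0, description="cohort age at model entry, years")
    male_fraction: float = Field(ge=0, le=1)
    baseline_nyha: ByClass
    discount_rate_annual: float = Field(ge=0)
    sae_discontinuation_annual: float = Field(ge=0, le=1)
    srt_switch_annual: ByClass
    srt_perioperative_mortality: float = Field(ge=0, le=1)
    natural_progression_annual: float = Field(ge=0, le=1)
    natural_progression_per_cycle: float = Field(ge=0, le=1)
    utilities: ByClass
    mortality_hr: ByClass
    week30_nonresponse_discontinuation: ByClass
    horizon_age: float = Field(gt=0)
    cycle_days: float = Field(gt=0)
    seed: int = Field(ge=0)
    half_cycle_correction: bool = False
    repeat_srt_allowed: bool = True

    @model_validator(mode="after")
    def _check_invariants(self) -> "ModelParams":
        b = self.baseline_nyha
        if abs(b.I + b.II + b.III + b.IV - 1.0) > 1e-9:
            raise ValueError("baseline_nyha must sum to 1")
        if b.I != 0.0 or b.IV != 0.0:
            raise ValueError("baseline cohort enters in NYHA II/III only (trial entry criteria)")
        _unit_interval(b, "baseline_nyha")
        _unit_interval(self.srt_switch_annual, "srt_switch_annual")
        _unit_interval(self.utilities, "utilities")
        _unit_interval(self.week30_nonresponse_discontinuation, "week30_nonresponse_discontinuation")
        for c in NYHA:
            if self.mortality_hr[c] <= 0:
                raise ValueError(f"mortality_hr.{c.name} must be > 0")
        if self.horizon_age <= self.start_age:
            raise ValueError("horizon_age must exceed start_age")
        return self


def default_params() -> ModelParams:
    """The published base-case parameter set."""
    return ModelParams(
        start_age=42.0,
        male_fraction=0.7160,
        baseline_nyha=ByClass(I=0.0, II=0.7654, III=0.2346, IV=0.0),
        discount_rate_annual=0.05,
        sae_discontinuation_annual=0.05,
        srt_switch_annual=ByClass(I=0.1637, II=0.2140, III=0.3280, IV=0.3926),
        srt_perioperative_mortality=0.018,
        natural_progression_annual=0.0455,
        # Printed per-cycle value; NOT the constant-hazard conversion of the
        # annual rate (which would give 0.00356) — kept as published.
        natural_progression_per_cycle=0.0034,
        utilities=ByClass(I=0.905, II=0.845, III=0.687, IV=0.687),
        mortality_hr=ByClass(I=1.00, II=1.80, III=4.12, IV=10.90),
        week30_nonresponse_discontinuation=ByClass(I=0.0, II=0.0, III=1.0, IV=1.0),
        horizon_age=100.0,
        cycle_days=28.0,
        seed=20251031,
    )


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> ModelParams:
    """Load a YAML/JSON configuration as overrides on :func:`default_params`.

    Unknown keys are rejected; all invariants are re-validated. An empty file
    yields the defaults unchanged.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        override = json.loads(text) if text.strip() else {}
    else:
        override = yaml.safe_load(text) or {}
    if not isinstance(override, dict):
        raise ValueError(f"{path}: top level must be a mapping, got {type(override).__name__}")
    merged = _deep_merge(default_params().model_dump(), override)
    return ModelParams.model_validate(merged)


def apply_param(params: ModelParams, name: str, value: float) -> ModelParams:
    """Return a copy of *params* with the named scalar set to *value*.

    Names are dotted paths, e.g. ``"utilities.III"`` or ``"mortality_hr.IV"``.
    ``"baseline_nyha.II"`` keeps the distribution normalised by assigning the
    complement to class III (the only other occupied entry class).
    """
    data = params.model_dump()
    current = data
    for part in name.split("."):
        current = current[part] if isinstance(current, dict) and part in current else None
        if current is None:
            break
    if current == value:  # no-op edits stay bit-identical
        return params
    if name == "baseline_nyha.II":
        data["baseline_nyha"]["II"] = value
        data["baseline_nyha"]["III"] = 1.0 - value
    elif "." in name:
        group, cls = name.split(".", 1)
        if group not in data or cls not in data[group]:
            raise KeyError(name)
        data[group][cls] = value
    else:
        if name not in data:
            raise KeyError(name)
        data[name] = value
    return ModelParams.model_validate(data)


# ---------------------------------------------------------------------------
# time conversions


def annual_prob_to_cycle(p_annual: float, cycle_days: float) -> float:
    """Constant-hazard rescaling of an annual probability to a cycle length.

    ``1 - (1 - p)^(cycle_days / 365.25)``.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual = {p_annual} outside [0, 1]")
    if cycle_days <= 0:
        raise ValueError("cycle_days must be > 0")
    if p_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** (cycle_days / DAYS_PER_YEAR)


def cycle_prob_to_annual(p_cycle: float, cycle_days: float) -> float:
    """Exact inverse of :func:`annual_prob_to_cycle`."""
    if not 0.0 <= p_cycle <= 1.0:
        raise ValueError(f"p_cycle = {p_cycle} outside [0, 1]")
    if cycle_days <= 0:
        raise ValueError("cycle_days must be > 0")
    if p_cycle == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_cycle) ** (DAYS_PER_YEAR / cycle_days)


# ---------------------------------------------------------------------------
# cycle schedule

Phase = Literal["trial", "maintenance", "long_term"]


@dataclass(frozen=True)
class CycleSchedule:
    """Ordered cycle boundaries: ten unequal trial cycles, then a uniform grid.

    The trial phase mirrors the clinical assessment weeks
    {0,4,6,8,12,14,18,20,24,26,30}; afterwards every cycle has length
    ``cycle_days`` (28 days by default, the dosing interval) out to the
    horizon age.
    """

    start_days: tuple[float, ...]
    end_days: tuple[float, ...]
    phases: tuple[Phase, ...]

    @classmethod
    def build(cls, params: ModelParams) -> "CycleSchedule":
        starts: list[float] = []
        ends: list[float] = []
        phases: list[Phase] = []
        horizon_days = (params.horizon_age - params.start_age) * DAYS_PER_YEAR
        eps = 1e-9  # absorb float error in horizon arithmetic
        for w0, w1 in zip(TRIAL_WEEKS[:-1], TRIAL_WEEKS[1:]):
            if w0 * 7.0 >= horizon_days - eps:
                return cls(tuple(starts), tuple(ends), tuple(phases))
            starts.append(w0 * 7.0)
            ends.append(w1 * 7.0)
            phases.append("trial")
        t = TRIAL_END_WEEK * 7.0
        maintenance_end = MAINTENANCE_END_WEEK * 7.0
        while t < horizon_days - eps:
            starts.append(t)
            ends.append(t + params.cycle_days)
            phases.append("maintenance" if t < maintenance_end else "long_term")
            t += params.cycle_days
        return cls(tuple(starts), tuple(ends), tuple(phases))

    def __len__(self) -> int:
        return len(self.start_days)

    def lengths_days(self) -> tuple[float, ...]:
        return tuple(e - s for s, e in zip(self.start_days, self.end_days))

    @property
    def n_trial_cycles(self) -> int:
        return sum(1 for p in self.phases if p == "trial")

    def is_final_trial_cycle(self, k: int) -> bool:
        return self.phases[k] == "trial" and (
            k + 1 == len(self) or self.phases[k + 1] != "trial"
        )


# ---------------------------------------------------------------------------
# sensitivity-analysis parameter specification

DistTag = Literal["dirichlet_row", "beta", "lognormal", "normal"]


@dataclass(frozen=True)
class ParamSpec:
    """A scalar parameter with point estimate and 95% interval for DSA/PSA.

    When no interval is published, callers construct bounds with
    ``point ± 1.96 × (0.10 × point)`` (the SE = 10%-of-point rule).
    """

    name: str
    point: float
    lower: float
    upper: float
    dist: DistTag = "beta"

    def __post_init__(self) -> None:
        if not self.lower <= self.point <= self.upper:
            raise ValueError(
                f"{self.name}: bounds ({self.lower}, {self.upper}) must bracket point {self.point}"
            )

    @classmethod
    def from_se_rule(cls, name: str, point: float, dist: DistTag = "beta",
                     clamp: tuple[float, float] | None = None) -> "ParamSpec":
        half = 1.96 * 0.10 * point
        lo, hi = point - half, point + half
        if clamp is not None:
            lo, hi = max(lo, clamp[0]), min(hi, clamp[1])
        return cls(name, point, lo, hi, dist)
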