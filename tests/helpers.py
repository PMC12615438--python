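"""Shared builders for degenerate model configurations used across tests."""

import numpy as np

from ohcm.nyha_transitions import MatrixScheduleEntry, TransitionMatrix
from ohcm.parameters import TRIAL_WEEKS, ModelParams, default_params


def identity_schedule(arm="treatment"):
    """All ten trial intervals with identity (fully observed) matrices."""
    ident = TransitionMatrix(np.eye(4), np.ones(4, dtype=bool))
    return [
        MatrixScheduleEntry(w0, w1, arm, ident)
        for w0, w1 in zip(TRIAL_WEEKS[:-1], TRIAL_WEEKS[1:])
    ]


def inert_params(**overrides) -> ModelParams:
    """No switching, no progression, no discounting unless overridden."""
    p = default_params().model_dump()
    p.update(
        dict(
            sae_discontinuation_annual=0.0,
            srt_switch_annual={"I": 0.0, "II": 0.0, "III": 0.0, "IV": 0.0},
            natural_progression_per_cycle=0.0,
            srt_perioperative_mortality=0.0,
            week30_nonresponse_discontinuation={"I": 0.0, "II": 0.0, "III": 0.0, "IV": 0.0},
            discount_rate_annual=0.0,
        )
    )
    p.update(overrides)
    return ModelParams.model_validate(p)
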