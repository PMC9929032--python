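"""Reading and writing the delimited trial and parameter tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import CUES, GROUPS, KICK_TYPES, OCCLUSIONS, RESPONSES, TrialRecord

TRIAL_COLUMNS = ["participant_id", "group", "kick_type", "occlusion", "outcome_cue", "response"]
PARAM_COLUMNS = ["participant_id", "group", "cell", "SP_hat", "pB_hat", "log_posterior", "converged", "n_trials"]

_VOCAB = {
    "group": GROUPS,
    "kick_type": KICK_TYPES,
    "occlusion": OCCLUSIONS,
    "outcome_cue": CUES,
    "response": RESPONSES,
}


class ValidationError(ValueError):
    """A table is missing a required column or holds an unknown label."""


def validate_trial_table(df: pd.DataFrame, require_response: bool = False) -> None:
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"trial table is missing required column {col!r}")
    for col, vocab in _VOCAB.items():
        values = df[col].dropna()
        bad = set(values.unique()) - set(vocab)
        if bad:
            raise ValidationError(f"column {col!r} holds unknown labels {sorted(bad)!r}")
    if require_response and df["response"].isna().any():
        raise ValidationError("column 'response' holds missing values")


def read_trials(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    validate_trial_table(df)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    validate_trial_table(df)
    df.to_csv(path, index=False)


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    validate_trial_table(df)
    return [
        TrialRecord(
            participant_id=str(row.participant_id),
            group=None if pd.isna(row.group) else str(row.group),
            kick_type=str(row.kick_type),
            occlusion=str(row.occlusion),
            outcome_cue=str(row.outcome_cue),
            response=None if pd.isna(row.response) else str(row.response),
        )
        for row in df.itertuples(index=False)
    ]


def frame_from_trials(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "group": t.group,
                "kick_type": t.kick_type,
                "occlusion": t.occlusion,
                "outcome_cue": t.outcome_cue,
                "response": t.response,
            }
            for t in trials
        ]
    )


def read_parameter_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in PARAM_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"parameter table is missing required column {col!r}")
    return df


def write_parameter_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
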