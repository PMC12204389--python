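"""Delimited-text I/O for trial tables and model parameters."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .glmhmm import GLMHMMParams

__all__ = ["write_trial_table", "read_trial_table", "save_params", "load_params"]

#: columns every trial table must carry (derived columns are optional extras)
CORE_COLUMNS = [
    "session_id",
    "subject_id",
    "block_index",
    "trial_number",
    "reward_magnitude",
    "reward_probability",
    "decision",
    "reward_outcome",
]


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table as tab-separated text with a single header row."""
    missing = [c for c in CORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: not a trial table (missing {missing})")
    return table


def save_params(params: GLMHMMParams, path) -> None:
    Path(path).write_text(params.to_json())


def load_params(path) -> GLMHMMParams:
    return GLMHMMParams.from_json(Path(path).read_text())
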