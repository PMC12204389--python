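"""Derived behavioral regressors.

All window statistics are strictly retrospective — computed over the w
trials *preceding* the current trial — and never cross a session boundary:

* richness_t   = mean(reward_outcome_{t-w .. t-1})
* stochasticity_t = sd(richness_{t-w .. t-1})          (sample sd, ddof=1)
* AveEV_t      = mean(EV_{t-w .. t-1}),  EV = magnitude x probability
* behavioral_history_t = decision_{t-1}

Trials whose window crosses the session start are left missing (NaN) and
are excluded listwise from any regression that uses the affected column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .task import PROB_GRID

__all__ = [
    "expected_value",
    "env_richness",
    "env_stochasticity",
    "ave_ev",
    "behavioral_history",
    "lagged_outcomes",
    "add_derived_regressors",
    "zscore_within",
    "TrialFeaturizer",
]

DEFAULT_WINDOW = 5

#: continuous columns z-scored within subject before model fitting
ZSCORE_COLUMNS = [
    "reward_magnitude",
    "reward_probability",
    "richness",
    "stochasticity",
    "ev",
    "ave_ev",
    "trial_number",
]


def expected_value(magnitude, probability):
    """EV of an offer: magnitude x probability. Probability must sit on the
    0.05 grid the stimulus can display."""
    magnitude = np.asarray(magnitude)
    probability = np.asarray(probability)
    if np.any((probability < PROB_GRID - 1e-9) | (probability > 1 + 1e-9)):
        raise ValueError("probability outside [0.05, 1]")
    ratio = probability / PROB_GRID
    if not np.allclose(ratio, np.round(ratio), atol=1e-6):
        raise ValueError("probability not on the 0.05 grid")
    if not np.all(np.isin(magnitude, [1, 2, 3])):
        raise ValueError("magnitude must be 1, 2 or 3 drops")
    return magnitude * probability


def _trailing(series: pd.Series, w: int, fn: str) -> pd.Series:
    shifted = series.shift(1)
    roll = shifted.rolling(w, min_periods=w)
    return roll.mean() if fn == "mean" else roll.std(ddof=1)


def env_richness(outcomes, w: int = DEFAULT_WINDOW) -> pd.Series:
    """Trailing w-trial mean of received reward; NaN for the first w trials."""
    return _trailing(pd.Series(np.asarray(outcomes, dtype=float)), w, "mean")


def env_stochasticity(richness_series, w: int = DEFAULT_WINDOW) -> pd.Series:
    """Trailing w-trial sample sd of the richness series."""
    return _trailing(pd.Series(np.asarray(richness_series, dtype=float)), w, "std")


def ave_ev(ev_series, w: int = DEFAULT_WINDOW) -> pd.Series:
    """Trailing w-trial mean of offered expected values (reward availability)."""
    return _trailing(pd.Series(np.asarray(ev_series, dtype=float)), w, "mean")


def behavioral_history(decisions) -> pd.Series:
    """Previous trial's pursue/reject decision; NaN on trial 1."""
    return pd.Series(np.asarray(decisions, dtype=float)).shift(1)


def lagged_outcomes(outcomes, max_lag: int = 10) -> pd.DataFrame:
    """Reward outcomes on trials t-1 .. t-max_lag as columns outcome_lag{k}."""
    s = pd.Series(np.asarray(outcomes, dtype=float))
    return pd.DataFrame({f"outcome_lag{k}": s.shift(k) for k in range(1, max_lag + 1)})


def add_derived_regressors(
    table: pd.DataFrame,
    w: int = DEFAULT_WINDOW,
    max_lag: int = 10,
    richness_from_blocks: bool = False,
) -> pd.DataFrame:
    """Return a copy of the trial table with all derived columns added.

    Computations group by session so no window leaks across sessions.
    ``richness_from_blocks`` switches the richness regressor to the design
    block label (robustness variant) instead of the trailing reward mean.
    """
    out = table.copy()
    out["ev"] = expected_value(out["reward_magnitude"], out["reward_probability"])
    grp = out.groupby("session_id", sort=False)
    parts = []
    for _, g in grp:
        rich = env_richness(g["reward_outcome"].to_numpy(), w)
        block = pd.DataFrame(
            {
                "richness": rich.to_numpy(),
                "stochasticity": env_stochasticity(rich.to_numpy(), w).to_numpy(),
                "ave_ev": ave_ev(g["ev"].to_numpy(), w).to_numpy(),
                "behavioral_history": behavioral_history(
                    g["decision"].to_numpy()
                ).to_numpy(),
            },
            index=g.index,
        )
        lags = lagged_outcomes(g["reward_outcome"].to_numpy(), max_lag)
        lags.index = g.index
        parts.append(pd.concat([block, lags], axis=1))
    derived = pd.concat(parts).sort_index()
    out = pd.concat([out, derived], axis=1)
    if richness_from_blocks:
        out["richness"] = out["richness_cue"]
    if "rt" in out.columns:
        out["log_rt"] = np.log(out["rt"])
    return out


def zscore_within(
    table: pd.DataFrame,
    columns=ZSCORE_COLUMNS,
    group: str = "subject_id",
    prefix: str = "z_",
) -> pd.DataFrame:
    """Within-group z-scores of the given columns, added as ``z_*`` columns."""
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        g = out.groupby(group)[col]
        out[prefix + col] = (out[col] - g.transform("mean")) / g.transform("std")
    return out


class TrialFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer adding derived regressors (and optional z-scores) to a
    trial table.  Stateless; ``fit`` only validates the schema.

    Parameters
    ----------
    window : trailing window length in trials for richness / stochasticity /
        AveEV (default 5).
    max_lag : number of lagged-outcome columns.
    zscore : add within-subject z-scored copies of continuous regressors.
    richness_from_blocks : use the block design label as the richness
        regressor instead of the trailing reward mean.
    """

    REQUIRED = ["session_id", "reward_magnitude", "reward_probability",
                "decision", "reward_outcome"]

    def __init__(self, window: int = DEFAULT_WINDOW, max_lag: int = 10,
                 zscore: bool = True, richness_from_blocks: bool = False):
        self.window = window
        self.max_lag = max_lag
        self.zscore = zscore
        self.richness_from_blocks = richness_from_blocks

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in self.REQUIRED if c not in X.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = add_derived_regressors(
            X, w=self.window, max_lag=self.max_lag,
            richness_from_blocks=self.richness_from_blocks,
        )
        if self.zscore:
            out = zscore_within(out)
        return out
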