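"""ROI time-course statistics on (synthetic) BOLD signal.

Machinery: per-session ROI series are z-scored, up-sampled by a factor of
15 from the native TR of 1.282 s, and epoched to 6-s windows from 1 s
before to 5 s after stimulus onset.  Ordinary least squares is run at
each time point across trials, giving a beta time course per regressor
per session.  Group inference uses a leave-one-out peak selection: the
peak time for session s is the argmax of the mean |beta| curve of the
other sessions inside a 1-5 s post-onset window, so session s never
selects its own peak (no selection bias); the collected peak betas are
tested with a two-tailed one-sample t-test, Holm-corrected across ROIs
or regressors within an analysis family.

A synthetic ROI generator convolves task events with a gamma-shaped
hemodynamic response (peak ~4 s, the canonical macaque latency) plus
autocorrelated noise, so injected effects are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TR",
    "UPSAMPLE",
    "EPOCH_WINDOW",
    "hrf",
    "synthesize_bold",
    "epoch_upsample",
    "EpochedSeries",
    "ols_timecourse",
    "loo_peak_stats",
    "TimecourseStats",
    "holm_correct",
    "ppi_fit",
    "transition_window_scan",
    "BOLD_GLMS",
    "bold_design",
]

TR = 1.282  # seconds
UPSAMPLE = 15
EPOCH_WINDOW = (-1.0, 5.0)  # seconds around stimulus onset
PEAK_SEARCH_WINDOW = (1.0, 5.0)  # post-onset, centered on the macaque HRF


def hrf(t, peak: float = 4.0, shape: float = 6.0):
    """Gamma-shaped hemodynamic response, unit peak at ``peak`` seconds."""
    t = np.asarray(t, float)
    theta = peak / (shape - 1.0)
    tp = np.where(t > 0, t, 0.0)
    return (tp / peak) ** (shape - 1) * np.exp(-(tp - peak) / theta) * (t > 0)


#: regressor sets of the ROI time-course GLM registry (confounds included)
BOLD_GLMS = {
    "GLM3.1": ["reward_magnitude", "reward_probability", "richness",
               "stochasticity", "behavioral_history",
               "richness:behavioral_history", "stochasticity:behavioral_history",
               "pupil_iti", "trial_number"],
    "GLM3.2": ["reward_magnitude", "reward_probability", "richness",
               "stochasticity", "pupil_iti", "trial_number"],
    "GLM3.3": ["decision", "pupil_iti", "trial_number"],
    "GLM3.4": ["transition_period", "motivation", "pupil_iti", "trial_number"],
    "GLM3.5": ["ev", "ave_ev", "pupil_iti", "trial_number"],
}


def bold_design(table: pd.DataFrame, glm: str) -> pd.DataFrame:
    """Trial-level design for one registry GLM (interaction terms built as
    products of the named columns); rows with missing regressors dropped
    by the caller via the returned frame's NaNs."""
    if glm not in BOLD_GLMS:
        raise KeyError(f"unknown BOLD GLM {glm!r}")
    out = pd.DataFrame(index=table.index)
    for term in BOLD_GLMS[glm]:
        if ":" in term:
            a, b = term.split(":")
            out[term] = table[a] * table[b]
        else:
            out[term] = table[term]
    return out


def synthesize_bold(
    onsets_s,
    trial_effects=None,
    duration_s: float | None = None,
    tr: float = TR,
    hrf_peak: float = 4.0,
    noise_sd: float = 1.0,
    ar_coef: float = 0.4,
    rng=None,
):
    """Synthetic ROI series: each trial contributes an HRF-shaped response
    of amplitude ``1 + trial_effects[i]`` at its onset, on top of AR(1)
    Gaussian noise.  Returns ``(series, t)`` sampled at the native TR."""
    rng = np.random.default_rng(rng)
    onsets_s = np.asarray(onsets_s, float)
    if trial_effects is None:
        trial_effects = np.zeros(len(onsets_s))
    trial_effects = np.asarray(trial_effects, float)
    if duration_s is None:
        duration_s = onsets_s[-1] + 20.0
    t = np.arange(0.0, duration_s, tr)
    series = np.zeros_like(t)
    for onset, eff in zip(onsets_s, trial_effects):
        series += (1.0 + eff) * hrf(t - onset, peak=hrf_peak)
    eps = rng.normal(0.0, noise_sd, size=len(t))
    noise = np.empty_like(eps)
    noise[0] = eps[0]
    for i in range(1, len(eps)):
        noise[i] = ar_coef * noise[i - 1] + eps[i]
    return series + noise, t


@dataclass
class EpochedSeries:
    """Trials x upsampled-time matrix around stimulus onsets."""

    data: np.ndarray  # (n_trials_kept, n_samples)
    times: np.ndarray  # seconds relative to onset
    kept: np.ndarray  # boolean per input trial (False = too close to an edge)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def epoch_upsample(
    series,
    onsets_s,
    tr: float = TR,
    window=EPOCH_WINDOW,
    factor: int = UPSAMPLE,
    normalize: bool = True,
) -> EpochedSeries:
    """Epoch an ROI series to per-trial windows on a x15 upsampled grid.

    The series is z-scored per session (``normalize``), linearly
    interpolated to a time step of TR/factor, and sliced to the 6-s window
    around each onset.  Trials whose window leaves the series are flagged
    out in ``kept``.
    """
    series = np.asarray(series, float)
    onsets_s = np.asarray(onsets_s, float)
    if normalize:
        series = (series - series.mean()) / series.std()
    t_native = np.arange(len(series)) * tr
    dt = tr / factor
    n_samp = int(round((window[1] - window[0]) * factor / tr))
    rel = window[0] + dt * np.arange(n_samp)
    kept = np.zeros(len(onsets_s), dtype=bool)
    rows = []
    for i, onset in enumerate(onsets_s):
        tt = onset + rel
        if tt[0] < 0 or tt[-1] > t_native[-1]:
            continue
        kept[i] = True
        rows.append(np.interp(tt, t_native, series))
    return EpochedSeries(np.array(rows), rel, kept)


def _check_rank(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name a minimal offending column by greedy elimination
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                raise ValueError(
                    f"design is rank-deficient; column {names[j]!r} is "
                    "collinear with the others"
                )
        raise ValueError("design is rank-deficient")


def ols_timecourse(epochs: EpochedSeries, design: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint OLS across trials; returns a (regressor x time) frame
    of beta weights.  An intercept is added; the design must be full rank."""
    X = np.asarray(design, float)
    if X.shape[0] != epochs.n_trials:
        raise ValueError(
            f"design has {X.shape[0]} rows but epochs have {epochs.n_trials} trials"
        )
    names = ["Intercept"] + list(design.columns)
    X = np.column_stack([np.ones(X.shape[0]), X])
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, epochs.data, rcond=None)
    return pd.DataFrame(beta, index=names, columns=epochs.times)


@dataclass
class TimecourseStats:
    """Leave-one-out peak statistics for one regressor."""

    peak_betas: np.ndarray  # one per session
    peak_times: np.ndarray  # chosen without that session
    t_stat: float
    p_value: float
    df: int


def loo_peak_stats(beta_curves: np.ndarray, times: np.ndarray,
                   window=PEAK_SEARCH_WINDOW) -> TimecourseStats:
    """Unbiased peak estimation: for each session, the peak time is the
    argmax of the mean |beta| curve of the *other* sessions inside the
    search window; the session's beta at that time enters a two-tailed
    one-sample t-test."""
    beta_curves = np.asarray(beta_curves, float)
    n = beta_curves.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sessions for leave-one-out statistics")
    in_win = (times >= window[0]) & (times <= window[1])
    win_idx = np.flatnonzero(in_win)
    peaks = np.empty(n)
    peak_t = np.empty(n)
    for s in range(n):
        others = np.delete(beta_curves, s, axis=0).mean(axis=0)
        j = win_idx[np.argmax(np.abs(others[win_idx]))]
        peaks[s] = beta_curves[s, j]
        peak_t[s] = times[j]
    t, p = stats.ttest_1samp(peaks, 0.0)
    return TimecourseStats(peaks, peak_t, float(t), float(p), n - 1)


def holm_correct(p_values) -> np.ndarray:
    """Bonferroni-Holm adjusted p-values (family = ROIs or regressors)."""
    return multipletests(np.asarray(p_values, float), method="holm")[1]


def ppi_fit(
    target_epochs: EpochedSeries,
    seed_epochs: EpochedSeries,
    psych_var,
    confounds: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Psychophysiological interaction: per-timepoint OLS of the target on
    [seed(t), psych, seed(t) x psych, confounds].  Returns the beta time
    courses (rows: Intercept, seed, psych, ppi, confounds...)."""
    psych = np.asarray(psych_var, float)
    if psych.std() == 0:
        raise ValueError("psychological variable is constant")
    if target_epochs.data.shape != seed_epochs.data.shape:
        raise ValueError("target and seed epochs must be aligned")
    n_t = target_epochs.data.shape[1]
    names = ["Intercept", "seed", "psych", "ppi"]
    C = None
    if confounds is not None:
        C = np.asarray(confounds, float)
        names += list(confounds.columns)
    betas = np.empty((len(names), n_t))
    for j in range(n_t):
        s = seed_epochs.data[:, j]
        cols = [np.ones_like(s), s, psych, s * psych]
        if C is not None:
            cols.extend(C.T)
        X = np.column_stack(cols)
        betas[:, j], *_ = np.linalg.lstsq(X, target_epochs.data[:, j], rcond=None)
    return pd.DataFrame(betas, index=names, columns=target_epochs.times)


def transition_window_scan(
    epochs_by_session,
    paths_by_session,
    confounds_by_session=None,
    offsets_list=None,
):
    """Re-run the transition-period GLM for each seven-trial window
    placement from (t-6..t) to (t..t+6) and collect leave-one-out peak
    statistics on the transition regressor at each placement.

    Returns a frame (offsets, t, p, mean_peak_beta, n_transitions); empty
    placements (no transitions anywhere) are flagged with NaN statistics.
    """
    if offsets_list is None:
        offsets_list = [(-6 + i, 0 + i) for i in range(7)]
    rows = []
    for off in offsets_list:
        curves = []
        n_trans = 0
        for s, (ep, path) in enumerate(zip(epochs_by_session, paths_by_session)):
            mask = path.period_mask(off)[ep.kept].astype(float)
            n_trans += len(path.transitions)
            design = pd.DataFrame(
                {"transition_period": mask,
                 "motivation": path.motivation[ep.kept].astype(float)}
            )
            if confounds_by_session is not None:
                conf = confounds_by_session[s]
                design = pd.concat(
                    [design, conf.loc[ep.kept].reset_index(drop=True)], axis=1
                )
            if mask.std() == 0:  # no transition period in this session/window
                continue
            betas = ols_timecourse(ep, design)
            curves.append(betas.loc["transition_period"].to_numpy())
        if len(curves) < 3:
            rows.append({"offsets": off, "t": np.nan, "p": np.nan,
                         "mean_peak_beta": np.nan, "n_sessions": len(curves),
                         "n_transitions": n_trans})
            continue
        st = loo_peak_stats(np.array(curves), epochs_by_session[0].times)
        rows.append({"offsets": off, "t": st.t_stat, "p": st.p_value,
                     "mean_peak_beta": float(st.peak_betas.mean()),
                     "n_sessions": len(curves), "n_transitions": n_trans})
    return pd.DataFrame(rows)
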