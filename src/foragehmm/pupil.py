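"""Pupillometry preprocessing and epoching (exercised on synthetic traces).

Traces are sampled at 250 Hz (pupil diameter plus x/y gaze).  The
preprocessing chain: scrub blinks and artefacts (adjacent-sample jumps
> 50 a.u.) together with symmetric 25-sample (0.1 s) guard windows and
linearly interpolate; low-pass at 4 Hz (zero-phase 3rd-order Butterworth);
z-score; regress x/y gaze out of pupil size and keep the residual.

Epoching extracts, per trial, the mean residual pupil 0.5-0 s before
stimulus onset (ITI phase) and 0.5-1.0 s after it (decision phase) —
the first 0.5 s post-onset is skipped to avoid luminance transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PupilTrace",
    "preprocess_pupil",
    "epoch_pupil",
    "simulate_session_pupil",
    "SAMPLE_RATE",
]

SAMPLE_RATE = 250.0  # Hz
ARTEFACT_JUMP = 50.0  # a.u. between consecutive samples
SCRUB_HALF_WINDOW = 25  # samples each side of a flagged sample
LOWPASS_HZ = 4.0


@dataclass
class PupilTrace:
    """Raw eye-tracker record for one session."""

    pupil: np.ndarray
    x_gaze: np.ndarray
    y_gaze: np.ndarray
    blink: np.ndarray  # boolean per sample
    fs: float = SAMPLE_RATE

    def __post_init__(self):
        n = len(self.pupil)
        if not (len(self.x_gaze) == len(self.y_gaze) == len(self.blink) == n):
            raise ValueError("all channels must have equal length")
        self.blink = np.asarray(self.blink, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.pupil)


def _scrub_mask(x: np.ndarray, blink: np.ndarray) -> np.ndarray:
    """Samples to remove: blinks and >50 a.u. jumps, each dilated by the
    symmetric 25-sample guard window."""
    bad = blink.copy()
    jumps = np.abs(np.diff(x)) > ARTEFACT_JUMP
    bad[:-1] |= jumps
    bad[1:] |= jumps
    if bad.any():
        # dilate by +-SCRUB_HALF_WINDOW
        kernel = np.ones(2 * SCRUB_HALF_WINDOW + 1, dtype=int)
        bad = np.convolve(bad.astype(int), kernel, mode="same") > 0
    return bad


def _interpolate(x: np.ndarray, bad: np.ndarray) -> np.ndarray:
    good = ~bad
    if good.sum() < 2:
        raise ValueError("trace has fewer than 2 clean samples")
    idx = np.arange(len(x))
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[good], x[good])
    return out


def _clean_channel(x, blink, fs):
    bad = _scrub_mask(x, blink)
    x = _interpolate(np.asarray(x, float), bad)
    sos = signal.butter(3, LOWPASS_HZ, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    return (x - x.mean()) / x.std(), bad


def preprocess_pupil(trace: PupilTrace, max_scrub_frac: float = 0.5):
    """Clean a trace and return ``(residual, info)``.

    ``residual`` is the z-scored, filtered pupil signal with linear x/y-gaze
    contributions regressed out.  ``info`` records the scrubbed fraction and
    a ``usable`` flag (False when more than ``max_scrub_frac`` of samples
    were scrubbed, after which the residual should not be analyzed).
    """
    z_pupil, bad = _clean_channel(trace.pupil, trace.blink, trace.fs)
    z_x, _ = _clean_channel(trace.x_gaze, trace.blink, trace.fs)
    z_y, _ = _clean_channel(trace.y_gaze, trace.blink, trace.fs)
    G = np.column_stack([np.ones_like(z_x), z_x, z_y])
    coef, *_ = np.linalg.lstsq(G, z_pupil, rcond=None)
    residual = z_pupil - G @ coef
    frac = float(bad.mean())
    info = {"scrub_fraction": frac, "usable": frac <= max_scrub_frac,
            "gaze_coef": coef[1:]}
    return residual, info


def epoch_pupil(residual: np.ndarray, stimulus_onsets_s, fs: float = SAMPLE_RATE,
                blink: np.ndarray | None = None,
                max_closed_frac: float = 0.5) -> pd.DataFrame:
    """Per-trial mean pupil in the ITI phase (-0.5..0 s) and decision phase
    (+0.5..+1.0 s) around each stimulus onset.

    Trials whose windows fall outside the trace are flagged missing, as are
    trials where the eyes were closed (blinks) for more than
    ``max_closed_frac`` of either window.
    """
    n = len(residual)
    half = int(round(0.5 * fs))  # 125 samples at 250 Hz
    rows = []
    for i, onset in enumerate(np.asarray(stimulus_onsets_s, float)):
        s = int(round(onset * fs))
        iti_lo, iti_hi = s - half, s
        dec_lo, dec_hi = s + half, s + 2 * half
        valid = iti_lo >= 0 and dec_hi <= n
        closed = False
        if valid and blink is not None:
            closed = (
                blink[iti_lo:iti_hi].mean() > max_closed_frac
                or blink[dec_lo:dec_hi].mean() > max_closed_frac
            )
        if valid and not closed:
            rows.append(
                {"trial": i, "pupil_iti": residual[iti_lo:iti_hi].mean(),
                 "pupil_decision": residual[dec_lo:dec_hi].mean(), "valid": True}
            )
        else:
            rows.append({"trial": i, "pupil_iti": np.nan,
                         "pupil_decision": np.nan, "valid": False})
    return pd.DataFrame(rows)


def simulate_session_pupil(
    onsets_s: np.ndarray,
    motivation: np.ndarray,
    rng,
    state_gain: float = 0.4,
    noise_sd: float = 0.3,
    gaze_gain: float = 0.5,
    blink_rate_hz: float = 0.1,
    fs: float = SAMPLE_RATE,
    baseline: float = 1500.0,
    scale: float = 60.0,
) -> PupilTrace:
    """Synthetic eye-tracker trace with a motivation-linked slow pupil
    component (high state -> larger pupil), gaze leakage into the pupil
    channel, slow drift, and occasional blinks.

    Emulates only the features the preprocessing chain consumes: realistic
    amplitudes, slow dynamics, gaze correlation, and blink dropouts.
    """
    rng = np.random.default_rng(rng)
    onsets_s = np.asarray(onsets_s, float)
    motivation = np.asarray(motivation, float)
    n = int(round((onsets_s[-1] + 8.0) * fs))
    t = np.arange(n) / fs
    # per-sample motivation level (step function across trials)
    level = np.zeros(n)
    edges = np.concatenate([onsets_s, [t[-1] + 1]])
    for i in range(len(onsets_s)):
        level[(t >= edges[i]) & (t < edges[i + 1])] = motivation[i]
    # slow dynamics: smooth the step function with a 2 s moving average
    w = int(2 * fs)
    level = np.convolve(level, np.ones(w) / w, mode="same")
    sos = signal.butter(2, 0.5, btype="low", fs=fs, output="sos")
    drift = signal.sosfiltfilt(sos, rng.normal(0, 1, n)) * 3.0
    noise = signal.sosfiltfilt(sos, rng.normal(0, 1, n)) * noise_sd * 10
    x_gaze = signal.sosfiltfilt(sos, rng.normal(0, 1, n)) * 20
    y_gaze = signal.sosfiltfilt(sos, rng.normal(0, 1, n)) * 20
    pupil = baseline + scale * (state_gain * level + drift + noise) + gaze_gain * x_gaze
    blink = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(blink_rate_hz * t[-1])
    for s in rng.integers(0, max(n - 60, 1), size=n_blinks):
        blink[s: s + rng.integers(25, 60)] = True
    pupil = pupil.copy()
    pupil[blink] = 0.0  # tracker drops to zero during blinks
    return PupilTrace(pupil=pupil, x_gaze=x_gaze, y_gaze=y_gaze, blink=blink, fs=fs)
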