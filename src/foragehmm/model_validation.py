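"""Simulation-based validation of the GLM-HMM pipeline.

Three families of experiment, all fully seeded:

* decoding validation — simulate datasets from the reference two-state
  agent, re-fit the model to each dataset, Viterbi-decode, and score
  trialwise state accuracy and the distance between decoded and true
  state-transition trials;
* model and parameter recovery — simulate from one-state and two-state
  generators and check that cross-validated model selection recovers the
  generating K and that bias/self-transition estimates recover the
  generating values;
* behavioral recapitulation — decision autocorrelation, run-length
  distributions, and the richness / choice-history regressions compared
  between two-state GLM-HMM simulations and matched stateless binomial-GLM
  simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import task
from .glmhmm import GLMHMM, build_design, decode_transitions, select_k, cross_validate_states
from .behavior_glms import fit_model, get_spec

__all__ = [
    "DecodingReport",
    "RecapReport",
    "decoding_experiment",
    "transition_distance",
    "model_recovery",
    "parameter_recovery",
    "acf_decisions",
    "acf_by_session",
    "run_lengths",
    "recapitulation_glms",
]


# ---------------------------------------------------------------------------
# decoding validation (trialwise accuracy and transition distances)


@dataclass
class DecodingReport:
    session_accuracy: np.ndarray  # % correct per simulated session
    dataset_accuracy: np.ndarray  # % correct per dataset
    distances: np.ndarray  # signed decoded-minus-true trial distances (matched)
    n_decoded_transitions: int
    n_missed: int  # decoded transitions with no same-direction match within +-10

    @property
    def mean_accuracy(self) -> float:
        return float(self.dataset_accuracy.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.dataset_accuracy.std(ddof=1))

    @property
    def mean_distance(self) -> float:
        return float(self.distances.mean())

    @property
    def frac_within_3(self) -> float:
        """Fraction of all decoded transitions within +-3 trials of a true
        same-direction transition."""
        within = int((np.abs(self.distances) <= 3).sum())
        return within / self.n_decoded_transitions

    def summary(self) -> dict:
        return {
            "mean_accuracy_pct": self.mean_accuracy,
            "sd_accuracy_pct": self.sd_accuracy,
            "frac_within_3": self.frac_within_3,
            "mean_distance_trials": self.mean_distance,
            "n_decoded_transitions": self.n_decoded_transitions,
            "n_missed": self.n_missed,
        }


def transition_distance(decoded, truth, max_dist: int = 10):
    """Match each decoded transition to the nearest true transition of the
    same direction (ties to the earlier one); signed distance is decoded
    minus true.  Decoded transitions with no match within ``max_dist``
    trials are counted as misses.

    Returns ``(distances, n_decoded, n_missed)``.  With no true transitions
    the distance array is empty and every decoded transition is a miss.
    """
    if isinstance(decoded, np.ndarray):
        decoded = decode_transitions(decoded)
    if isinstance(truth, np.ndarray):
        truth = decode_transitions(truth)
    if len(decoded.states) != len(truth.states):
        raise ValueError("decoded and true paths must have the same length")
    dists = []
    n_miss = 0
    for t, dirn in zip(decoded.transitions, decoded.directions):
        cand = np.array(
            [tt for tt, dd in zip(truth.transitions, truth.directions) if dd == dirn]
        )
        if cand.size == 0:
            n_miss += 1
            continue
        diffs = t - cand  # decoded minus true
        d = diffs[np.argmin(np.abs(diffs))]
        if abs(d) > max_dist:
            n_miss += 1
        else:
            dists.append(int(d))
    return np.array(dists, dtype=int), len(decoded.transitions), n_miss


def decoding_experiment(
    agent: task.AgentParams | None = None,
    n_datasets: int = 10,
    n_sessions: int = 16,
    seed: int = 0,
    decode_with: str = "refit",
    n_restarts: int = 5,
    **fit_kw,
) -> DecodingReport:
    """Simulate ``n_datasets`` datasets of ``n_sessions`` sessions from the
    (default reference) two-state agent, decode each with a model re-fitted
    to that dataset (``decode_with='true'`` uses the generating parameters
    as an oracle ceiling), and score decoding against the known states."""
    if agent is None:
        agent = task.default_agent()
    if agent.n_states != 2:
        raise ValueError("decoding experiment expects a two-state agent")
    root = np.random.SeedSequence(seed)
    sess_acc, ds_acc, dists = [], [], []
    n_dec = n_miss = 0
    for d, child in enumerate(root.spawn(n_datasets)):
        ds_seed = int(child.generate_state(1)[0] % (2**31))
        tab = task.generate_dataset(1, n_sessions, {"none": agent}, seed=ds_seed)
        X, y, sess = build_design(tab)
        if decode_with == "refit":
            model = GLMHMM(n_states=2, n_restarts=n_restarts,
                           random_state=ds_seed, **fit_kw).fit(X, y, sess)
            z = model.decode(X, y, sess)
        elif decode_with == "true":
            model = GLMHMM(n_states=2)
            model.weights_ = agent.weights
            model.transmat_ = agent.transmat
            model.startprob_ = agent.startprob
            model.n_params_ = 0
            z = model.decode(X, y, sess)
        else:
            raise ValueError("decode_with must be 'refit' or 'true'")
        true = tab["true_state"].to_numpy()
        ds_acc.append(100.0 * (z == true).mean())
        for sid in pd.unique(sess):
            m = sess == sid
            sess_acc.append(100.0 * (z[m] == true[m]).mean())
            d_s, n_s, miss_s = transition_distance(z[m], true[m])
            dists.append(d_s)
            n_dec += n_s
            n_miss += miss_s
    return DecodingReport(
        session_accuracy=np.array(sess_acc),
        dataset_accuracy=np.array(ds_acc),
        distances=np.concatenate(dists) if dists else np.array([], int),
        n_decoded_transitions=n_dec,
        n_missed=n_miss,
    )


# ---------------------------------------------------------------------------
# model and parameter recovery


def model_recovery(
    seed: int = 0,
    n_datasets: int = 10,
    n_sessions: int = 16,
    k_list=(1, 2, 3),
    n_folds: int = 5,
    n_restarts: int = 2,
    max_iter: int = 75,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Generate datasets from one-state and two-state exemplar agents, run
    cross-validated state-number selection on each, and tabulate the
    selected K (generator, dataset, selected_k)."""
    generators = {
        "two_state": task.default_agent(),
        "one_state": task.binomial_glm_agent(),
    }
    rows = []
    for gi, (gen_name, agent) in enumerate(generators.items()):
        root = np.random.SeedSequence([seed, gi])
        for d, child in enumerate(root.spawn(n_datasets)):
            ds_seed = int(child.generate_state(1)[0] % (2**31))
            tab = task.generate_dataset(1, n_sessions, {"none": agent},
                                        seed=ds_seed)
            X, y, sess = build_design(tab)
            cv = cross_validate_states(
                X, y, sess, k_list=k_list, n_folds=n_folds, seed=ds_seed,
                n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            )
            rows.append({"generator": gen_name, "dataset": d,
                         "selected_k": select_k(cv)})
    return pd.DataFrame(rows)


def parameter_recovery(
    seed: int = 0,
    n_datasets: int = 10,
    n_sessions: int = 16,
    n_restarts: int = 5,
) -> pd.DataFrame:
    """Fit the two-state model to datasets simulated from the reference
    agent and report bias and self-transition estimation errors."""
    agent = task.default_agent()
    root = np.random.SeedSequence(seed)
    rows = []
    for d, child in enumerate(root.spawn(n_datasets)):
        ds_seed = int(child.generate_state(1)[0] % (2**31))
        tab = task.generate_dataset(1, n_sessions, {"none": agent}, seed=ds_seed)
        X, y, sess = build_design(tab)
        m = GLMHMM(n_states=2, n_restarts=n_restarts, random_state=ds_seed).fit(X, y, sess)
        rows.append(
            {
                "dataset": d,
                "bias_high_err": m.weights_[0, 0] - agent.weights[0, 0],
                "bias_low_err": m.weights_[1, 0] - agent.weights[1, 0],
                "self_trans_high_err": m.transmat_[0, 0] - agent.transmat[0, 0],
                "self_trans_low_err": m.transmat_[1, 1] - agent.transmat[1, 1],
                "ev_weight_err": m.weights_[0, 1] - agent.weights[0, 1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavioral recapitulation (ACF, run lengths, regression battery)


def acf_decisions(y, max_lag: int = 10) -> np.ndarray:
    """Sample autocorrelation of a binary decision series at lags 1..max_lag
    (Pearson correlation between the series and its lagged copy).  NaN where
    the overlapping segments have zero variance."""
    y = np.asarray(y, dtype=float)
    out = np.full(max_lag, np.nan)
    for k in range(1, max_lag + 1):
        if k >= len(y):
            break
        a, b = y[k:], y[:-k]
        if a.std() == 0 or b.std() == 0:
            continue
        out[k - 1] = np.corrcoef(a, b)[0, 1]
    return out


def acf_by_session(table: pd.DataFrame, max_lag: int = 10) -> np.ndarray:
    """Session-wise decision ACF averaged over sessions (NaN-aware)."""
    curves = [
        acf_decisions(g["decision"].to_numpy(), max_lag)
        for _, g in table.groupby("session_id", sort=False)
    ]
    return np.nanmean(np.vstack(curves), axis=0)


def run_lengths(y) -> np.ndarray:
    """Lengths of maximal runs of repeated decisions; they partition T."""
    y = np.asarray(y)
    if y.size == 0:
        return np.array([], dtype=int)
    change = np.flatnonzero(np.diff(y) != 0)
    edges = np.concatenate([[-1], change, [y.size - 1]])
    return np.diff(edges).astype(int)


def run_length_counts(table: pd.DataFrame) -> pd.Series:
    """Pooled run-length histogram over sessions."""
    runs = np.concatenate(
        [
            run_lengths(g["decision"].to_numpy())
            for _, g in table.groupby("session_id", sort=False)
        ]
    )
    return pd.Series(runs).value_counts().sort_index()


@dataclass
class RecapReport:
    acf_hmm: np.ndarray
    acf_glm: np.ndarray
    runs_hmm: pd.Series
    runs_glm: pd.Series
    glm_coefs: pd.DataFrame  # generator x model x term -> estimate, se, p


def recapitulation_glms(
    seed: int = 0,
    n_subjects: int = 4,
    n_sessions: int = 8,
    max_lag: int = 10,
) -> RecapReport:
    """Simulate matched datasets from the two-state agent and the stateless
    binomial agent and compare decision ACF, run lengths, and the richness /
    behavioral-history regression coefficients between them."""
    tabs = {
        "glmhmm": task.generate_dataset(n_subjects, n_sessions, seed=seed),
        "binomial": task.generate_dataset(
            n_subjects, n_sessions,
            {"none": task.binomial_glm_agent()}, seed=seed + 1,
        ),
    }
    from .features import add_derived_regressors

    rows = []
    for gen, tab in tabs.items():
        der = add_derived_regressors(tab)
        for model in ("GLM1.2", "GLM1.3"):
            fit = fit_model(get_spec(model), der, method="fixed")
            for term in ("richness", "behavioral_history"):
                hit = fit.params[fit.params["term"].str.contains(term)]
                for _, r in hit.iterrows():
                    rows.append(
                        {"generator": gen, "model": model, "term": r["term"],
                         "estimate": r["estimate"], "se": r["se"], "p": r["p"]}
                    )
    return RecapReport(
        acf_hmm=acf_by_session(tabs["glmhmm"], max_lag),
        acf_glm=acf_by_session(tabs["binomial"], max_lag),
        runs_hmm=run_length_counts(tabs["glmhmm"]),
        runs_glm=run_length_counts(tabs["binomial"]),
        glm_coefs=pd.DataFrame(rows),
    )
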