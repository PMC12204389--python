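"""Binary-choice GLM-HMM: inference, EM fitting, decoding, model selection.

The model: on trial t the animal occupies a latent motivation state
z_t in {1..K} following a stationary Markov chain (transition matrix A,
per-session initial distribution tau), and the pursue/reject decision is

    p(y_t = pursue | z_t = k, x_t) = logistic(w_k . x_t)

with design x_t = [bias, z-scored EV, richness cue, stochasticity cue].
By default only the bias weight differs between states (a share mask
constrains the remaining columns equal across states), so the states
capture shifts in the intrinsic propensity to pursue rewards.

Fitting is maximum marginal likelihood via EM with seeded random restarts:
the E-step is a scaled forward-backward pass run jointly over sessions
(padded to a common length), the M-step re-estimates A and tau from
expected counts (with a small smoothing pseudocount) and maximizes the
expected complete-data log-likelihood over the masked weights with
L-BFGS (the weight subproblem is convex).  Decoding is exact Viterbi.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

__all__ = [
    "GLMHMM",
    "GLMHMMParams",
    "StatePath",
    "build_design",
    "forward_loglik",
    "state_posteriors",
    "viterbi_path",
    "simulate_from",
    "decode_transitions",
    "label_states",
    "cross_validate_states",
    "select_k",
    "DESIGN_COLUMNS",
]

DESIGN_COLUMNS = ["bias", "z_ev", "richness_cue", "stochasticity_cue"]

_EPS = 1e-300


# ---------------------------------------------------------------------------
# parameter container


@dataclass
class GLMHMMParams:
    """Serializable parameter set: weights (K x M, row-major), transition
    matrix, initial-state distribution, and the share mask used in fitting."""

    weights: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    share_mask: str = "bias_only"
    state_labels: tuple = ("high", "low")

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        _validate(self.weights, self.transmat, self.startprob)

    @property
    def n_states(self) -> int:
        return self.weights.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "transmat": self.transmat.tolist(),
                "startprob": self.startprob.tolist(),
                "share_mask": self.share_mask,
                "state_labels": list(self.state_labels),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GLMHMMParams":
        d = json.loads(text)
        return cls(
            np.array(d["weights"]),
            np.array(d["transmat"]),
            np.array(d["startprob"]),
            d.get("share_mask", "bias_only"),
            tuple(d.get("state_labels", ("high", "low"))),
        )


def _validate(W, A, tau):
    K = W.shape[0]
    if K < 1:
        raise ValueError("need at least one state")
    if A.shape != (K, K):
        raise ValueError(f"transmat shape {A.shape} does not match K={K}")
    if np.any(A < -1e-12) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    if tau.shape != (K,) or not np.isclose(tau.sum(), 1.0, atol=1e-8):
        raise ValueError("startprob must be a length-K distribution")


# ---------------------------------------------------------------------------
# exact single-session inference (reference implementations)


def _log_emissions(W, X, y):
    """(T, K) log p(y_t | z_t=k)."""
    logits = X @ W.T  # (T, K)
    sign = (1.0 - 2.0 * y)[:, None]  # +1 for y=0, -1 for y=1
    return -np.logaddexp(0.0, sign * logits)


def forward_loglik(params, X, y) -> float:
    """Session log marginal likelihood log p(y | x, params) via the forward
    recursion in log space."""
    W, A, tau = params.weights, params.transmat, params.startprob
    _validate(W, A, tau)
    logB = _log_emissions(W, np.asarray(X, float), np.asarray(y, float))
    with np.errstate(divide="ignore"):
        logA = np.log(A)
        alpha = np.log(tau) + logB[0]
    for t in range(1, len(y)):
        alpha = logsumexp(alpha[:, None] + logA, axis=0) + logB[t]
    return float(logsumexp(alpha))


def state_posteriors(params, X, y) -> np.ndarray:
    """(T, K) marginal posteriors p(z_t = k | y, x) via forward-backward."""
    W, A, tau = params.weights, params.transmat, params.startprob
    _validate(W, A, tau)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    T, K = len(y), W.shape[0]
    B = np.exp(_log_emissions(W, X, y))
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = tau * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    return gamma / gamma.sum(axis=1, keepdims=True)


def viterbi_path(params, X, y) -> np.ndarray:
    """Exact MAP state path; ties broken toward the lower state index."""
    W, A, tau = params.weights, params.transmat, params.startprob
    _validate(W, A, tau)
    logB = _log_emissions(W, np.asarray(X, float), np.asarray(y, float))
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(A)
        delta = np.log(tau) + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    z = np.empty(T, dtype=int)
    z[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        z[t - 1] = back[t, z[t]]
    return z


def simulate_from(params, X, rng):
    """Sample (y, z) from the generative model on a provided design."""
    rng = np.random.default_rng(rng)
    W, A, tau = params.weights, params.transmat, params.startprob
    _validate(W, A, tau)
    X = np.asarray(X, float)
    T, K = X.shape[0], W.shape[0]
    z = np.empty(T, dtype=int)
    z[0] = rng.choice(K, p=tau)
    for t in range(1, T):
        z[t] = rng.choice(K, p=A[z[t - 1]])
    p = expit(np.einsum("tm,tm->t", X, W[z]))
    y = (rng.random(T) < p).astype(int)
    return y, z


# ---------------------------------------------------------------------------
# design matrices


def build_design(trial_table: pd.DataFrame):
    """Build per-session design matrices from a trial table.

    Returns ``(X, y, sessions)``: stacked T x 4 designs with columns
    [bias=1, z-scored EV, richness cue, stochasticity cue], the 0/1
    decisions, and the session id of every row.  EV is z-scored within
    session (sessions are the modelling unit).
    """
    required = ["session_id", "reward_magnitude", "reward_probability",
                "decision", "richness_cue", "stochasticity_cue"]
    missing = [c for c in required if c not in trial_table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    ev = (trial_table["reward_magnitude"] * trial_table["reward_probability"]).astype(float)
    g = ev.groupby(trial_table["session_id"])
    sd = g.transform("std").replace(0.0, 1.0)
    zev = (ev - g.transform("mean")) / sd
    X = np.column_stack(
        [
            np.ones(len(trial_table)),
            zev.to_numpy(),
            trial_table["richness_cue"].to_numpy(dtype=float),
            trial_table["stochasticity_cue"].to_numpy(dtype=float),
        ]
    )
    y = trial_table["decision"].to_numpy(dtype=int)
    return X, y, trial_table["session_id"].to_numpy()


def _split_sessions(X, y, sessions):
    """Split stacked arrays into per-session lists, preserving order."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if sessions is None:
        return [X], [np.asarray(y, int)], np.array([0])
    sessions = np.asarray(sessions)
    ids = pd.unique(sessions)
    Xs, ys = [], []
    for sid in ids:
        m = sessions == sid
        Xs.append(X[m])
        ys.append(np.asarray(y[m], int))
    return Xs, ys, ids


# ---------------------------------------------------------------------------
# batched (padded) forward-backward for EM


def _pad(Xs, ys):
    S = len(Xs)
    lengths = np.array([len(y) for y in ys])
    Tmax, M = lengths.max(), Xs[0].shape[1]
    Xp = np.zeros((S, Tmax, M))
    yp = np.zeros((S, Tmax))
    for i, (X, y) in enumerate(zip(Xs, ys)):
        Xp[i, : len(y)] = X
        yp[i, : len(y)] = y
    return Xp, yp, lengths


def _batch_emissions(W, Xp, yp, lengths):
    """(S, Tmax, K) emission probabilities; 1.0 on padded steps."""
    logits = np.einsum("stm,km->stk", Xp, W)
    sign = (1.0 - 2.0 * yp)[..., None]
    B = expit(-sign * logits)  # p(y_t | k)
    steps = np.arange(Xp.shape[1])
    B[steps[None, :] >= lengths[:, None]] = 1.0
    return np.clip(B, _EPS, None)


def _batch_forward_backward(W, A, tau, Xp, yp, lengths):
    """Scaled forward-backward over padded sessions.

    Returns (loglik_per_session, gamma, xi_sum) where gamma is
    (S, Tmax, K) posteriors (zero on padding) and xi_sum is the (K, K)
    expected transition-count matrix summed over sessions and time.
    """
    S, Tmax, _ = Xp.shape
    K = W.shape[0]
    B = _batch_emissions(W, Xp, yp, lengths)
    alpha = np.empty((S, Tmax, K))
    c = np.ones((S, Tmax))
    active = np.arange(Tmax)[None, :] < lengths[:, None]

    a = tau[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, Tmax):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        ct = a.sum(axis=1)
        act = active[:, t]
        c[:, t] = np.where(act, ct, 1.0)
        alpha[:, t] = np.where(act[:, None], a / np.maximum(ct, _EPS)[:, None],
                               alpha[:, t - 1])
    loglik = np.where(active, np.log(c), 0.0).sum(axis=1)

    beta = np.empty((S, Tmax, K))
    beta[:, -1] = 1.0
    # beta at each session's last real step is 1; padding carries it back
    xi_sum = np.zeros((K, K))
    for t in range(Tmax - 2, -1, -1):
        step = (B[:, t + 1] * beta[:, t + 1]) @ A.T / c[:, t + 1, None]
        act = active[:, t + 1]
        beta[:, t] = np.where(act[:, None], step, beta[:, t + 1])
        # expected transitions t -> t+1 where that step is real
        w = np.where(act, 1.0 / c[:, t + 1], 0.0)
        xi_sum += np.einsum(
            "si,ij,sj,s->ij", alpha[:, t], A,
            B[:, t + 1] * beta[:, t + 1], w,
        )
    gamma = alpha * beta
    gamma = np.where(active[..., None], gamma, 0.0)
    norm = gamma.sum(axis=2, keepdims=True)
    gamma = gamma / np.maximum(norm, _EPS)
    return loglik, gamma, xi_sum


# ---------------------------------------------------------------------------
# weight parameterization under the share mask


class _WeightMap:
    """Maps between the K x M weight matrix and the free vector theta under
    a share mask ('bias_only': column 0 state-specific, rest shared;
    'all': every column state-specific)."""

    def __init__(self, K, M, share_mask):
        if share_mask not in ("bias_only", "all"):
            raise ValueError(f"unknown share_mask {share_mask!r}")
        self.K, self.M, self.share_mask = K, M, share_mask
        self.specific_cols = list(range(M)) if share_mask == "all" else [0]
        self.shared_cols = [m for m in range(M) if m not in self.specific_cols]
        self.n_free = K * len(self.specific_cols) + len(self.shared_cols)

    def to_matrix(self, theta):
        W = np.empty((self.K, self.M))
        ns = len(self.specific_cols)
        W[:, self.specific_cols] = theta[: self.K * ns].reshape(self.K, ns)
        W[:, self.shared_cols] = theta[self.K * ns:][None, :]
        return W

    def to_vector(self, W):
        ns = len(self.specific_cols)
        return np.concatenate(
            [W[:, self.specific_cols].ravel(), W[0, self.shared_cols]]
        )

    def fold_grad(self, G):
        """Collapse a K x M gradient to the free vector (summing shared cols)."""
        ns = len(self.specific_cols)
        return np.concatenate(
            [G[:, self.specific_cols].ravel(), G[:, self.shared_cols].sum(axis=0)]
        )


def _optimize_weights(wmap, theta0, Xall, yall, gamma_flat, l2=1e-6, maxiter=200):
    """Maximize the expected complete-data log-likelihood over weights
    (convex weighted logistic problem)."""
    sign = 1.0 - 2.0 * yall  # (N,)

    def negQ(theta):
        W = wmap.to_matrix(theta)
        logits = Xall @ W.T  # (N, K)
        ll = -np.logaddexp(0.0, sign[:, None] * logits)
        val = -(gamma_flat * ll).sum() + 0.5 * l2 * (theta @ theta)
        P = expit(logits)
        R = gamma_flat * (yall[:, None] - P)  # (N, K)
        G = -(R.T @ Xall)  # (K, M) gradient of negQ
        return val, wmap.fold_grad(G) + l2 * theta

    res = minimize(negQ, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    return res.x


# ---------------------------------------------------------------------------
# decoded-path container


@dataclass
class StatePath:
    """Decoded state sequence for one session, with transitions and the
    seven-trial transition periods used in downstream analyses."""

    states: np.ndarray  # decoded state indices (0 = high after labelling)
    motivation: np.ndarray  # 1 = high-motivation, 0 = low
    transitions: np.ndarray = field(default=None)  # trial index of first trial in new state
    directions: list = field(default=None)  # 'high_to_low' / 'low_to_high'
    periods: list = field(default=None)  # (start, stop) inclusive, truncated

    def __post_init__(self):
        if self.transitions is None:
            t = np.flatnonzero(np.diff(self.states) != 0) + 1
            self.transitions = t
            self.directions = [
                "high_to_low" if self.motivation[i] == 0 else "low_to_high"
                for i in t
            ]
            self.periods = [
                _window(i, len(self.states), (-3, 3)) for i in t
            ]

    def period_mask(self, offsets=(-3, 3)) -> np.ndarray:
        """Boolean per-trial mask of transition periods for a given window
        placement (offsets relative to the transition trial)."""
        mask = np.zeros(len(self.states), dtype=bool)
        for i in self.transitions:
            lo, hi = _window(i, len(self.states), offsets)
            mask[lo: hi + 1] = True
        return mask


def _window(center, T, offsets):
    return max(0, center + offsets[0]), min(T - 1, center + offsets[1])


def decode_transitions(states, high_state: int = 0) -> StatePath:
    """Extract transitions, directions, and truncated seven-trial periods
    from a decoded state sequence (state ``high_state`` = high motivation)."""
    states = np.asarray(states, int)
    motivation = (states == high_state).astype(int)
    return StatePath(states=states, motivation=motivation)


def label_states(params) -> dict:
    """Order states by pursue bias: the state with the larger bias weight is
    labelled 'high'.  Returns the ordering and a tie flag."""
    bias = params.weights[:, 0]
    order = np.argsort(-bias, kind="stable")
    tie = bool(np.isclose(bias.max(), bias.min())) and len(bias) > 1
    labels = ["high", "low"] if len(bias) == 2 else [f"state{i}" for i in order]
    return {"order": order, "tie": tie, "labels": labels}


# ---------------------------------------------------------------------------
# the estimator


class GLMHMM(BaseEstimator):
    """Binary GLM-HMM with state-specific bias, fit by EM.

    Parameters
    ----------
    n_states : number of latent states K.
    share_mask : 'bias_only' (default) lets only the bias weight vary by
        state; 'all' makes every weight state-specific.
    n_restarts : seeded random EM restarts; the best final likelihood wins.
    max_iter, tol : EM stopping rule (absolute log-likelihood change).
    transition_pseudocount : Dirichlet-style smoothing added to expected
        transition and initial-state counts (avoids zero rows on short data).
    random_state : seed for restarts.

    Fitted attributes
    -----------------
    weights_ : (K, M) weight matrix, states ordered by descending bias
        (state 0 = high-motivation).
    transmat_, startprob_ : transition matrix and initial distribution.
    loglik_ : total training log marginal likelihood.
    history_ : per-iteration log-likelihood trace of the winning restart.
    converged_ : whether the winning restart met ``tol``.
    n_params_ : number of free parameters (for AIC).
    """

    def __init__(self, n_states=2, share_mask="bias_only", n_restarts=10,
                 max_iter=200, tol=1e-6, transition_pseudocount=1e-2,
                 random_state=None):
        self.n_states = n_states
        self.share_mask = share_mask
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.transition_pseudocount = transition_pseudocount
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, sessions=None):
        Xs, ys, ids = _split_sessions(X, y, sessions)
        if len(ys) == 0 or sum(len(v) for v in ys) == 0:
            raise ValueError("no sessions to fit")
        yall = np.concatenate(ys)
        if yall.min() == yall.max():
            warnings.warn("all responses identical; fit is degenerate",
                          UserWarning, stacklevel=2)
        K, M = int(self.n_states), Xs[0].shape[1]
        wmap = _WeightMap(K, M, self.share_mask)
        Xp, yp, lengths = _pad(Xs, ys)
        Xall = np.concatenate(Xs)
        rng = np.random.default_rng(self.random_state)

        # pooled logistic fit seeds the shared weights
        pooled = _optimize_weights(
            _WeightMap(1, M, "all"), np.zeros(M), Xall, yall,
            np.ones((len(yall), 1)),
        )

        best = None
        self.restart_logliks_ = []
        for r in range(int(self.n_restarts)):
            W0 = np.tile(pooled, (K, 1))
            if K > 1:
                offsets = np.sort(rng.normal(0.0, 1.3, size=K))[::-1]
                W0[:, 0] = pooled[0] + offsets
                if self.share_mask == "all":
                    W0[:, 1:] += rng.normal(0.0, 0.2, size=(K, M - 1))
            diag = rng.uniform(0.80, 0.98)
            A0 = np.full((K, K), (1 - diag) / max(K - 1, 1))
            np.fill_diagonal(A0, diag if K > 1 else 1.0)
            tau0 = rng.dirichlet(np.full(K, 5.0)) if K > 1 else np.ones(1)
            out = self._em(wmap, W0, A0, tau0, Xp, yp, lengths, Xall, yall)
            self.restart_logliks_.append(out["loglik"])
            if best is None or out["loglik"] > best["loglik"]:
                best = out

        order = np.argsort(-best["W"][:, 0], kind="stable")
        self.weights_ = best["W"][order]
        self.transmat_ = best["A"][np.ix_(order, order)]
        self.startprob_ = best["tau"][order]
        self.loglik_ = best["loglik"]
        self.history_ = best["history"]
        self.converged_ = best["converged"]
        if not best["converged"]:
            warnings.warn("EM did not converge within max_iter",
                          UserWarning, stacklevel=2)
        self.session_ids_ = ids
        self.n_features_in_ = M
        self.n_params_ = wmap.n_free + K * (K - 1) + (K - 1)
        return self

    def _em(self, wmap, W, A, tau, Xp, yp, lengths, Xall, yall):
        pc = self.transition_pseudocount
        K = wmap.K
        history = []
        prev = -np.inf
        converged = False
        theta = wmap.to_vector(W)
        active = np.arange(Xp.shape[1])[None, :] < lengths[:, None]
        for it in range(int(self.max_iter)):
            ll_s, gamma, xi = _batch_forward_backward(W, A, tau, Xp, yp, lengths)
            ll = float(ll_s.sum())
            history.append(ll)
            if ll - prev < self.tol and it > 0:
                converged = True
                break
            prev = ll
            if K > 1:
                A = xi + pc
                A /= A.sum(axis=1, keepdims=True)
                tau = gamma[:, 0].sum(axis=0) + pc
                tau /= tau.sum()
            gamma_flat = gamma[active]  # (N, K) in stacking order
            theta = _optimize_weights(wmap, theta, Xall, yall, gamma_flat)
            W = wmap.to_matrix(theta)
        return {"W": W, "A": A, "tau": tau, "loglik": history[-1],
                "history": np.array(history), "converged": converged}

    # -- inference ---------------------------------------------------------

    def _params(self) -> GLMHMMParams:
        return GLMHMMParams(self.weights_, self.transmat_, self.startprob_,
                            self.share_mask)

    def session_loglik(self, X, y, sessions=None) -> np.ndarray:
        Xs, ys, _ = _split_sessions(X, y, sessions)
        p = self._params()
        return np.array([forward_loglik(p, Xi, yi) for Xi, yi in zip(Xs, ys)])

    def score(self, X, y, sessions=None) -> float:
        """Total log marginal likelihood of the data."""
        return float(self.session_loglik(X, y, sessions).sum())

    def aic(self, X, y, sessions=None) -> np.ndarray:
        """Session-wise AIC, 2k - 2 LL_s, with k the total free-parameter
        count of the jointly fitted model."""
        return 2.0 * self.n_params_ - 2.0 * self.session_loglik(X, y, sessions)

    def decode(self, X, y, sessions=None) -> np.ndarray:
        """Viterbi MAP state path per session, stacked in row order
        (state 0 = high-motivation)."""
        Xs, ys, _ = _split_sessions(X, y, sessions)
        p = self._params()
        return np.concatenate([viterbi_path(p, Xi, yi) for Xi, yi in zip(Xs, ys)])

    def predict(self, X, y, sessions=None) -> np.ndarray:
        return self.decode(X, y, sessions)

    def predict_proba(self, X, y, sessions=None) -> np.ndarray:
        """Stacked (N, K) forward-backward state posteriors."""
        Xs, ys, _ = _split_sessions(X, y, sessions)
        p = self._params()
        return np.vstack([state_posteriors(p, Xi, yi) for Xi, yi in zip(Xs, ys)])

    def sample(self, X, rng=None):
        """Sample (y, z) trajectories from the fitted model on a design."""
        return simulate_from(self._params(), X, rng)


# ---------------------------------------------------------------------------
# model selection


def cross_validate_states(
    X, y, sessions, k_list=(1, 2, 3, 4, 5), n_folds=5, seed=0, **fit_kw
) -> pd.DataFrame:
    """Session-level K-fold cross-validation over the number of states.

    Models are fit to the training sessions and scored by total held-out
    log-likelihood; fold sizes differ by at most one session.  Returns a
    tidy table (k, fold, heldout_ll, n_test_sessions).
    """
    Xs, ys, ids = _split_sessions(X, y, sessions)
    S = len(ids)
    if S < n_folds:
        raise ValueError(f"need at least {n_folds} sessions, got {S}")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for k in k_list:
        for fold, (tr, te) in enumerate(kf.split(np.arange(S))):
            Xtr = np.concatenate([Xs[i] for i in tr])
            ytr = np.concatenate([ys[i] for i in tr])
            str_ = np.concatenate([np.full(len(ys[i]), i) for i in tr])
            kw = dict(fit_kw)
            # every fold fit is deterministically seeded from the CV seed
            kw.setdefault("random_state",
                          (1000003 * seed + 101 * k + fold) % (2**31))
            model = GLMHMM(n_states=k, **kw).fit(Xtr, ytr, str_)
            ll = sum(
                forward_loglik(model._params(), Xs[i], ys[i]) for i in te
            )
            rows.append({"k": k, "fold": fold, "heldout_ll": ll,
                         "n_test_sessions": len(te)})
    return pd.DataFrame(rows)


def select_k(cv_table: pd.DataFrame, rule: str = "one_se") -> int:
    """Select the number of states from a cross-validation table.

    ``rule='argmax'`` takes the K with the greatest mean held-out
    log-likelihood.  The default ``'one_se'`` applies a parsimony rule for
    nested models: the smallest K whose held-out log-likelihood is within
    one standard error of the best, where the SE is computed on the
    *paired* fold-wise differences against the best K (fold log-likelihoods
    are strongly correlated across K, so the paired SE is the relevant
    noise scale).  A larger K must beat a smaller one by more than fitting
    noise to be chosen.
    """
    means = cv_table.groupby("k")["heldout_ll"].mean()
    k_best = int(means.idxmax())
    if rule == "argmax":
        return k_best
    if rule != "one_se":
        raise ValueError(f"unknown selection rule {rule!r}")
    piv = cv_table.pivot_table(index="fold", columns="k", values="heldout_ll")
    for k in sorted(means.index):
        if k == k_best:
            return k_best
        diff = piv[k_best] - piv[k]  # per-fold deficit of the smaller model
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        if diff.mean() <= se:
            return int(k)
    return k_best
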