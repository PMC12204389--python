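import itertools

import numpy as np
import pytest
from scipy.special import expit

from foragehmm import task
from foragehmm.features import add_derived_regressors


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the package's recursions)


def brute_force_inference(params, X, y):
    """Enumerate all K^T state paths: returns (loglik, posteriors, map_path).

    MAP ties resolve to the lexicographically smallest path, matching the
    lower-state-index tie-break of the Viterbi implementation.
    """
    W, A, tau = params.weights, params.transmat, params.startprob
    T, K = len(y), W.shape[0]
    y = np.asarray(y)
    best_lp, best_z = -np.inf, None
    total = 0.0
    post = np.zeros((T, K))
    for z in itertools.product(range(K), repeat=T):
        lp = np.log(tau[z[0]])
        for t in range(1, T):
            lp += np.log(A[z[t - 1], z[t]])
        p = expit(np.einsum("tm,tm->t", X, W[list(z)]))
        lp += float(np.sum(np.where(y == 1, np.log(p), np.log(1 - p))))
        w = np.exp(lp)
        total += w
        for t in range(T):
            post[t, z[t]] += w
        if lp > best_lp + 1e-12:
            best_lp, best_z = lp, z
    return np.log(total), post / total, np.array(best_z)


def brute_force_trailing(values, w, fn):
    """Reference trailing-window statistic: fn over the w values preceding
    each position, NaN when unavailable."""
    values = np.asarray(values, float)
    out = np.full(len(values), np.nan)
    for t in range(len(values)):
        if t >= w:
            out[t] = fn(values[t - w: t])
    return out


# ---------------------------------------------------------------------------
# shared (expensive) data fixtures


@pytest.fixture(scope="session")
def reference_dataset():
    """Default-scale synthetic dataset: 4 subjects x 16 sessions from the
    reference two-state agent, with derived regressors."""
    table = task.generate_dataset(4, 16, seed=7)
    return add_derived_regressors(table)


@pytest.fixture(scope="session")
def single_animal_table():
    """One simulated animal (16 sessions) from the reference agent."""
    return task.generate_dataset(1, 16, seed=42)


@pytest.fixture(scope="session")
def decoding_report():
    """The full-scale decoding-validation experiment (10 datasets x 16
    sessions, refit-then-decode)."""
    from foragehmm.model_validation import decoding_experiment

    return decoding_experiment(seed=11)
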