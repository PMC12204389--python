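"""Synthetic reward-pursuit task and generative GLM-HMM agent.

The task presents sequential reward opportunities that vary in magnitude
(1-3 juice drops) and probability (0.05-grid).  Sessions comprise four
blocks of 40-50 trials, one per reward environment: the cross of richness
(rich: mean probability 0.80, poor: 0.55) and stochasticity (predictable:
Gaussian sd 0.05, stochastic: uniform over a 0.40-wide grid, sd ~0.129).
Block order alternates richness so the animal never faces two poor (or two
rich) environments in a row.

Behavior is generated by a two-state GLM-HMM agent: a latent motivation
state evolves as a Markov chain, and on each trial the pursue/reject
decision is Bernoulli with logit given by a state-specific bias plus
shared weights on the (z-scored) expected value of the offer and the
binary environment cues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BlockSpec",
    "SessionDesign",
    "AgentParams",
    "MU_RICH",
    "MU_POOR",
    "SIGMA_PREDICTABLE",
    "STOCHASTIC_RANGE",
    "PROB_GRID",
    "make_block_spec",
    "draw_reward_probability",
    "make_session",
    "simulate_behavior",
    "generate_dataset",
    "default_agent",
    "binomial_glm_agent",
    "perturb_agent",
]

MU_RICH = 0.80
MU_POOR = 0.55
SIGMA_PREDICTABLE = 0.05
STOCHASTIC_RANGE = 0.40  # full width of the uniform support
PROB_GRID = 0.05

RICHNESS_LABELS = ("rich", "poor")
STOCHASTICITY_LABELS = ("stochastic", "predictable")
CONDITION_LABELS = ("sham", "DRN", "VTA", "STS")

#: column order of the TrialTable written by :func:`simulate_behavior`
TRIAL_COLUMNS = [
    "session_id",
    "subject_id",
    "block_index",
    "trial_number",
    "richness_label",
    "stochasticity_label",
    "richness_cue",
    "stochasticity_cue",
    "reward_magnitude",
    "reward_probability",
    "decision",
    "reward_outcome",
    "true_state",
    "rt",
    "condition",
    "onset_s",
]


@dataclass(frozen=True)
class BlockSpec:
    """Reward-probability generator for one block (environment)."""

    richness_label: str
    stochasticity_label: str
    mu: float
    sigma_or_range: float
    n_trials: int

    def __post_init__(self):
        if not (40 <= self.n_trials <= 50):
            raise ValueError(f"n_trials must lie in [40, 50], got {self.n_trials}")


@dataclass
class SessionDesign:
    """Fully specified session: block sequence plus per-trial task variables."""

    session_id: str
    subject_id: str
    blocks: list  # of BlockSpec
    block_index: np.ndarray  # per trial, 0..3
    reward_magnitude: np.ndarray
    reward_probability: np.ndarray
    richness_cue: np.ndarray  # 1 = rich block
    stochasticity_cue: np.ndarray  # 1 = stochastic block
    go_cue_delay: np.ndarray
    action_outcome_delay: np.ndarray
    iti: np.ndarray
    onset_s: np.ndarray  # stimulus-onset time of each trial, seconds

    @property
    def n_trials(self) -> int:
        return int(self.reward_magnitude.size)


@dataclass
class AgentParams:
    """Generative agent: GLM-HMM parameters plus an optional condition label.

    ``weights`` is K x M over the design columns
    [bias, z-scored EV, richness cue, stochasticity cue]; ``transmat`` is the
    K x K state transition matrix and ``startprob`` the initial-state
    distribution.  ``condition`` tags the rows the agent generates (e.g. a
    simulated ultrasound-stimulation condition); perturbations are applied
    with :func:`perturb_agent`.
    """

    weights: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    condition: str = "none"
    rt_state_shift: float = 0.15  # log-RT reduction in the high state

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        _check_stochastic(self.transmat, "transmat")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-8):
            raise ValueError("startprob must sum to 1")

    @property
    def n_states(self) -> int:
        return self.weights.shape[0]


def _check_stochastic(A: np.ndarray, name: str) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square")
    if np.any(A < -1e-12) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError(f"{name} rows must be non-negative and sum to 1")


def default_agent(condition: str = "none") -> AgentParams:
    """Reference two-state agent used by the validation experiments.

    Bias separation is 2.6 logits (high +1.3, low -1.3), the shared weight on
    z-scored EV is 1.0, self-transition probability 0.97 in both states, and
    the session starts in the high state with probability 0.70.  These are
    package defaults emulating a plausibly-fitted animal, not ground truth.
    """
    W = np.array(
        [
            [+1.3, 1.0, 0.0, 0.0],  # high-motivation state
            [-1.3, 1.0, 0.0, 0.0],  # low-motivation state
        ]
    )
    A = np.array([[0.97, 0.03], [0.03, 0.97]])
    tau = np.array([0.70, 0.30])
    return AgentParams(W, A, tau, condition=condition)


def binomial_glm_agent(condition: str = "none") -> AgentParams:
    """Stateless (K=1) agent matched to the marginal pursue rate of the
    reference agent: one bias at 0 with the same shared EV weight."""
    W = np.array([[0.0, 1.0, 0.0, 0.0]])
    return AgentParams(W, np.array([[1.0]]), np.array([1.0]), condition=condition)


def perturb_agent(
    agent: AgentParams,
    transition_scale: float = 1.0,
    bias_shift: float = 0.0,
    condition: str | None = None,
) -> AgentParams:
    """Scale off-diagonal transition rates and/or shift state biases.

    Emulates a focal disruption (e.g. ultrasound over the dorsal raphe)
    that reduces the rate of motivation-state transitions.  The perturbed
    transition matrix is renormalized row-wise, so it stays stochastic.
    """
    A = agent.transmat.copy()
    off = ~np.eye(A.shape[0], dtype=bool)
    A[off] *= transition_scale
    A[np.diag_indices_from(A)] = 0.0
    np.fill_diagonal(A, 1.0 - A.sum(axis=1))
    W = agent.weights.copy()
    W[:, 0] += bias_shift
    return AgentParams(
        W, A, agent.startprob.copy(),
        condition=agent.condition if condition is None else condition,
        rt_state_shift=agent.rt_state_shift,
    )


# ---------------------------------------------------------------------------
# environment construction


def make_block_spec(richness_label, stochasticity_label, n_trials, rng=None) -> BlockSpec:
    if richness_label not in RICHNESS_LABELS:
        raise ValueError(f"unknown richness label {richness_label!r}")
    if stochasticity_label not in STOCHASTICITY_LABELS:
        raise ValueError(f"unknown stochasticity label {stochasticity_label!r}")
    mu = MU_RICH if richness_label == "rich" else MU_POOR
    width = SIGMA_PREDICTABLE if stochasticity_label == "predictable" else STOCHASTIC_RANGE
    return BlockSpec(richness_label, stochasticity_label, mu, width, int(n_trials))


def draw_reward_probability(spec: BlockSpec, rng, size=None):
    """Draw reward probabilities on the 0.05 grid for one block type.

    Predictable blocks: Gaussian(mu, 0.05) clipped to [0.05, 1] then rounded
    to the grid.  Stochastic blocks: discrete uniform over the 9 grid points
    mu +/- {0, 0.05, 0.10, 0.15, 0.20} (width 0.40, sd ~0.129).
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    if spec.stochasticity_label == "predictable":
        draws = rng.normal(spec.mu, SIGMA_PREDICTABLE, size=n)
        draws = np.clip(draws, PROB_GRID, 1.0)
        p = np.round(draws / PROB_GRID) * PROB_GRID
    else:
        support = spec.mu + PROB_GRID * np.arange(-4, 5)
        p = rng.choice(support, size=n)
    p = np.round(p, 10)
    return float(p[0]) if scalar else p


_BLOCK_ORDERS = [
    # richness must alternate; stochasticity covers both levels on each side
    ("rich", "poor", "rich", "poor"),
    ("poor", "rich", "poor", "rich"),
]


def make_session(
    config: dict | None = None,
    rng=None,
    session_id: str = "s0",
    subject_id: str = "m0",
) -> SessionDesign:
    """Build one session: 4 blocks (one per environment type), richness
    alternating, magnitudes uniform on {1,2,3}, delays per the task design."""
    rng = np.random.default_rng(rng)
    cfg = {"n_trials_low": 40, "n_trials_high": 50}
    if config:
        cfg.update(config)

    richness_seq = list(_BLOCK_ORDERS[rng.integers(2)])
    stoch_by_rich = {
        "rich": list(rng.permutation(STOCHASTICITY_LABELS)),
        "poor": list(rng.permutation(STOCHASTICITY_LABELS)),
    }
    blocks = []
    for r in richness_seq:
        s = stoch_by_rich[r].pop()
        n = int(rng.integers(cfg["n_trials_low"], cfg["n_trials_high"] + 1))
        blocks.append(make_block_spec(r, s, n))

    block_index, mags, probs, rich_cue, stoch_cue = [], [], [], [], []
    for i, b in enumerate(blocks):
        block_index.append(np.full(b.n_trials, i))
        mags.append(rng.integers(1, 4, size=b.n_trials))
        probs.append(draw_reward_probability(b, rng, size=b.n_trials))
        rich_cue.append(np.full(b.n_trials, 1.0 if b.richness_label == "rich" else 0.0))
        stoch_cue.append(
            np.full(b.n_trials, 1.0 if b.stochasticity_label == "stochastic" else 0.0)
        )
    block_index = np.concatenate(block_index)
    T = block_index.size
    go = rng.uniform(3.0, 4.0, size=T)
    ao = rng.uniform(3.0, 4.0, size=T)
    # intertrial interval ~ N(1, var 4), truncated below at 0.5 s
    iti = np.maximum(rng.normal(1.0, 2.0, size=T), 0.5)
    # stimulus onsets: decision phase + (go cue + action-outcome + feedback) + ITI
    trial_dur = go + 1.0 + ao + iti
    onsets = np.concatenate([[0.0], np.cumsum(trial_dur)[:-1]])
    return SessionDesign(
        session_id=session_id,
        subject_id=subject_id,
        blocks=blocks,
        block_index=block_index,
        reward_magnitude=np.concatenate(mags).astype(int),
        reward_probability=np.concatenate(probs),
        richness_cue=np.concatenate(rich_cue),
        stochasticity_cue=np.concatenate(stoch_cue),
        go_cue_delay=go,
        action_outcome_delay=ao,
        iti=iti,
        onset_s=onsets,
    )


def _design_matrix(design: SessionDesign) -> np.ndarray:
    """Agent-facing design: [1, z-scored EV, richness cue, stochasticity cue]."""
    ev = design.reward_magnitude * design.reward_probability
    sd = ev.std()
    zev = (ev - ev.mean()) / sd if sd > 0 else np.zeros_like(ev)
    return np.column_stack(
        [np.ones(design.n_trials), zev, design.richness_cue, design.stochasticity_cue]
    )


def simulate_behavior(design: SessionDesign, agent: AgentParams, rng) -> pd.DataFrame:
    """Simulate one session of agent behavior; returns a TrialTable.

    The latent state follows z_1 ~ startprob, z_{t+1} ~ transmat[z_t]; the
    decision is Bernoulli(logistic(w_{z_t} . x_t)); the outcome is
    magnitude * Bernoulli(probability) when pursued and 0 when rejected.
    """
    rng = np.random.default_rng(rng)
    X = _design_matrix(design)
    if X.shape[1] != agent.weights.shape[1]:
        raise ValueError(
            f"agent weights have {agent.weights.shape[1]} columns but the "
            f"design matrix has {X.shape[1]}"
        )
    T = design.n_trials
    K = agent.n_states
    z = np.empty(T, dtype=int)
    z[0] = rng.choice(K, p=agent.startprob)
    for t in range(1, T):
        z[t] = rng.choice(K, p=agent.transmat[z[t - 1]])
    logits = np.einsum("tm,tm->t", X, agent.weights[z])
    p_pursue = 1.0 / (1.0 + np.exp(-logits))
    decision = (rng.random(T) < p_pursue).astype(int)
    rewarded = rng.random(T) < design.reward_probability
    outcome = np.where(decision == 1, design.reward_magnitude * rewarded, 0)
    # log-normal RTs with a state-linked speed-up in the high state (state 0)
    high = (z == 0).astype(float) if K > 1 else np.zeros(T)
    rt = np.exp(rng.normal(np.log(0.76) - agent.rt_state_shift * high, 0.09, size=T))
    rt[decision == 0] = np.nan  # rejections have no pursue response

    return pd.DataFrame(
        {
            "session_id": design.session_id,
            "subject_id": design.subject_id,
            "block_index": design.block_index,
            "trial_number": np.arange(1, T + 1),
            "richness_label": np.array(
                [design.blocks[i].richness_label for i in design.block_index]
            ),
            "stochasticity_label": np.array(
                [design.blocks[i].stochasticity_label for i in design.block_index]
            ),
            "richness_cue": design.richness_cue,
            "stochasticity_cue": design.stochasticity_cue,
            "reward_magnitude": design.reward_magnitude,
            "reward_probability": design.reward_probability,
            "decision": decision,
            "reward_outcome": outcome.astype(int),
            "true_state": z,
            "rt": rt,
            "condition": agent.condition,
            "onset_s": design.onset_s,
        },
        columns=TRIAL_COLUMNS,
    )


def generate_dataset(
    n_subjects: int = 4,
    n_sessions_per_subject: int = 16,
    agent_by_condition: dict[str, AgentParams] | None = None,
    seed: int = 0,
    session_config: dict | None = None,
) -> pd.DataFrame:
    """Generate a full multi-subject dataset; bit-reproducible given seed.

    ``agent_by_condition`` maps condition labels to agents; each subject
    contributes ``n_sessions_per_subject`` sessions per condition (default:
    a single unlabelled reference agent).
    """
    if n_subjects <= 0 or n_sessions_per_subject <= 0:
        raise ValueError("n_subjects and n_sessions_per_subject must be positive")
    if agent_by_condition is None:
        agent_by_condition = {"none": default_agent()}
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(n_subjects):
        for cond, agent in agent_by_condition.items():
            for j in range(n_sessions_per_subject):
                sid = f"m{i}_{cond}_s{j}" if cond != "none" else f"m{i}_s{j}"
                design = make_session(
                    session_config, rng, session_id=sid, subject_id=f"m{i}"
                )
                tab = simulate_behavior(design, agent, rng)
                tab["condition"] = cond
                tables.append(tab)
    return pd.concat(tables, ignore_index=True)
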