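"""Active-inference MDP agent for the go/no-go task.

The agent treats each of the four cues as belonging to an unknown context
and runs Bayesian inference over contexts while selecting policies (go /
no-go) by their Kullback-Leibler proximity to preferred outcomes.

State space: {initial, lose, null, win} x {G2W, G2AL, NG2W, NG2AL} = 16
states, of which 12 are reachable in the task (win contexts never emit a
loss and vice versa).  Transitions are block-diagonal over contexts; from
an initial state the context-appropriate action reaches the optimal
outcome with probability 0.8, the inappropriate action with 0.2, and
outcome states are absorbing.  The observation map is deterministic, so
the likelihood is folded into the transition matrices.

Per trial the agent:

1. decays its stored context posterior toward the Pavlovian prior D0
   with leak f over the n_gap intervening trials;
2. infers policy precision gamma by fixed-point alternation of the
   policy posterior softmax(gamma * Q s_hat) and
   gamma = alpha / (1 - pi_hat' Q s_hat)   (gamma prior rate beta = 1);
3. emits go with probability sum_j pi_hat(go | s_j) s_hat(j);
4. updates the stored posterior from the observed action/outcome via the
   transition-implied likelihoods.

Since Q s_hat <= 0, gamma is bounded above by its prior alpha and attains
it exactly when predicted and preferred outcomes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels, taskenv
from .taskenv import CONTEXTS, GO, NOGO, Context, Session, SessionArrays

__all__ = [
    "AIParams",
    "StateSpace",
    "build_transitions",
    "context_prior",
    "preferences",
    "kl_quality_term",
    "policy_quality",
    "initial_state_quality",
    "outcome_likelihoods",
    "infer_precision",
    "forget",
    "update_context_posterior",
    "ai_choice_prob",
    "ai_session_loglik",
    "ai_simulate",
]

KINDS = ("initial", "lose", "null", "win")
KIND_RETURN = {"lose": -1, "null": 0, "win": 1}
N_STATES = 16

#: default numerical controls for the precision fixed point
PRECISION_TOL = 1e-6
PRECISION_MAX_ITER = 64

#: the agent's generative feedback validity (task instruction, not a free
#: parameter)
MODEL_VALIDITY = 0.8


@dataclass(frozen=True)
class AIParams:
    """Native-space agent parameters.

    alpha     prior on policy precision (shape of a gamma prior, rate 1);
              upper bound on the inferred trial-wise precision
    c_tau     inverse temperature of prior preferences over returns
    f         working-memory forgetting rate in (0, 1)
    p_W       prior probability a context is win-valenced
    p_go_W    prior probability the best action is go given a win context
    p_nogo_AL prior probability the best action is no-go given avoid-loss
    """

    alpha: float
    c_tau: float
    f: float
    p_W: float
    p_go_W: float
    p_nogo_AL: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.c_tau <= 0:
            raise ValueError("c_tau must be positive")
        for name in ("f", "p_W", "p_go_W", "p_nogo_AL"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")


class StateSpace:
    """Labelled hidden states: outcome kind x context."""

    def __init__(self):
        self.states: list[tuple[str, Context]] = [
            (kind, ctx) for ctx in CONTEXTS for kind in KINDS
        ]
        self.reachable: list[tuple[str, Context]] = [
            (kind, ctx)
            for (kind, ctx) in self.states
            if kind == "initial"
            or (ctx.is_win and kind in ("win", "null"))
            or (not ctx.is_win and kind in ("lose", "null"))
        ]

    def index(self, kind: str, context: Context) -> int:
        return context.index * 4 + KINDS.index(kind)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_reachable(self) -> int:
        return len(self.reachable)


STATE_SPACE = StateSpace()


def build_transitions(validity: float = MODEL_VALIDITY) -> tuple[np.ndarray, np.ndarray]:
    """(B_go, B_nogo): 16 x 16 column-stochastic matrices p(s' | s, policy)."""
    space = STATE_SPACE
    mats = {}
    for action in (GO, NOGO):
        B = np.zeros((N_STATES, N_STATES))
        for ctx in CONTEXTS:
            init = space.index("initial", ctx)
            best_kind = "win" if ctx.is_win else "null"
            worse_kind = "null" if ctx.is_win else "lose"
            p_best = validity if action == ctx.correct_action else 1.0 - validity
            B[space.index(best_kind, ctx), init] = p_best
            B[space.index(worse_kind, ctx), init] = 1.0 - p_best
            for kind in KINDS[1:]:  # outcome states are absorbing
                j = space.index(kind, ctx)
                B[j, j] = 1.0
        mats[action] = B
    return mats[GO], mats[NOGO]


B_GO, B_NOGO = build_transitions()


def context_prior(params: AIParams) -> np.ndarray:
    """Prior over the four contexts implied by the Pavlovian beliefs P0.

    Ordered as CONTEXTS = (G2W, G2AL, NG2W, NG2AL); sums to one by
    construction.
    """
    d0 = np.empty(4)
    d0[Context.G2W.index] = params.p_W * params.p_go_W
    d0[Context.NG2W.index] = params.p_W * (1.0 - params.p_go_W)
    d0[Context.NG2AL.index] = (1.0 - params.p_W) * params.p_nogo_AL
    d0[Context.G2AL.index] = (1.0 - params.p_W) * (1.0 - params.p_nogo_AL)
    return d0


def preferences(params: AIParams, d0: np.ndarray | None = None) -> np.ndarray:
    """Prior preference distribution c over the 16 states.

    Mass sits only on the 8 reachable outcome states: the softmax of
    returns {-1, 0, +1} at inverse temperature c_tau, tempered by the
    prior prevalence of the outcome's context, then normalized.
    """
    if d0 is None:
        d0 = context_prior(params)
    returns = np.array([-1.0, 0.0, 1.0])
    w = np.exp(params.c_tau * (returns - returns.max()))
    w /= w.sum()
    sigma = {-1: w[0], 0: w[1], 1: w[2]}
    c = np.zeros(N_STATES)
    for kind, ctx in STATE_SPACE.reachable:
        if kind == "initial":
            continue
        c[STATE_SPACE.index(kind, ctx)] = d0[ctx.index] * sigma[KIND_RETURN[kind]]
    if np.any(c[[STATE_SPACE.index(k, x) for k, x in STATE_SPACE.reachable if k != "initial"]] == 0.0):
        raise ValueError("c_tau too extreme: zero preference mass on a reachable outcome")
    return c / c.sum()


def kl_quality_term(b: float, c: float) -> float:
    """Single-destination contribution b*ln(c) - b*ln(b) to the policy quality."""
    if b == 0.0:
        return 0.0
    return b * np.log(c) - b * np.log(b)


def policy_quality(B_go: np.ndarray, B_nogo: np.ndarray, c: np.ndarray) -> np.ndarray:
    """KL policy-quality matrix Q (policies x states); rows (nogo, go).

    Q[i, j] = sum_dest B{i}_dest,j (ln c_dest - ln B{i}_dest,j)
            = -KL(B{i}_.,j || c) <= 0, with 0 iff the predicted and
    preferred distributions coincide.  Entries are -inf where a policy
    assigns mass to a state with no preference mass.
    """
    out = np.empty((2, B_go.shape[1]))
    for i, B in enumerate((B_nogo, B_go)):
        for j in range(B.shape[1]):
            col = B[:, j]
            nz = col > 0.0
            if np.any(c[nz] == 0.0):
                out[i, j] = -np.inf
                continue
            out[i, j] = np.sum(col[nz] * (np.log(c[nz]) - np.log(col[nz])))
    return out


def initial_state_quality(params: AIParams) -> np.ndarray:
    """Q restricted to the four initial states, columns in CONTEXTS order."""
    c = preferences(params)
    q_full = policy_quality(B_GO, B_NOGO, c)
    cols = [STATE_SPACE.index("initial", ctx) for ctx in CONTEXTS]
    return q_full[:, cols]


def outcome_likelihoods(validity: float = MODEL_VALIDITY) -> np.ndarray:
    """p(outcome | context, action) implied by the transition model.

    Shape (4 contexts, 2 actions [nogo, go], 3 outcomes [-1, 0, +1]).
    """
    lik = np.zeros((4, 2, 3))
    for ctx in CONTEXTS:
        for a, action in enumerate((NOGO, GO)):
            best, worse = ctx.outcomes
            p_best = validity if action == ctx.correct_action else 1.0 - validity
            lik[ctx.index, a, best + 1] = p_best
            lik[ctx.index, a, worse + 1] = 1.0 - p_best
    return lik


def infer_precision(
    Qmat: np.ndarray,
    s_hat: np.ndarray,
    alpha: float,
    tol: float = PRECISION_TOL,
    max_iter: int = PRECISION_MAX_ITER,
) -> tuple[float, np.ndarray, int]:
    """Fixed-point inference of policy precision gamma and posterior pi_hat.

    Alternates ln pi_hat proportional to gamma * (Q s_hat) with
    gamma = alpha / (1 - pi_hat' Q s_hat), starting at gamma = alpha,
    until successive gamma values change by less than ``tol``.  Returns
    (gamma, pi_hat over (nogo, go), iterations used).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    q = Qmat @ s_hat
    gamma, pi_go, n_iter = _kernels.precision_fixed_point(
        float(q[1]), float(q[0]), float(alpha), tol, max_iter
    )
    return gamma, np.array([1.0 - pi_go, pi_go]), n_iter


def forget(D_stored: np.ndarray, D0: np.ndarray, f: float, n_gap: int) -> np.ndarray:
    """Leaky-memory mixing of the stored posterior back toward the prior.

    D_t = D_stored (1 - f^n_gap) + D0 (1 - (1-f)^n_gap), renormalized
    (the two weights already sum to one at n_gap = 1).
    """
    if n_gap < 1:
        raise ValueError("n_gap must be >= 1")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    mixed = D_stored * (1.0 - f**n_gap) + D0 * (1.0 - (1.0 - f) ** n_gap)
    total = mixed.sum()
    if total == 0.0:  # f = 0 with n_gap such that both weights vanish cannot occur
        return D0.copy()
    return mixed / total


def update_context_posterior(
    D_t: np.ndarray, lik: np.ndarray, action: str, outcome: int
) -> np.ndarray:
    """Bayes update of the context belief from one observed action/outcome."""
    a = 1 if action == GO else 0
    post = D_t * lik[:, a, outcome + 1]
    total = post.sum()
    if total <= 0.0:
        raise ValueError("observation impossible under every context")
    return post / total


def ai_choice_prob(Qmat: np.ndarray, s_hat: np.ndarray, gamma: float) -> float:
    """p(go) marginalizing the per-state policy posterior over the belief."""
    z = gamma * Qmat  # (2, 4)
    z = z - z.max(axis=0, keepdims=True)
    ez = np.exp(z)
    p_go_per_state = ez[1] / ez.sum(axis=0)
    return float(p_go_per_state @ s_hat)


def ai_session_loglik(
    session: Session | SessionArrays,
    params: AIParams,
    tol: float = PRECISION_TOL,
    max_iter: int = PRECISION_MAX_ITER,
    return_trace: bool = False,
):
    """Sequential log-likelihood of a session, with optional per-trial traces.

    The trace frame has columns p_go, gamma_hat and the four
    context-belief components at choice time.
    """
    arr = session.to_arrays() if isinstance(session, Session) else session
    d0 = context_prior(params)
    qmat = initial_state_quality(params)
    lik = outcome_likelihoods()
    n = arr.n_trials
    p_go = np.empty(n)
    gamma = np.empty(n)
    beliefs = np.empty((n, 4))
    ll = _kernels.ai_loglik_core(
        arr.context, arr.n_gap, arr.first_of_chain, arr.action, arr.outcome,
        d0, qmat, lik, float(params.f), float(params.alpha),
        tol, max_iter, p_go, gamma, beliefs,
    )
    if not np.isfinite(ll):
        raise ValueError("session contains an observation impossible under the model")
    if not return_trace:
        return float(ll), p_go
    trace = pd.DataFrame(
        {"p_go": p_go, "gamma_hat": gamma}
        | {f"belief_{c.name}": beliefs[:, c.index] for c in CONTEXTS}
    )
    return float(ll), trace


def ai_simulate(
    schedule: list[Context],
    params: AIParams,
    seed: int | np.random.Generator,
    subject_id: str = "sim",
    feedback_validity: float = 0.8,
    tol: float = PRECISION_TOL,
    max_iter: int = PRECISION_MAX_ITER,
) -> Session:
    """Generate a session by sampling actions from the agent's policy posterior."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d0 = context_prior(params)
    qmat = initial_state_quality(params)
    lik = outcome_likelihoods()
    stored: dict[int, np.ndarray] = {}
    last_seen: dict[int, int] = {}
    actions, outcomes = [], []
    for i, context in enumerate(schedule):
        k = context.index
        if k not in stored:
            d_t = d0.copy()
        else:
            d_t = forget(stored[k], d0, params.f, i - last_seen[k])
        gamma, _, _ = infer_precision(qmat, d_t, params.alpha, tol, max_iter)
        p_go = ai_choice_prob(qmat, d_t, gamma)
        action = GO if rng.random() < p_go else NOGO
        outcome = taskenv.emit_outcome(context, action, feedback_validity, rng)
        stored[k] = update_context_posterior(d_t, lik, action, outcome)
        last_seen[k] = i
        actions.append(action)
        outcomes.append(outcome)
    return taskenv.build_session(
        subject_id, schedule, actions, outcomes, feedback_validity
    )
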