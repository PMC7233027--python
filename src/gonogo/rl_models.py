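"""Rescorla-Wagner model family for the orthogonalized go/no-go task.

Eight nested variants share a compressed-softmax choice rule with
irreducible noise xi,

    p(go) = xi * sigmoid(W_go - W_nogo) + (1 - xi) / 2,

and differ in how the action weights W are built from learned action
values Q, a go bias b, and a Pavlovian bias that couples the learned
state value V (or its latched sign) to the go weight:

    Model 1  rho, eps                          (xi fixed at 1)
    Model 2  + irreducible noise xi
    Model 3  + go bias b
    Model 4  + Pavlovian bias pi * V(s)
    Model 5  Model 3 with separate rho_win / rho_loss
    Model 6  Model 4 with separate rho_win / rho_loss
    Model 7  Model 6 with constant Pavlovian bias pi_c * sgn(V(s))
    Model 8  Model 7 + decay delta of unchosen action values

Outcome sensitivity rho multiplies returns inside the value updates and
is functionally identical to a softmax inverse temperature.  sgn(V) for
the constant bias is latched permanently from the first non-null outcome
observed in a context.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels, taskenv
from .taskenv import CONTEXT_IS_WIN, CONTEXTS, GO, NOGO, Context, Session, SessionArrays

__all__ = [
    "RLParams",
    "RLModelSpec",
    "RLState",
    "MODEL_SPECS",
    "action_weights",
    "choice_prob",
    "update",
    "session_loglik",
    "simulate",
]


@dataclass(frozen=True)
class RLParams:
    """Native-space parameter vector; only fields the variant uses are read."""

    rho_win: float = 1.0
    rho_loss: float = 1.0
    epsilon: float = 0.1
    xi: float = 1.0
    b: float = 0.0
    pi: float = 0.0
    pi_c: float = 0.0
    delta: float = 0.0

    @property
    def rho(self) -> float:
        return self.rho_win

    def with_(self, **kw) -> "RLParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class RLModelSpec:
    """Which mechanisms a variant switches on."""

    model_id: int
    has_xi: bool
    has_bias: bool
    pavlovian_kind: str  # "none" | "value" | "constant"
    dual_rho: bool
    has_decay: bool

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["rho_win", "rho_loss"] if self.dual_rho else ["rho"]
        names.append("epsilon")
        if self.has_xi:
            names.append("xi")
        if self.has_bias:
            names.append("b")
        if self.pavlovian_kind == "value":
            names.append("pi")
        elif self.pavlovian_kind == "constant":
            names.append("pi_c")
        if self.has_decay:
            names.append("delta")
        return tuple(names)

    def params_from_dict(self, values: dict[str, float]) -> RLParams:
        kw = dict(values)
        if not self.dual_rho:
            rho = kw.pop("rho")
            kw["rho_win"] = kw["rho_loss"] = rho
        if not self.has_xi:
            kw.setdefault("xi", 1.0)
        return RLParams(**kw)


MODEL_SPECS: dict[int, RLModelSpec] = {
    1: RLModelSpec(1, False, False, "none", False, False),
    2: RLModelSpec(2, True, False, "none", False, False),
    3: RLModelSpec(3, True, True, "none", False, False),
    4: RLModelSpec(4, True, True, "value", False, False),
    5: RLModelSpec(5, True, True, "none", True, False),
    6: RLModelSpec(6, True, True, "value", True, False),
    7: RLModelSpec(7, True, True, "constant", True, False),
    8: RLModelSpec(8, True, True, "constant", True, True),
}


@dataclass
class RLState:
    """Evolving value tables: Q (action x context), V and latched sgn(V)."""

    Q: np.ndarray
    V: np.ndarray
    sgnV: np.ndarray

    @classmethod
    def zeros(cls) -> "RLState":
        return cls(Q=np.zeros((4, 2)), V=np.zeros(4), sgnV=np.zeros(4))

    def copy(self) -> "RLState":
        return RLState(self.Q.copy(), self.V.copy(), self.sgnV.copy())


def _pav_args(params: RLParams, spec: RLModelSpec) -> tuple[float, int]:
    if spec.pavlovian_kind == "value":
        return params.pi, _kernels.PAV_VALUE
    if spec.pavlovian_kind == "constant":
        return params.pi_c, _kernels.PAV_CONSTANT
    return 0.0, _kernels.PAV_NONE


def action_weights(
    state: RLState, params: RLParams, spec: RLModelSpec, context: Context
) -> tuple[float, float]:
    """(W_go, W_nogo) for the current context under the chosen variant."""
    s = context.index
    w_go = state.Q[s, 1]
    if spec.has_bias:
        w_go += params.b
    if spec.pavlovian_kind == "value":
        w_go += params.pi * state.V[s]
    elif spec.pavlovian_kind == "constant":
        w_go += params.pi_c * state.sgnV[s]
    return float(w_go), float(state.Q[s, 0])


def choice_prob(weights: tuple[float, float], xi: float) -> float:
    """Compressed softmax: xi-weighted sigmoid mixed with a uniform lapse.

    Range is exactly [(1 - xi)/2, (1 + xi)/2]; xi = 0 gives coin flips
    regardless of the weights.
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    w_go, w_nogo = weights
    return xi / (1.0 + np.exp(-(w_go - w_nogo))) + (1.0 - xi) / 2.0


def update(
    state: RLState,
    params: RLParams,
    spec: RLModelSpec,
    context: Context,
    action: str,
    outcome: int,
) -> RLState:
    """One Rescorla-Wagner step; returns a new state (input unchanged)."""
    new = state.copy()
    s = context.index
    a = 1 if action == GO else 0
    rho = params.rho_win if context.is_win else (
        params.rho_loss if spec.dual_rho else params.rho_win
    )
    r = float(outcome)
    new.Q[s, a] += params.epsilon * (rho * r - new.Q[s, a])
    new.V[s] += params.epsilon * (rho * r - new.V[s])
    if new.sgnV[s] == 0.0 and r != 0.0:
        new.sgnV[s] = np.sign(r)
    if spec.has_decay and params.delta > 0.0:
        mask = np.ones((4, 2), dtype=bool)
        mask[s, a] = False
        new.Q[mask] *= 1.0 - params.delta
    return new


def _kernel_args(params: RLParams, spec: RLModelSpec):
    rho_loss = params.rho_loss if spec.dual_rho else params.rho_win
    xi = params.xi if spec.has_xi else 1.0
    b = params.b if spec.has_bias else 0.0
    pav_weight, pav_kind = _pav_args(params, spec)
    delta = params.delta if spec.has_decay else 0.0
    return params.rho_win, rho_loss, params.epsilon, xi, b, pav_weight, delta, pav_kind


def session_loglik(
    session: Session | SessionArrays, params: RLParams, spec: RLModelSpec
) -> tuple[float, np.ndarray]:
    """Log-likelihood of the observed actions plus the per-trial p(go) trace.

    Missing-response trials are skipped (they add nothing to the
    likelihood and trigger no update).
    """
    arr = session.to_arrays() if isinstance(session, Session) else session
    for v in _kernel_args(params, spec)[:3]:
        if not np.isfinite(v):
            raise ValueError("non-finite parameter")
    p_go = np.empty(arr.n_trials)
    ll = _kernels.rl_loglik_core(
        arr.context, arr.action, arr.outcome, CONTEXT_IS_WIN,
        *_kernel_args(params, spec), p_go,
    )
    return float(ll), p_go


def simulate(
    schedule: list[Context],
    params: RLParams,
    spec: RLModelSpec,
    seed: int | np.random.Generator,
    subject_id: str = "sim",
    feedback_validity: float = 0.8,
) -> Session:
    """Generate a session by sampling actions from the model's choice rule."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    state = RLState.zeros()
    actions, outcomes = [], []
    xi = params.xi if spec.has_xi else 1.0
    eff = params if spec.has_bias else params.with_(b=0.0)
    for context in schedule:
        p_go = choice_prob(action_weights(state, eff, spec, context), xi)
        action = GO if rng.random() < p_go else NOGO
        outcome = taskenv.emit_outcome(context, action, feedback_validity, rng)
        state = update(state, eff, spec, context, action, outcome)
        actions.append(action)
        outcomes.append(outcome)
    return taskenv.build_session(
        subject_id, schedule, actions, outcomes, feedback_validity
    )
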