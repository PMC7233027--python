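"""Uniform fitting interface over both model families.

A :class:`BehavioralModel` bundles what the hierarchical fitter and the
model-comparison stage need to know about a model: its free parameter
names, the transform that Gaussianizes each parameter, a session
log-likelihood, and a simulator.  ``get_model("rl7")`` or
``get_model("ai")`` resolves the nine candidates compared in this
package (RL Models 1-8 plus the active-inference agent).
"""

from __future__ import annotations

import numpy as np

from . import active_inference as ai
from . import rl_models as rl
from .hierfit import GroupPrior
from .taskenv import Context, Session, SessionArrays

__all__ = ["BehavioralModel", "RLModel", "AIModel", "get_model", "MODEL_NAMES"]


class BehavioralModel:
    """Abstract fitting interface; see subclasses."""

    name: str
    param_names: tuple[str, ...]
    transform_kinds: dict[str, str]

    def loglik(self, arr: SessionArrays, values: dict[str, float]) -> float:
        raise NotImplementedError

    def simulate(
        self, schedule: list[Context], values: dict[str, float],
        rng: np.random.Generator, subject_id: str = "sim",
        feedback_validity: float = 0.8,
    ) -> Session:
        raise NotImplementedError

    def default_prior(self) -> GroupPrior:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return len(self.param_names)


#: synthetic-cohort conventions for the RL group distributions (native
#: means; SDs in transformed space).  The source study does not print its
#: RL group estimates, so these are round, plausible values for this task
#: family, not estimates from any dataset.
_RL_PRIOR_DEFAULTS: dict[str, tuple[float, float]] = {
    "rho": (2.0, 0.5),
    "rho_win": (2.0, 0.5),
    "rho_loss": (2.0, 0.5),
    "epsilon": (0.15, 0.7),
    "xi": (0.85, 1.0),
    "b": (0.3, 0.5),
    "pi": (0.3, 0.5),
    "pi_c": (0.3, 0.5),
    "delta": (0.1, 0.7),
}

_RL_TRANSFORMS: dict[str, str] = {
    "rho": "log",
    "rho_win": "log",
    "rho_loss": "log",
    "epsilon": "logit",
    "xi": "logit",
    "b": "identity",
    "pi": "identity",
    "pi_c": "identity",
    "delta": "logit",
}


class RLModel(BehavioralModel):
    """Adapter for one of the eight Rescorla-Wagner variants."""

    def __init__(self, model_id: int):
        if model_id not in rl.MODEL_SPECS:
            raise ValueError(f"unknown RL model id {model_id}")
        self.spec = rl.MODEL_SPECS[model_id]
        self.model_id = model_id
        self.name = f"rl{model_id}"
        self.param_names = self.spec.param_names
        self.transform_kinds = {p: _RL_TRANSFORMS[p] for p in self.param_names}

    def _params(self, values: dict[str, float]) -> rl.RLParams:
        return self.spec.params_from_dict({k: values[k] for k in self.param_names})

    def loglik(self, arr: SessionArrays, values: dict[str, float]) -> float:
        ll, _ = rl.session_loglik(arr, self._params(values), self.spec)
        return ll

    def simulate(self, schedule, values, rng, subject_id="sim", feedback_validity=0.8):
        return rl.simulate(
            schedule, self._params(values), self.spec, rng,
            subject_id=subject_id, feedback_validity=feedback_validity,
        )

    def default_prior(self) -> GroupPrior:
        return GroupPrior.from_native(
            self.param_names,
            {p: _RL_PRIOR_DEFAULTS[p][0] for p in self.param_names},
            {p: _RL_PRIOR_DEFAULTS[p][1] for p in self.param_names},
            self.transform_kinds,
        )


#: group-level empirical priors for the active-inference agent (native
#: means; SDs in estimation space)
AI_PRIOR_NATIVE_MEANS: dict[str, float] = {
    "alpha": 1.627,
    "p_W": 0.5163,
    "p_go_W": 0.5211,
    "p_nogo_AL": 0.5063,
    "c_tau": 5.785,
    "f": 0.593,
}
AI_PRIOR_SDS: dict[str, float] = {
    "alpha": 0.31,
    "p_W": 0.14,
    "p_go_W": 0.21,
    "p_nogo_AL": 0.13,
    "c_tau": 0.019,
    "f": 0.48,
}


class AIModel(BehavioralModel):
    """Adapter for the active-inference agent."""

    name = "ai"
    param_names = ("alpha", "c_tau", "f", "p_W", "p_go_W", "p_nogo_AL")
    transform_kinds = {
        "alpha": "log",
        "c_tau": "log",
        "f": "logit",
        "p_W": "logit",
        "p_go_W": "logit",
        "p_nogo_AL": "logit",
    }

    def _params(self, values: dict[str, float]) -> ai.AIParams:
        return ai.AIParams(**{k: values[k] for k in self.param_names})

    def loglik(self, arr: SessionArrays, values: dict[str, float]) -> float:
        ll, _ = ai.ai_session_loglik(arr, self._params(values))
        return ll

    def simulate(self, schedule, values, rng, subject_id="sim", feedback_validity=0.8):
        return ai.ai_simulate(
            schedule, self._params(values), rng,
            subject_id=subject_id, feedback_validity=feedback_validity,
        )

    def default_prior(self) -> GroupPrior:
        return GroupPrior.from_native(
            self.param_names, AI_PRIOR_NATIVE_MEANS, AI_PRIOR_SDS, self.transform_kinds
        )


MODEL_NAMES: tuple[str, ...] = tuple(f"rl{i}" for i in range(1, 9)) + ("ai",)


def get_model(name: str | int) -> BehavioralModel:
    """Resolve a model by name ('rl1'..'rl8', 'ai') or RL model id (1-8)."""
    if isinstance(name, int):
        return RLModel(name)
    low = str(name).lower()
    if low == "ai":
        return AIModel()
    if low.startswith("rl") and low[2:].isdigit():
        return RLModel(int(low[2:]))
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
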