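"""Synthetic cohorts: simulated subjects plus a receptor-availability-like covariate.

Stands in for a behavioral study cohort: each subject's parameters are
drawn from group-level Gaussians in transformed space (the active-
inference defaults are the empirical group priors; the RL defaults are
round synthetic conventions), a full interleaved session is simulated,
and an optional per-subject scalar covariate is constructed with a
specified linear(+quadratic) dependence on a chosen parameter in its
fitting transform -- emulating how striatal D2/3 receptor availability
(BP_ND) was related to stochasticity parameters, without any kinetic
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierfit import GroupPrior, transform_value
from .models import BehavioralModel, get_model
from .taskenv import Session, make_schedule

__all__ = ["CovariateSpec", "CohortSpec", "sample_cohort", "sample_covariate"]


@dataclass(frozen=True)
class CovariateSpec:
    """covariate = intercept + slope*g(param) + quad*g(param)^2 + noise.

    ``g`` is the source parameter's fitting transform (log/logit/identity),
    so the constructed dependence lives on the Gaussianized scale used by
    the downstream association stage.
    """

    source: str = "alpha"
    intercept: float = 2.5
    slope: float = -0.3
    quad: float = 0.0
    noise_sd: float = 0.3

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a cohort and its ground truth."""

    model: str = "ai"
    n_subjects: int = 75
    trials_per_context: int = 36
    feedback_validity: float = 0.8
    seed: int = 0
    group: GroupPrior | None = None  # defaults to the model's prior
    covariate: CovariateSpec | None = None

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")


def sample_cohort(spec: CohortSpec) -> tuple[list[Session], pd.DataFrame]:
    """Simulate a cohort; returns (sessions, ground-truth parameter table).

    The truth table has one row per subject with native parameters and
    their transformed-space values (columns ``<name>_transformed``), plus
    the covariate when a covariate model is specified.
    """
    model = get_model(spec.model)
    group = spec.group if spec.group is not None else model.default_prior()
    rng = np.random.default_rng(spec.seed)
    draws = group.sample(rng, spec.n_subjects)
    sessions: list[Session] = []
    rows = []
    for i in range(spec.n_subjects):
        sid = f"sim{i:03d}"
        values = group.transforms.untransform(draws[i])
        schedule = make_schedule(spec.trials_per_context, rng)
        sessions.append(
            model.simulate(
                schedule, values, rng, subject_id=sid,
                feedback_validity=spec.feedback_validity,
            )
        )
        row = {"subject_id": sid, **values}
        row.update({f"{n}_transformed": draws[i, j] for j, n in enumerate(group.names)})
        rows.append(row)
    truth = pd.DataFrame(rows)
    if spec.covariate is not None:
        truth["covariate"] = sample_covariate(truth, spec.covariate, model, rng)
    return sessions, truth


def sample_covariate(
    true_params: pd.DataFrame,
    spec: CovariateSpec,
    model: BehavioralModel | str,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Construct the per-subject covariate from the ground-truth table."""
    model = get_model(model) if isinstance(model, str) else model
    if spec.source not in true_params.columns:
        raise ValueError(f"source parameter {spec.source!r} not in truth table")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    kind = model.transform_kinds[spec.source]
    g = np.array([transform_value(v, kind) for v in true_params[spec.source]])
    noise = rng.normal(0.0, spec.noise_sd, size=len(g)) if spec.noise_sd > 0 else 0.0
    return spec.intercept + spec.slope * g + spec.quad * g**2 + noise
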