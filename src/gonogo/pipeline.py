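"""High-level workflows tying the stages together.

Each function is a plain library call used both by the command-line
interface and by scripts: simulate a cohort, fit one model
hierarchically, compare a model set by iBIC, run a
simulate-refit-correlate parameter-recovery study, summarize behavior,
and run the covariate association stage.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import AssociationResult, associate
from .behavior_stats import BehaviorSummary, summarize_cohort
from .hierfit import FitResult, GroupPrior, em_fit
from .modelcomp import ComparisonReport, compare_models
from .models import get_model
from .synthetic_cohort import CohortSpec, CovariateSpec, sample_cohort
from .taskenv import Session

__all__ = [
    "simulate_cohort",
    "fit_cohort",
    "compare",
    "recover",
    "behavior_summary",
    "associate_stage",
    "write_manifest",
]

#: defaults for recovery studies: a short EM schedule and a few
#: optimizer starts keep simulate-refit loops tractable at cohort scale
RECOVERY_EM_ITER = 2
RECOVERY_STARTS = 3


def simulate_cohort(
    model: str = "ai",
    n_subjects: int = 75,
    seed: int = 0,
    trials_per_context: int = 36,
    covariate: CovariateSpec | None = None,
    group: GroupPrior | None = None,
) -> tuple[list[Session], pd.DataFrame]:
    spec = CohortSpec(
        model=model,
        n_subjects=n_subjects,
        trials_per_context=trials_per_context,
        seed=seed,
        group=group,
        covariate=covariate,
    )
    return sample_cohort(spec)


def fit_cohort(
    sessions: list[Session],
    model_name: str,
    max_iter: int = 20,
    tol: float = 1e-3,
    starts: int = 5,
    seed: int = 0,
    init: GroupPrior | None = None,
) -> FitResult:
    model = get_model(model_name)
    return em_fit(
        sessions, model, init=init, max_iter=max_iter, tol=tol,
        starts=starts, seed=seed,
    )


def compare(
    sessions: list[Session],
    model_names: list[str],
    n_samples: int = 2000,
    seed: int = 0,
    em_max_iter: int = 3,
    starts: int = 3,
) -> ComparisonReport:
    """Fit each candidate model then compare by Monte-Carlo iBIC."""
    models = {name: get_model(name) for name in model_names}
    fitted = {}
    for name, model in models.items():
        res = em_fit(
            sessions, model, max_iter=em_max_iter, starts=starts, seed=seed
        )
        fitted[name] = res.prior
    return compare_models(sessions, fitted, models, n_samples=n_samples, seed=seed)


def recover(
    model_name: str = "ai",
    n_subjects: int = 50,
    seed: int = 0,
    trials_per_context: int = 36,
    em_max_iter: int = RECOVERY_EM_ITER,
    starts: int = RECOVERY_STARTS,
    group: GroupPrior | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate-refit-correlate parameter recovery.

    Returns (correlations, merged table).  Correlations are Pearson r
    between generating and re-estimated parameters in transformed space,
    one row per parameter.
    """
    model = get_model(model_name)
    generating = group if group is not None else model.default_prior()
    sessions, truth = simulate_cohort(
        model_name, n_subjects=n_subjects, seed=seed,
        trials_per_context=trials_per_context, group=generating,
    )
    fit = em_fit(
        sessions, model, init=generating, max_iter=em_max_iter,
        starts=starts, seed=seed + 1,
    )
    est = fit.parameter_table()
    merged = truth.merge(est, on="subject_id", suffixes=("_true", "_est"))
    rows = []
    for name in generating.names:
        x = merged[f"{name}_transformed_true"]
        y = merged[f"{name}_transformed_est"]
        r = float(np.corrcoef(x, y)[0, 1]) if x.std() > 0 and y.std() > 0 else np.nan
        rows.append({"parameter": name, "pearson_r": r})
    return pd.DataFrame(rows), merged


def behavior_summary(sessions: list[Session], last_k: int = 20) -> BehaviorSummary:
    return summarize_cohort(sessions, last_k=last_k)


def associate_stage(
    params: pd.DataFrame,
    covariate,
    n_factors: int = 3,
    method: str = "principal_axis",
    rotation: str | None = "varimax",
    include_quadratic: bool = True,
    targets: list[str] | None = None,
) -> AssociationResult:
    return associate(
        params, covariate, n_factors=n_factors, method=method,
        rotation=rotation, include_quadratic=include_quadratic, targets=targets,
    )


def write_manifest(path, config: dict, seeds: dict, outputs: list[str]) -> dict:
    """Record versions, seeds and a config hash next to pipeline outputs."""

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        if hasattr(obj, "__dataclass_fields__"):
            return _clean(asdict(obj))
        return obj

    config = _clean(config)
    manifest = {
        "package": "gonogo",
        "version": __version__,
        "python": platform.python_version(),
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "seeds": _clean(seeds),
        "outputs": [str(o) for o in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
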