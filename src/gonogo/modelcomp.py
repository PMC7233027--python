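"""Group-level model comparison: integrated likelihood, iBIC and pseudo-R2.

The integrated (sample-averaged) likelihood replaces each subject's
maximum-likelihood fit with a Monte-Carlo average of the data likelihood
over parameters drawn from the fitted group-level Gaussian:

    ln p(y | theta_group) ~= sum_i ln (1/N) sum_n p(y_i | h_n),
                             h_n ~ N(mean, sd) (transformed space)

computed with log-sum-exp.  The iBIC then penalizes the group-level
hyperparameter count:

    iBIC = -2 ln p(y | theta_group) + |theta| ln |s|

where |theta| counts group hyperparameters (a mean and an SD per free
parameter) and |s| is the total number of observed choices.  Smaller is
better.  Pseudo-R2 scales a subject's log-likelihood between chance (0)
and perfect prediction (1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .hierfit import GroupPrior
from .taskenv import Session

__all__ = [
    "integrated_loglik",
    "ibic",
    "pseudo_r2",
    "ComparisonReport",
    "compare_models",
]

DEFAULT_N_SAMPLES = 2000


def integrated_loglik(
    sessions: list[Session],
    model,
    group: GroupPrior,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Monte-Carlo integrated log-likelihood; returns (total, per-subject).

    Parameter vectors are drawn once per subject from the group Gaussian
    in transformed space, untransformed, and the likelihoods averaged on
    the log scale via log-sum-exp.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    per_subject = np.empty(len(sessions))
    for i, session in enumerate(sessions):
        arr = session.to_arrays()
        draws = group.sample(rng, n_samples)
        lls = np.empty(n_samples)
        for n in range(n_samples):
            values = group.transforms.untransform(draws[n])
            try:
                lls[n] = model.loglik(arr, values)
            except ValueError:
                lls[n] = -np.inf
        per_subject[i] = logsumexp(lls) - np.log(n_samples)
        if not np.isfinite(per_subject[i]):
            raise FloatingPointError(
                f"integrated likelihood underflowed for subject {session.subject_id}"
            )
    return float(per_subject.sum()), per_subject


def ibic(integrated_ll: float, n_group_params: int, n_datapoints: int) -> float:
    """-2 * integrated log-likelihood + |theta| ln |s|."""
    if n_group_params <= 0 or n_datapoints <= 0:
        raise ValueError("counts must be positive")
    return -2.0 * integrated_ll + n_group_params * np.log(n_datapoints)


def pseudo_r2(subject_loglik: float, n_trials: int) -> float:
    """Likelihood-based fit index: 0 at chance, 1 at perfect prediction.

    |1 - L / (t ln 0.5)|; the absolute value folds worse-than-chance fits
    back into [0, 1], mirroring how the index is conventionally printed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    chance = n_trials * np.log(0.5)
    return float(abs(1.0 - subject_loglik / chance))


@dataclass
class ComparisonReport:
    """Per-model comparison table; the winner has the smallest iBIC."""

    table: pd.DataFrame  # model, integrated_loglik, n_group_params, n_datapoints, ibic, mean_pseudo_r2, winner
    per_subject: dict[str, np.ndarray]

    @property
    def winner(self) -> str:
        return str(self.table.loc[self.table["ibic"].idxmin(), "model"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_models(
    sessions: list[Session],
    fitted: dict[str, GroupPrior],
    models: dict[str, object],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> ComparisonReport:
    """Integrated-likelihood comparison of fitted models on one cohort."""
    n_data = int(sum(s.to_arrays().n_observed for s in sessions))
    trials_per_subject = np.array([s.to_arrays().n_observed for s in sessions])
    rows = []
    per_subject = {}
    for k, name in enumerate(fitted):
        model = models[name]
        group = fitted[name]
        total, per = integrated_loglik(
            sessions, model, group, n_samples=n_samples,
            seed=np.random.default_rng([seed, k]),
        )
        per_subject[name] = per
        n_group = 2 * len(group.names)  # a mean and an SD per free parameter
        rows.append(
            {
                "model": name,
                "integrated_loglik": total,
                "n_group_params": n_group,
                "n_datapoints": n_data,
                "ibic": ibic(total, n_group, n_data),
                "mean_pseudo_r2": float(
                    np.mean([pseudo_r2(l, t) for l, t in zip(per, trials_per_subject)])
                ),
            }
        )
    table = pd.DataFrame(rows)
    table["delta_ibic"] = table["ibic"] - table["ibic"].min()
    table["winner"] = table["ibic"] == table["ibic"].min()
    return ComparisonReport(table=table, per_subject=per_subject)
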