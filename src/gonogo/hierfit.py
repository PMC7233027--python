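"""Hierarchical empirical-Bayes fitting.

Parameters are mapped to the real line (log for positive scales, logit
for unit-interval rates, identity for unconstrained biases) so that the
group-level distribution of each is a Gaussian.  Fitting alternates:

  E-step  per-subject MAP estimation of the transformed parameters under
          the current group Gaussian prior, with a Laplace (inverse
          Hessian) covariance at the mode;
  M-step  moment updates of the group mean and SD, where each subject
          contributes its MAP estimate plus its Laplace variance.

A small number of EM iterations suffices on this task; convergence is
declared when transformed group means move by less than ``tol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit as _logit

from .taskenv import Session, SessionArrays

__all__ = [
    "transform_value",
    "untransform_value",
    "TransformSpec",
    "GroupPrior",
    "SubjectFit",
    "FitResult",
    "fit_subject",
    "em_fit",
]

_SD_FLOOR = 1e-3  # floor on group SDs (transformed space)


def transform_value(x: float, kind: str) -> float:
    """Map a native parameter value to the real line."""
    if kind == "identity":
        return float(x)
    if kind == "log":
        if x <= 0:
            raise ValueError(f"log transform requires x > 0, got {x}")
        return float(np.log(x))
    if kind == "logit":
        if not 0.0 < x < 1.0:
            raise ValueError(f"logit transform requires 0 < x < 1, got {x}")
        return float(_logit(x))
    raise ValueError(f"unknown transform {kind!r}")


def untransform_value(y: float, kind: str) -> float:
    """Inverse of :func:`transform_value`."""
    if kind == "identity":
        return float(y)
    if kind == "log":
        return float(np.exp(y))
    if kind == "logit":
        return float(expit(y))
    raise ValueError(f"unknown transform {kind!r}")


@dataclass(frozen=True)
class TransformSpec:
    """Ordered per-parameter transform map."""

    names: tuple[str, ...]
    kinds: tuple[str, ...]

    @classmethod
    def from_dict(cls, kinds: dict[str, str], names=None) -> "TransformSpec":
        names = tuple(names) if names is not None else tuple(kinds)
        return cls(names=names, kinds=tuple(kinds[n] for n in names))

    def transform(self, values: dict[str, float]) -> np.ndarray:
        return np.array(
            [transform_value(values[n], k) for n, k in zip(self.names, self.kinds)]
        )

    def untransform(self, vec: np.ndarray) -> dict[str, float]:
        return {
            n: untransform_value(v, k)
            for n, k, v in zip(self.names, self.kinds, vec)
        }


@dataclass(frozen=True)
class GroupPrior:
    """Group-level Gaussian over transformed parameters."""

    names: tuple[str, ...]
    mean: np.ndarray  # transformed space
    sd: np.ndarray  # transformed space
    transforms: TransformSpec

    def __post_init__(self):
        if np.any(self.sd <= 0):
            raise ValueError("prior SDs must be positive")

    @classmethod
    def from_native(
        cls,
        names,
        native_means: dict[str, float],
        sds: dict[str, float],
        kinds: dict[str, str],
    ) -> "GroupPrior":
        names = tuple(names)
        spec = TransformSpec.from_dict(kinds, names)
        mean = spec.transform({n: native_means[n] for n in names})
        sd = np.array([sds[n] for n in names], dtype=float)
        return cls(names=names, mean=mean, sd=sd, transforms=spec)

    def logpdf(self, vec: np.ndarray) -> float:
        z = (vec - self.mean) / self.sd
        return float(-0.5 * np.sum(z**2) - np.sum(np.log(self.sd)) - 0.5 * len(vec) * np.log(2 * np.pi))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=(n, len(self.names)))

    def with_moments(self, mean: np.ndarray, sd: np.ndarray) -> "GroupPrior":
        return GroupPrior(self.names, mean, np.maximum(sd, _SD_FLOOR), self.transforms)

    def native_means(self) -> dict[str, float]:
        return self.transforms.untransform(self.mean)


@dataclass
class SubjectFit:
    """Per-subject MAP fit in transformed space plus Laplace covariance."""

    subject_id: str
    map_transformed: np.ndarray
    cov: np.ndarray
    loglik: float  # data log-likelihood at the MAP
    logpost: float
    n_observed: int
    names: tuple[str, ...] = ()

    def native(self, transforms: TransformSpec) -> dict[str, float]:
        return transforms.untransform(self.map_transformed)


@dataclass
class FitResult:
    """Cohort-level fit: subject fits, final group prior, EM trajectory."""

    subject_fits: list[SubjectFit]
    prior: GroupPrior
    history: list[dict] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def total_loglik(self) -> float:
        return float(sum(f.loglik for f in self.subject_fits))

    def parameter_table(self) -> pd.DataFrame:
        """One row per subject: transformed and native MAP estimates."""
        rows = []
        for f in self.subject_fits:
            row = {"subject_id": f.subject_id, "loglik": f.loglik}
            for n, v in zip(self.prior.names, f.map_transformed):
                row[f"{n}_transformed"] = v
            row.update(f.native(self.prior.transforms))
            rows.append(row)
        return pd.DataFrame(rows)


def _neg_log_posterior(model, arr: SessionArrays, prior: GroupPrior):
    spec = prior.transforms

    def f(y: np.ndarray) -> float:
        values = spec.untransform(y)
        try:
            ll = model.loglik(arr, values)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -(ll + prior.logpdf(y))

    return f


def _numerical_hessian(f, y: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(y)
    H = np.empty((n, n))
    steps = h * np.maximum(1.0, np.abs(y))
    f0 = f(y)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(y + ei) - 2 * f0 + f(y - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(y + ei + ej) - f(y + ei - ej) - f(y - ei + ej) + f(y - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


def _laplace_cov(H: np.ndarray) -> np.ndarray:
    """Invert a Hessian, clipping eigenvalues to keep it positive definite."""
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    w = np.clip(w, 1e-6, None)
    return V @ np.diag(1.0 / w) @ V.T


def fit_subject(
    session: Session | SessionArrays,
    model,
    prior: GroupPrior,
    starts: int = 5,
    seed: int | np.random.Generator = 0,
    subject_id: str | None = None,
) -> SubjectFit:
    """MAP estimate of one subject's transformed parameters under the prior.

    Multi-start L-BFGS from the prior mean plus seeded jitter; the best
    optimum wins.  A session with no observed responses returns the prior
    mean with the prior covariance.
    """
    if isinstance(session, Session):
        sid = subject_id if subject_id is not None else session.subject_id
        arr = session.to_arrays()
    else:
        sid = subject_id if subject_id is not None else "subject"
        arr = session
    if arr.n_trials == 0 or arr.n_observed == 0:
        return SubjectFit(
            subject_id=sid,
            map_transformed=prior.mean.copy(),
            cov=np.diag(prior.sd**2),
            loglik=0.0,
            logpost=prior.logpdf(prior.mean),
            n_observed=0,
            names=prior.names,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = _neg_log_posterior(model, arr, prior)
    best = None
    for k in range(max(1, starts)):
        y0 = prior.mean.copy()
        if k > 0:
            y0 = y0 + 0.5 * prior.sd * rng.standard_normal(len(y0))
        res = optimize.minimize(f, y0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("optimizer failed on all starts")
    y_hat = best.x
    cov = _laplace_cov(_numerical_hessian(f, y_hat))
    ll = model.loglik(arr, prior.transforms.untransform(y_hat))
    return SubjectFit(
        subject_id=sid,
        map_transformed=y_hat,
        cov=cov,
        loglik=float(ll),
        logpost=float(-best.fun),
        n_observed=arr.n_observed,
        names=prior.names,
    )


def em_fit(
    sessions: list[Session],
    model,
    init: GroupPrior | None = None,
    max_iter: int = 20,
    tol: float = 1e-3,
    starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Empirical-Bayes EM over a cohort.

    E-step: per-subject MAP + Laplace covariance under the current group
    prior.  M-step: group mean is the average MAP; group variance is the
    average second moment (MAP^2 + Laplace variance) minus the squared
    mean, floored at a small value.  Stops when transformed group means
    move by less than ``tol`` or after ``max_iter`` iterations.
    """
    if len(sessions) < 2:
        raise ValueError("em_fit needs at least 2 subjects")
    prior = init if init is not None else model.default_prior()
    arrays = [s.to_arrays() for s in sessions]
    ids = [s.subject_id for s in sessions]
    rng = np.random.default_rng(seed)
    history: list[dict] = []
    fits: list[SubjectFit] = []
    converged = False
    prev_objective = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        fits = [
            fit_subject(arr, model, prior, starts=starts, seed=rng, subject_id=sid)
            for arr, sid in zip(arrays, ids)
        ]
        maps = np.array([f.map_transformed for f in fits])
        variances = np.array([np.diag(f.cov) for f in fits])
        mean = maps.mean(axis=0)
        var = (maps**2 + variances).mean(axis=0) - mean**2
        sd = np.sqrt(np.maximum(var, _SD_FLOOR**2))
        objective = float(sum(f.logpost for f in fits))
        if objective < prev_objective - 1e-6:
            warnings.warn(
                f"EM objective decreased at iteration {it} "
                f"({prev_objective:.3f} -> {objective:.3f}); Laplace approximation",
                stacklevel=2,
            )
        prev_objective = objective
        delta = float(np.max(np.abs(mean - prior.mean)))
        if not np.all(np.isfinite(mean)) or not np.all(np.isfinite(sd)):
            raise RuntimeError("EM diverged: non-finite group moments")
        history.append(
            {"iter": it, "mean": mean.copy(), "sd": sd.copy(),
             "objective": objective, "delta_mean": delta}
        )
        prior = prior.with_moments(mean, sd)
        if delta < tol:
            converged = True
            break
    return FitResult(
        subject_fits=fits, prior=prior, history=history,
        converged=converged, n_iter=it,
    )
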