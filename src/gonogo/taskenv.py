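"""Generative process and trial-record schema for the orthogonalized go/no-go task.

The task crosses action (go vs. no-go) with outcome valence (win vs. avoid
loss), yielding four cued contexts that are interleaved at random within a
session.  Feedback is probabilistic: the action-appropriate outcome is
delivered with probability ``feedback_validity`` (0.8 by default), the other
outcome otherwise.  Win contexts pay out in {+1, 0}, loss contexts in
{0, -1} (unit returns standing in for the +/-10 pence task currency).

Every other module consumes the :class:`Session` container defined here.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Context",
    "CONTEXTS",
    "TrialRecord",
    "Session",
    "SessionArrays",
    "make_schedule",
    "emit_outcome",
    "read_session",
    "write_session",
    "SessionValidationError",
]

GO, NOGO, MISSING = "go", "nogo", "missing"


class Context(enum.Enum):
    """One of the four task contexts: valence x correct action."""

    G2W = ("win", GO)
    G2AL = ("loss", GO)
    NG2W = ("win", NOGO)
    NG2AL = ("loss", NOGO)

    def __init__(self, valence: str, correct_action: str):
        self.valence = valence
        self.correct_action = correct_action

    @property
    def index(self) -> int:
        return _CONTEXT_INDEX[self]

    @property
    def is_win(self) -> bool:
        return self.valence == "win"

    @property
    def outcomes(self) -> tuple[int, int]:
        """(better, worse) outcome pair available in this valence."""
        return (1, 0) if self.is_win else (0, -1)


CONTEXTS: tuple[Context, ...] = (
    Context.G2W,
    Context.G2AL,
    Context.NG2W,
    Context.NG2AL,
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS)}

#: per-context valence flag (1 = win) and correct action (1 = go), indexed
#: in CONTEXTS order; used by the numerical model kernels.
CONTEXT_IS_WIN = np.array([int(c.is_win) for c in CONTEXTS], dtype=np.int64)
CONTEXT_CORRECT_GO = np.array(
    [int(c.correct_action == GO) for c in CONTEXTS], dtype=np.int64
)


class SessionValidationError(ValueError):
    """Raised when a trial table violates the task schema."""


@dataclass(frozen=True)
class TrialRecord:
    """A single trial of one subject's session.

    ``t_within`` counts prior trials of the same context (0-based) and
    ``n_gap`` is the number of trials since this context last occurred
    (1 for consecutive trials; 1 by convention on the first trial of a
    chain, where no forgetting is applied anyway).
    """

    subject_id: str
    trial: int
    context: Context
    t_within: int
    n_gap: int
    action: str
    outcome: int

    def __post_init__(self):
        if self.action not in (GO, NOGO, MISSING):
            raise SessionValidationError(f"unknown action {self.action!r}")
        allowed = (1, 0) if self.context.is_win else (0, -1)
        if self.outcome not in allowed:
            raise SessionValidationError(
                f"outcome {self.outcome} invalid in {self.context.name} "
                f"({self.context.valence} valence)"
            )
        if self.n_gap < 1:
            raise SessionValidationError("n_gap must be >= 1")


@dataclass
class SessionArrays:
    """Dense integer view of a session used by the likelihood kernels.

    ``action`` codes go=1, nogo=0, missing=-1; ``context`` indexes
    :data:`CONTEXTS`; ``first_of_chain`` marks the first trial of each
    context chain.
    """

    context: np.ndarray
    t_within: np.ndarray
    n_gap: np.ndarray
    action: np.ndarray
    outcome: np.ndarray
    first_of_chain: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.context.size)

    @property
    def n_observed(self) -> int:
        return int(np.sum(self.action >= 0))


@dataclass
class Session:
    """One subject's ordered trial records across the four context chains."""

    subject_id: str
    trials: list[TrialRecord] = field(default_factory=list)
    trials_per_context: int = 36
    feedback_validity: float = 0.8

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [t.subject_id for t in self.trials],
                "trial": [t.trial for t in self.trials],
                "context": [t.context.name for t in self.trials],
                "t_within": [t.t_within for t in self.trials],
                "n_gap": [t.n_gap for t in self.trials],
                "action": [t.action for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
            }
        )

    def to_arrays(self) -> SessionArrays:
        ctx = np.array([t.context.index for t in self.trials], dtype=np.int64)
        act = np.array(
            [1 if t.action == GO else (0 if t.action == NOGO else -1) for t in self.trials],
            dtype=np.int64,
        )
        t_within = np.array([t.t_within for t in self.trials], dtype=np.int64)
        return SessionArrays(
            context=ctx,
            t_within=t_within,
            n_gap=np.array([t.n_gap for t in self.trials], dtype=np.int64),
            action=act,
            outcome=np.array([t.outcome for t in self.trials], dtype=np.int64),
            first_of_chain=(t_within == 0),
        )


def make_schedule(trials_per_context: int, seed: int | np.random.Generator) -> list[Context]:
    """Uniformly shuffled interleaving of the four contexts.

    Each context appears exactly ``trials_per_context`` times; the
    permutation is unconstrained (no run-length cap) and deterministic
    given ``seed``.
    """
    if trials_per_context < 1:
        raise ValueError("trials_per_context must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = rng.permutation(np.repeat(np.arange(4), trials_per_context))
    return [CONTEXTS[i] for i in order]


def emit_outcome(
    context: Context, action: str, validity: float, rng: np.random.Generator
) -> int:
    """Sample the probabilistic feedback for one trial.

    With probability ``validity`` the action-appropriate outcome is
    delivered: the better outcome of the valence if the action is correct,
    the worse one otherwise.  With probability 1 - validity the other
    outcome is delivered.
    """
    if not 0.0 <= validity <= 1.0:
        raise ValueError("validity must lie in [0, 1]")
    better, worse = context.outcomes
    appropriate = better if action == context.correct_action else worse
    other = worse if appropriate == better else better
    return appropriate if rng.random() < validity else other


def schedule_metadata(schedule: list[Context]) -> tuple[list[int], list[int]]:
    """Per-trial (t_within, n_gap) implied by an ordered context schedule."""
    counts = {c: 0 for c in CONTEXTS}
    last_seen: dict[Context, int] = {}
    t_within, n_gap = [], []
    for i, c in enumerate(schedule):
        t_within.append(counts[c])
        n_gap.append(i - last_seen[c] if c in last_seen else 1)
        counts[c] += 1
        last_seen[c] = i
    return t_within, n_gap


def build_session(
    subject_id: str,
    schedule: list[Context],
    actions: list[str],
    outcomes: list[int],
    feedback_validity: float = 0.8,
) -> Session:
    """Assemble a validated Session from parallel per-trial lists."""
    t_within, n_gap = schedule_metadata(schedule)
    trials = [
        TrialRecord(subject_id, i, c, t_within[i], n_gap[i], actions[i], outcomes[i])
        for i, c in enumerate(schedule)
    ]
    n_per = len(schedule) // 4 if schedule else 0
    return Session(subject_id, trials, trials_per_context=n_per, feedback_validity=feedback_validity)


_COLUMNS = ["subject_id", "trial", "context", "t_within", "n_gap", "action", "outcome"]


def write_session(session: Session, path) -> None:
    """Write one session as UTF-8 comma-delimited text (header mandatory)."""
    session.to_frame().to_csv(path, index=False)


def sessions_to_frame(sessions: list[Session]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in sessions], ignore_index=True)


def write_sessions(sessions: list[Session], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def _session_from_frame(df: pd.DataFrame, subject_id: str) -> Session:
    trials = []
    for _, row in df.iterrows():
        try:
            ctx = Context[str(row["context"])]
        except KeyError as exc:
            raise SessionValidationError(f"unknown context label {row['context']!r}") from exc
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                trial=int(row["trial"]),
                context=ctx,
                t_within=int(row["t_within"]),
                n_gap=int(row["n_gap"]),
                action=str(row["action"]),
                outcome=int(row["outcome"]),
            )
        )
    # consistency of within-chain counters
    counts = {c: 0 for c in CONTEXTS}
    for t in trials:
        if t.t_within != counts[t.context]:
            raise SessionValidationError(
                f"subject {subject_id}: t_within {t.t_within} out of order in "
                f"{t.context.name} (expected {counts[t.context]})"
            )
        counts[t.context] += 1
    n_per = max(counts.values()) if trials else 0
    return Session(subject_id, trials, trials_per_context=n_per)


def read_session(path) -> Session:
    """Read a single-subject session file; inverse of :func:`write_session`."""
    sessions = read_sessions(path)
    if not sessions:
        return Session(subject_id="", trials=[])
    if len(sessions) > 1:
        raise SessionValidationError("file contains multiple subjects; use read_sessions")
    return sessions[0]


def read_sessions(path) -> list[Session]:
    """Read a multi-subject trial table, one Session per subject."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty session file", stacklevel=2)
        return []
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise SessionValidationError(f"missing columns: {missing_cols}")
    if df.empty:
        warnings.warn(f"{path}: no trial rows", stacklevel=2)
        return []
    out = []
    for sid, sub in df.groupby("subject_id", sort=False):
        out.append(_session_from_frame(sub.sort_values("trial"), str(sid)))
    return out
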