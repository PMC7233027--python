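"""Hand-defined behavioral summaries.

Three model-free descriptions of a subject's responding:

* decision point / consistency -- split a context's signed action
  sequence (go = +1, no-go = -1) at the point d that maximizes
  |sum(a_1..a_d)| + |sum(a_{d+1}..a_n)|, i.e. allow at most one change
  of mind and measure how consistent the two segments are;
* normalized switches -- the per-context fraction of consecutive
  observed responses that differ, averaged over the four contexts;
* accuracy curves -- mean proportion correct per context by within-chain
  trial, with a last-k window (default 20 trials) used to flag subjects
  responding above chance in every context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .taskenv import CONTEXTS, GO, MISSING, Context, Session

__all__ = [
    "decision_point",
    "normalized_switches",
    "accuracy_curves",
    "BehaviorSummary",
    "summarize_cohort",
]


def decision_point(actions: np.ndarray | list[int]) -> tuple[int, int]:
    """(d, con): earliest split maximizing two-segment consistency.

    ``actions`` is a signed sequence with entries in {-1, +1} (missing
    trials must be excluded beforehand).  d ranges over 0..n inclusive;
    d = 0 means the first segment is empty (the subject never changed
    their mind).  Ties go to the earliest d.
    """
    a = np.asarray(actions, dtype=float)
    if a.size == 0:
        raise ValueError("empty action sequence")
    if not np.all(np.isin(a, (-1.0, 1.0))):
        raise ValueError("actions must be coded -1 / +1")
    prefix = np.concatenate([[0.0], np.cumsum(a)])  # prefix[d] = sum of first d
    total = prefix[-1]
    con = np.abs(prefix) + np.abs(total - prefix)  # one value per d in 0..n
    d = int(np.argmax(con))  # argmax returns the earliest maximizer
    return d, int(con[d])


def _signed_chain(session: Session, context: Context) -> np.ndarray:
    vals = [
        1 if t.action == GO else -1
        for t in session.trials
        if t.context is context and t.action != MISSING
    ]
    return np.array(vals, dtype=int)


def normalized_switches(session: Session) -> float:
    """Mean over contexts of the fraction of consecutive response changes.

    Computed within each context chain (switching between contexts is not
    a change of policy); the denominator is the number of observed
    consecutive pairs, so the value is bounded in [0, 1].
    """
    per_context = []
    for context in CONTEXTS:
        a = _signed_chain(session, context)
        if a.size < 2:
            raise ValueError(
                f"context {context.name} has fewer than 2 observed trials"
            )
        per_context.append(float(np.mean(a[1:] != a[:-1])))
    return float(np.mean(per_context))


@dataclass
class BehaviorSummary:
    """Cohort-level behavioral description."""

    curves: pd.DataFrame  # context, t_within, p_correct, n
    last_k: pd.DataFrame  # subject_id, context, accuracy
    above_chance: pd.Series  # subject_id -> bool (>50% correct in every context)
    per_subject: pd.DataFrame  # subject_id, normalized_switches, and per-context d/con


def accuracy_curves(sessions: list[Session], last_k: int = 20) -> BehaviorSummary:
    """Per-context accuracy by within-chain trial plus last-k summaries."""
    rows = []
    for s in sessions:
        for t in s.trials:
            if t.action == MISSING:
                continue
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "context": t.context.name,
                    "t_within": t.t_within,
                    "correct": int(t.action == t.context.correct_action),
                }
            )
    df = pd.DataFrame(rows)
    curves = (
        df.groupby(["context", "t_within"])["correct"]
        .agg(p_correct="mean", n="size")
        .reset_index()
    )
    max_t = df.groupby(["subject_id", "context"])["t_within"].transform("max")
    tail = df[df["t_within"] > max_t - last_k]
    last = (
        tail.groupby(["subject_id", "context"])["correct"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    above = last.groupby("subject_id")["accuracy"].agg(lambda a: bool((a > 0.5).all()))
    per_subject_rows = []
    for s in sessions:
        row: dict = {"subject_id": s.subject_id}
        try:
            row["normalized_switches"] = normalized_switches(s)
        except ValueError:
            row["normalized_switches"] = np.nan
        for context in CONTEXTS:
            chain = _signed_chain(s, context)
            if chain.size:
                d, con = decision_point(chain)
                row[f"d_{context.name}"] = d
                row[f"con_{context.name}"] = con
        per_subject_rows.append(row)
    return BehaviorSummary(
        curves=curves,
        last_k=last,
        above_chance=above,
        per_subject=pd.DataFrame(per_subject_rows),
    )


def summarize_cohort(sessions: list[Session], last_k: int = 20) -> BehaviorSummary:
    """Alias for :func:`accuracy_curves` emphasizing the full summary."""
    return accuracy_curves(sessions, last_k=last_k)
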