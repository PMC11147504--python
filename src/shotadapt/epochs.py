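"""Epoch segmentation of a session's trial timeline.

The statistical contrasts operate on *epochs*: contiguous trial groups
defined relative to the perturbation events.  For the single-perturbation
design (exp1) there are six epochs::

    1  baseline trials
    2  first two trials after airflow onset
    3  third perturbation trial up to two before airflow offset
    4  last two perturbation trials
    5  first two washout trials
    6  remaining washout trials

For the direction-reversal design (exp2) there are nine, with epochs 4/5
bracketing the reversal and 7/8 bracketing airflow offset.  Boundary epochs
(2, 4, 5; plus 7, 8 for exp2) cover exactly two trials whenever the phase is
long enough; the "middle" epochs (3, 6, 9) may be empty — e.g. a
four-trial perturbation block is entirely epochs 2 and 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trials import Session, SessionSet

N_EPOCHS = {"exp1": 6, "exp2": 9}


class EpochAssignmentError(ValueError):
    """A phase too short to host its two-trial boundary epochs."""


@dataclass(frozen=True)
class EpochSchedule:
    """Design-specific mapping from trial position to epoch label."""

    design: str

    @property
    def n_epochs(self) -> int:
        return N_EPOCHS[self.design]


def _bracketed(n: int, first: int, middle: int, last: int, where: str) -> list[int]:
    """Labels for a phase whose first two and last two trials are epochs."""
    if n < 4:
        raise EpochAssignmentError(
            f"{where} has {n} trials; at least 4 are needed so the "
            f"two-trial boundary epochs {first} and {last} do not overlap"
        )
    return [first] * 2 + [middle] * (n - 4) + [last] * 2


def _leading(n: int, first: int, rest: int) -> list[int]:
    """First two trials -> `first`, remainder -> `rest`."""
    k = min(n, 2)
    return [first] * k + [rest] * (n - k)


def assign_epochs(session: Session) -> np.ndarray:
    """Epoch label (1-based) for every trial of a session, in order.

    Raises
    ------
    EpochAssignmentError
        If a perturbation phase has fewer than 4 trials.
    """
    lengths = session.phase_lengths()
    b = lengths.get("baseline", 0)
    p = lengths.get("perturbation", 0)
    w = lengths.get("washout", 0)
    who = f"session {session.session_id!r} of fish {session.fish_id!r}"
    if session.design == "exp1":
        labels = (
            [1] * b
            + _bracketed(p, 2, 3, 4, f"perturbation of {who}")
            + _leading(w, 5, 6)
        )
    else:
        r = lengths.get("perturbation_reversed", 0)
        labels = (
            [1] * b
            + _bracketed(p, 2, 3, 4, f"perturbation of {who}")
            + _bracketed(r, 5, 6, 7, f"reversed perturbation of {who}")
            + _leading(w, 8, 9)
        )
    out = np.asarray(labels, dtype=np.int64)
    assert len(out) == len(session)
    return out


def epoch_counts(session: Session) -> np.ndarray:
    """Trials per epoch (index 0 = epoch 1); sums to the session length."""
    labels = assign_epochs(session)
    n = N_EPOCHS[session.design]
    return np.bincount(labels - 1, minlength=n)


def annotate_sessions(sessions: SessionSet) -> pd.DataFrame:
    """Cohort DataFrame with an added ``epoch`` column."""
    df = sessions.to_dataframe()
    labels = np.concatenate(
        [assign_epochs(s) for s in sessions.sessions]
    ) if len(sessions) else np.empty(0, dtype=np.int64)
    df["epoch"] = labels
    return df
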