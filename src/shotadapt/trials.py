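"""Per-shot trial records: data model, validation, and CSV I/O.

A *trial* is one water-jet shot with a signed error in millimetres along the
airflow axis (positive = deflection in the direction the airflow pushes the
jet).  Trials are grouped into *sessions* — one uninterrupted sequence of
shots by one fish under a baseline / perturbation (/ reversed perturbation) /
washout schedule — and sessions into a :class:`SessionSet` spanning the whole
cohort.

The canonical on-disk form is a flat CSV with columns
``fish_id,session_id,trial_index,design,airflow_direction,phase,error_mm``
(UTF-8, comma-separated, "." decimal).  ``read_sessions`` also accepts a
directory of per-fish CSVs, which are concatenated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

PHASES = ("baseline", "perturbation", "perturbation_reversed", "washout")
_PHASE_RANK = {p: i for i, p in enumerate(PHASES)}

DESIGNS = ("exp1", "exp2")
AIRFLOW_DIRECTIONS = ("with_shot", "against_shot")

CSV_COLUMNS = [
    "fish_id",
    "session_id",
    "trial_index",
    "design",
    "airflow_direction",
    "phase",
    "error_mm",
]

#: inclusive per-phase block-length bounds for each experimental design;
#: ``None`` means unbounded above
DESIGN_BLOCK_BOUNDS = {
    "exp1": {
        "baseline": (5, 10),
        "perturbation": (10, 15),
        "washout": (5, 10),
    },
    "exp2": {
        "baseline": (5, 10),
        "perturbation": (8, 12),
        "perturbation_reversed": (15, 20),
        "washout": (5, None),
    },
}


class CSVParseError(ValueError):
    """A malformed row or header in a session CSV."""


class SessionValidationError(ValueError):
    """A session violating the trial/phase structural invariants."""


@dataclass(frozen=True)
class Trial:
    """One shot: 1-based trial index, schedule phase, signed error in mm."""

    fish_id: str
    session_id: str
    trial_index: int
    phase: str
    error_mm: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise SessionValidationError(
                f"unknown phase {self.phase!r}; expected one of {PHASES}"
            )
        if self.trial_index < 1:
            raise SessionValidationError(
                f"trial_index must be >= 1, got {self.trial_index}"
            )
        if not math.isfinite(self.error_mm):
            raise SessionValidationError(
                f"non-finite error_mm in trial {self.trial_index} "
                f"of session {self.session_id!r}"
            )


@dataclass(frozen=True)
class Session:
    """An ordered run of trials by one fish under one schedule.

    Structural invariants (consecutive 1-based trial indices, monotone phase
    order baseline -> perturbation (-> perturbation_reversed) -> washout,
    finite errors) are enforced on construction.  Design block-length bounds
    (e.g. 5-10 baseline trials for exp1) describe how the experiments were
    run and are checked separately via :meth:`check_design_bounds`, so that
    truncated or toy sessions remain representable.
    """

    fish_id: str
    session_id: str
    design: str
    airflow_direction: str
    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise SessionValidationError(f"unknown design {self.design!r}")
        if self.airflow_direction not in AIRFLOW_DIRECTIONS:
            raise SessionValidationError(
                f"unknown airflow_direction {self.airflow_direction!r}"
            )
        object.__setattr__(self, "trials", tuple(self.trials))
        prev_rank = -1
        for pos, t in enumerate(self.trials, start=1):
            if t.fish_id != self.fish_id or t.session_id != self.session_id:
                raise SessionValidationError(
                    f"trial {pos} of session {self.session_id!r} carries "
                    f"ids ({t.fish_id!r}, {t.session_id!r}) that do not "
                    f"match the session"
                )
            if t.trial_index != pos:
                raise SessionValidationError(
                    f"session {self.session_id!r} of fish {self.fish_id!r}: "
                    f"trial_index {t.trial_index} at position {pos}; indices "
                    f"must be consecutive from 1"
                )
            rank = _PHASE_RANK[t.phase]
            if rank < prev_rank:
                raise SessionValidationError(
                    f"session {self.session_id!r} of fish {self.fish_id!r}: "
                    f"phase {t.phase!r} follows a later phase; order must be "
                    f"baseline -> perturbation (-> perturbation_reversed) "
                    f"-> washout"
                )
            if t.phase == "perturbation_reversed" and self.design != "exp2":
                raise SessionValidationError(
                    f"phase 'perturbation_reversed' only occurs in exp2 "
                    f"(session {self.session_id!r})"
                )
            prev_rank = rank

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def errors(self) -> list[float]:
        return [t.error_mm for t in self.trials]

    @property
    def phases(self) -> list[str]:
        return [t.phase for t in self.trials]

    def phase_lengths(self) -> dict[str, int]:
        """Number of trials in each phase present in this session."""
        out: dict[str, int] = {}
        for t in self.trials:
            out[t.phase] = out.get(t.phase, 0) + 1
        return out

    def check_design_bounds(self) -> None:
        """Raise if phase block lengths fall outside the design's bounds."""
        bounds = DESIGN_BLOCK_BOUNDS[self.design]
        lengths = self.phase_lengths()
        for phase, (lo, hi) in bounds.items():
            n = lengths.get(phase, 0)
            if n < lo or (hi is not None and n > hi):
                raise SessionValidationError(
                    f"session {self.session_id!r} of fish {self.fish_id!r}: "
                    f"{phase} block has {n} trials, outside the {self.design} "
                    f"bounds [{lo}, {hi if hi is not None else 'inf'}]"
                )
        extra = set(lengths) - set(bounds)
        if extra:
            raise SessionValidationError(
                f"session {self.session_id!r}: phases {sorted(extra)} not "
                f"part of design {self.design!r}"
            )


@dataclass(frozen=True)
class SessionSet:
    """A cohort of sessions; (fish_id, session_id) pairs are unique."""

    sessions: tuple[Session, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sessions", tuple(self.sessions))
        seen = set()
        for s in self.sessions:
            key = (s.fish_id, s.session_id)
            if key in seen:
                raise SessionValidationError(
                    f"duplicate (fish_id, session_id) pair {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self) -> Iterator[Session]:
        return iter(self.sessions)

    @property
    def n_trials(self) -> int:
        return sum(len(s) for s in self.sessions)

    @property
    def fish_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.sessions:
            if s.fish_id not in out:
                out.append(s.fish_id)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (
                s.fish_id,
                s.session_id,
                t.trial_index,
                s.design,
                s.airflow_direction,
                t.phase,
                t.error_mm,
            )
            for s in self.sessions
            for t in s.trials
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SessionSet":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise CSVParseError(f"missing columns: {missing}")
        sessions = []
        for (fish, sess), grp in df.groupby(
            ["fish_id", "session_id"], sort=False
        ):
            design = str(grp["design"].iloc[0])
            direction = str(grp["airflow_direction"].iloc[0])
            trials = tuple(
                Trial(
                    fish_id=str(fish),
                    session_id=str(sess),
                    trial_index=int(r.trial_index),
                    phase=str(r.phase),
                    error_mm=float(r.error_mm),
                )
                for r in grp.itertuples()
            )
            sessions.append(
                Session(
                    fish_id=str(fish),
                    session_id=str(sess),
                    design=design,
                    airflow_direction=direction,
                    trials=trials,
                )
            )
        return cls(tuple(sessions))


def _read_one_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CSVParseError(f"{path}: header is missing columns {missing}")
    for col, caster in (("trial_index", int), ("error_mm", float)):
        values = []
        for pos, raw in enumerate(df[col]):
            try:
                # python parsers are correctly rounded, so written values
                # read back bit-exactly
                values.append(caster(raw))
            except (TypeError, ValueError):
                # +2: 1-based data rows after the header line
                raise CSVParseError(
                    f"{path}: row {pos + 2}: cannot parse {col}={raw!r}"
                ) from None
        df[col] = values
    return df


def read_sessions(path: str | Path, strict: bool = False) -> SessionSet:
    """Read a session CSV (or a directory of them) into a SessionSet.

    Parameters
    ----------
    path : str or Path
        A CSV file, or a directory whose ``*.csv`` files (sorted by name)
        are concatenated.
    strict : bool
        Also enforce the design's phase block-length bounds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise CSVParseError(f"{path}: no CSV files found")
        df = pd.concat([_read_one_csv(f) for f in files], ignore_index=True)
    else:
        df = _read_one_csv(path)
    sessions = SessionSet.from_dataframe(df)
    if strict:
        for s in sessions:
            s.check_design_bounds()
    return sessions


def write_sessions(sessions: SessionSet, path: str | Path) -> None:
    """Write a SessionSet to the canonical CSV (round-trips exactly)."""
    df = sessions.to_dataframe()
    # 17 significant digits round-trip any double exactly and deterministically
    df.to_csv(path, index=False, float_format="%.17g")


def concat_session_sets(sets: Iterable[SessionSet]) -> SessionSet:
    sessions: list[Session] = []
    for s in sets:
        sessions.extend(s.sessions)
    return SessionSet(tuple(sessions))
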