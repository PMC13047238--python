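"""Core domain types for the progressive illness-death model.

The process has three states: 0 (disease-free), 1 (diseased), 2 (dead).
Only the transitions 0->1, 0->2 and 1->2 are possible; state 2 is
absorbing and disease is irreversible.  The disease state doubles as a
binary time-dependent marker X(t): X(t)=1 once the subject has entered
state 1.

Disease is only observed at scheduled visits, so the illness time is
interval-censored: it is known to lie in the half-open interval (L, R]
between the last negative and the first positive screen.  Death (or
censoring) times T* are observed exactly.  A subject whose last screen
before death was negative has unknown terminal disease status.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

#: allowed transitions of the progressive illness-death chain
TRANSITIONS = ("01", "02", "12")

#: state labels
HEALTHY, DISEASED, DEAD = 0, 1, 2


class DataError(ValueError):
    """Raised when subject-level records violate the observation scheme."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's visit history plus survival outcome.

    Attributes
    ----------
    id : str
        Subject identifier.
    visit_times : ndarray
        Strictly increasing visit times in months, starting at 0.
    marker : ndarray
        Binary disease marker observed at each visit; non-decreasing
        (disease is irreversible).
    tstar : float
        End of follow-up T* (death or censoring time, months).
    delta : int
        Death indicator (1 = died at ``tstar``).
    """

    id: str
    visit_times: np.ndarray
    marker: np.ndarray
    tstar: float
    delta: int

    def __post_init__(self) -> None:
        vt = np.asarray(self.visit_times, dtype=float)
        mk = np.asarray(self.marker, dtype=int)
        object.__setattr__(self, "visit_times", vt)
        object.__setattr__(self, "marker", mk)
        if vt.ndim != 1 or vt.size == 0:
            raise DataError(f"subject {self.id}: empty visit grid")
        if vt.size != mk.size:
            raise DataError(f"subject {self.id}: visits and marker differ in length")
        if np.any(np.diff(vt) <= 0):
            raise DataError(f"subject {self.id}: visit times not strictly increasing")
        if not np.all(np.isin(mk, (0, 1))):
            raise DataError(f"subject {self.id}: marker must be 0/1")
        if np.any(np.diff(mk) < 0):
            raise DataError(f"subject {self.id}: non-monotone marker (disease is irreversible)")
        if vt[-1] > self.tstar + 1e-9:
            raise DataError(f"subject {self.id}: visit after end of follow-up")
        if self.delta not in (0, 1):
            raise DataError(f"subject {self.id}: delta must be 0/1")


@dataclass(frozen=True)
class IntervalSummary:
    """Interval-censored summary (L, R, T*, delta) of one subject.

    ``L`` is the last visit with a negative screen, ``R`` the first
    positive visit (``None`` if disease was never observed).  The
    censoring interval is half-open: illness occurred in (L, R].
    """

    id: str
    L: float
    R: Optional[float]
    tstar: float
    delta: int

    def __post_init__(self) -> None:
        if self.R is not None and not (self.L < self.R <= self.tstar + 1e-9):
            raise DataError(f"subject {self.id}: need L < R <= tstar")
        if self.L > self.tstar + 1e-9:
            raise DataError(f"subject {self.id}: L > tstar")


class PanelDataset:
    """A collection of :class:`SubjectRecord` with CSV (de)serialization.

    On disk the panel is long-format ``id,time,marker`` and the outcome
    file is ``id,tstar,delta``.
    """

    def __init__(self, subjects: Sequence[SubjectRecord]):
        self.subjects = list(subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __getitem__(self, i: int) -> SubjectRecord:
        return self.subjects[i]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (panel, outcomes) data frames in canonical long format."""
        rows = [
            (s.id, t, int(x))
            for s in self.subjects
            for t, x in zip(s.visit_times, s.marker)
        ]
        panel = pd.DataFrame(rows, columns=["id", "time", "marker"])
        outcomes = pd.DataFrame(
            [(s.id, s.tstar, s.delta) for s in self.subjects],
            columns=["id", "tstar", "delta"],
        )
        return panel, outcomes

    @classmethod
    def from_frames(cls, panel: pd.DataFrame, outcomes: pd.DataFrame) -> "PanelDataset":
        out = outcomes.set_index("id")
        subjects = []
        for sid, grp in panel.groupby("id", sort=False):
            grp = grp.sort_values("time")
            subjects.append(
                SubjectRecord(
                    id=str(sid),
                    visit_times=grp["time"].to_numpy(float),
                    marker=grp["marker"].to_numpy(int),
                    tstar=float(out.loc[sid, "tstar"]),
                    delta=int(out.loc[sid, "delta"]),
                )
            )
        return cls(subjects)

    def write_csv(self, panel_path, outcomes_path) -> None:
        panel, outcomes = self.to_frames()
        panel.to_csv(panel_path, index=False)
        outcomes.to_csv(outcomes_path, index=False)

    @classmethod
    def read_csv(cls, panel_path, outcomes_path) -> "PanelDataset":
        return cls.from_frames(pd.read_csv(panel_path), pd.read_csv(outcomes_path))


def summarize_intervals(data: PanelDataset | Iterable[SubjectRecord]) -> list[IntervalSummary]:
    """Reduce visit histories to interval-censored summaries (L, R, T*, delta).

    L is the last negative visit (0 when the very first screen is already
    positive); R is the first positive visit, absent when disease was
    never observed.
    """
    out = []
    for s in data:
        pos = np.flatnonzero(s.marker == 1)
        if pos.size:
            r = float(s.visit_times[pos[0]])
            L = float(s.visit_times[pos[0] - 1]) if pos[0] > 0 else 0.0
            out.append(IntervalSummary(s.id, L, r, float(s.tstar), int(s.delta)))
        else:
            out.append(
                IntervalSummary(s.id, float(s.visit_times[-1]), None, float(s.tstar), int(s.delta))
            )
    return out


def intervals_to_frame(intervals: Sequence[IntervalSummary]) -> pd.DataFrame:
    """Interval CSV layout: id,L,R,tstar,delta with empty field for absent R."""
    return pd.DataFrame(
        [(iv.id, iv.L, iv.R, iv.tstar, iv.delta) for iv in intervals],
        columns=["id", "L", "R", "tstar", "delta"],
    )


def intervals_from_frame(df: pd.DataFrame) -> list[IntervalSummary]:
    return [
        IntervalSummary(
            str(row.id),
            float(row.L),
            None if pd.isna(row.R) else float(row.R),
            float(row.tstar),
            int(row.delta),
        )
        for row in df.itertuples(index=False)
    ]


def validate_transprob(P: np.ndarray, atol: float = 1e-8) -> None:
    """Assert that P is a valid illness-death transition probability matrix."""
    P = np.asarray(P)
    if P.shape != (3, 3):
        raise ValueError("transition matrix must be 3x3")
    if np.any(P < -atol) or np.any(P > 1 + atol):
        raise ValueError("entries outside [0,1]")
    if not np.allclose(P.sum(axis=1), 1.0, atol=atol):
        raise ValueError("rows must sum to 1")
    if abs(P[2, 2] - 1.0) > atol or abs(P[1, 0]) > atol:
        raise ValueError("progressive structure violated")


class IllnessDeathModel(ABC):
    """Contract shared by the generating model and every fitted model.

    Implementations expose transition hazards, cumulative hazards,
    transition probability matrices P(s,t), and the ratio
    gamma(t) = lambda_12(t) / lambda_02(t) of the two death hazards,
    which drives the incident/dynamic AUC.
    """

    #: jump grid for step-function models (None for smooth hazards)
    jump_times: Optional[np.ndarray] = None

    @abstractmethod
    def hazard(self, tr: str, t: float) -> float:
        """Transition intensity lambda_tr(t) (rate per month)."""

    @abstractmethod
    def cumhaz(self, tr: str, t: float) -> float:
        """Cumulative hazard Lambda_tr(t)."""

    @abstractmethod
    def transprob(self, s: float, t: float) -> np.ndarray:
        """3x3 matrix P(s,t) with P[h,l] = Pr(V(t)=l | V(s)=h)."""

    @abstractmethod
    def death_hazard_ratio(self, t: float) -> float:
        """gamma(t) = lambda_12(t) / lambda_02(t)."""

    def transprob_left(self, s: float, t: float) -> np.ndarray:
        """P(s,t-): the left limit at t.

        For smooth models this equals ``transprob(s, t)``; step-function
        models override it to exclude jumps located exactly at t.
        """
        return self.transprob(s, t)
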