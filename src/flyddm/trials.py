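"""Domain types for two-choice decision data.

A :class:`Trial` is one decision by one fly: a walking-speed-normalized
reaction time, a correctness sign (+1 = exit into the arm carrying the lower
odor concentration, -1 = incorrect), a task difficulty ``x`` (log10 odor
concentration ratio, in [-1, +1] for the standard design), and the
photostimulation condition expressed as optical power in mW/mm^2 (0 for
unstimulated trials).

Reaction times are stored already normalized for walking speed and are
therefore dimensionless; raw seconds enter only through
:mod:`flyddm.kinematics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: canonical CSV column order
COLUMNS = ["fly_id", "difficulty", "light_mw_mm2", "rt", "choice"]


@dataclass(frozen=True)
class Trial:
    """A single decision.

    Parameters
    ----------
    rt : float
        Normalized reaction time, strictly positive (dimensionless).
    choice : int
        +1 for a correct choice, -1 for an incorrect one.
    difficulty : float
        Signed log10 concentration ratio x; finite.
    light : float
        Optical power of the photostimulation condition (mW/mm^2, >= 0).
    fly_id : str
        Animal identifier.
    """

    rt: float
    choice: int
    difficulty: float
    light: float = 0.0
    fly_id: str = "fly0"

    def __post_init__(self) -> None:
        if not self.rt > 0:
            raise ValidationError(f"rt must be > 0, got {self.rt!r}")
        if self.choice not in (-1, 1):
            raise ValidationError(f"choice must be +1 or -1, got {self.choice!r}")
        if not np.isfinite(self.difficulty):
            raise ValidationError(f"difficulty must be finite, got {self.difficulty!r}")
        if not self.light >= 0:
            raise ValidationError(f"light power must be >= 0, got {self.light!r}")


class TrialSet:
    """An ordered collection of :class:`Trial` objects.

    ``len(ts)`` is the number of decisions n that enters the BIC penalty.
    """

    def __init__(self, trials: Iterable[Trial]):
        self._trials = list(trials)

    def __len__(self) -> int:
        return len(self._trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self._trials)

    def __getitem__(self, i):
        out = self._trials[i]
        return TrialSet(out) if isinstance(i, slice) else out

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialSet):
            return NotImplemented
        return self._trials == other._trials

    def __repr__(self) -> str:
        return f"TrialSet(n={len(self)})"

    @property
    def n(self) -> int:
        return len(self)

    @property
    def difficulties(self) -> np.ndarray:
        """Sorted unique difficulty levels present."""
        return np.unique([t.difficulty for t in self])

    @property
    def lights(self) -> np.ndarray:
        """Sorted unique light powers present."""
        return np.unique([t.light for t in self])

    # -- array views used by the likelihood code ---------------------------
    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (rt, choice, difficulty) as float/int arrays."""
        rt = np.array([t.rt for t in self], dtype=float)
        choice = np.array([t.choice for t in self], dtype=int)
        x = np.array([t.difficulty for t in self], dtype=float)
        return rt, choice, x

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fly_id": [t.fly_id for t in self],
                "difficulty": [t.difficulty for t in self],
                "light_mw_mm2": [t.light for t in self],
                "rt": [t.rt for t in self],
                "choice": [t.choice for t in self],
            },
            columns=COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, source: str = "<frame>") -> "TrialSet":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{source}: missing required columns {missing}")
        trials = []
        bad: list[str] = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                trials.append(
                    Trial(
                        rt=float(row.rt),
                        choice=int(row.choice),
                        difficulty=float(row.difficulty),
                        light=float(row.light_mw_mm2),
                        fly_id=str(row.fly_id),
                    )
                )
            except (ValidationError, ValueError) as exc:
                # +2: one for the header line, one for 1-based numbering
                bad.append(f"line {i + 2}: {exc}")
        if bad:
            raise ValidationError(
                f"{source}: {len(bad)} malformed row(s):\n  " + "\n  ".join(bad[:20])
            )
        return cls(trials)


@dataclass
class ConditionSummary:
    """Per-(difficulty, light) summary: mean/SEM reaction time, accuracy, n.

    ``table`` is indexed by (difficulty, light) with columns
    ``mean_rt``, ``sem_rt``, ``accuracy``, ``n``.
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def n_total(self) -> int:
        return int(self.table["n"].sum())

    def cell(self, difficulty: float, light: float) -> pd.Series:
        return self.table.loc[(difficulty, light)]


def read_trials(
    path,
    *,
    column_map: Mapping[str, str] | None = None,
) -> TrialSet:
    """Read a trial table from CSV.

    Parameters
    ----------
    path : path-like
        CSV file with a header row; comma separated, '.' decimal.
    column_map : mapping, optional
        Maps canonical column names (``fly_id``, ``difficulty``,
        ``light_mw_mm2``, ``rt``, ``choice``) to the names used in the file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    return TrialSet.from_frame(df, source=str(path))


def write_trials(ts: TrialSet, path) -> None:
    """Write a trial table to CSV (inverse of :func:`read_trials`)."""
    ts.to_frame().to_csv(path, index=False)


def summarize(ts: TrialSet) -> ConditionSummary:
    """Summarize a trial set into per-(difficulty, light) cells.

    Accuracy is the fraction of +1 (correct) choices; SEM uses the ddof=1
    sample standard deviation (NaN for singleton cells).
    """
    if len(ts) == 0:
        raise ValidationError("cannot summarize an empty TrialSet")
    df = ts.to_frame()
    grouped = df.groupby(["difficulty", "light_mw_mm2"])
    table = grouped.agg(
        mean_rt=("rt", "mean"),
        sem_rt=("rt", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
        accuracy=("choice", lambda s: float(np.mean(s == 1))),
        n=("rt", "size"),
    )
    table.index.names = ["difficulty", "light"]
    return ConditionSummary(table=table)
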