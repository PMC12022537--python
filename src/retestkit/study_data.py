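"""Data model, validation, I/O and pairing logic for repeated-measures
testing data.

The canonical container is :class:`LongDataset`: one row per administered
trial, identified by (subject, test, day, trial), in long format.  Day and
trial indices are 1-based, matching the usual "Test 1 … Test 5" /
"1_2 … 4_5" labelling of intraday and interday comparisons.

Pairing logic turns the long table into :class:`PairedComparison` objects —
two aligned score vectors for one test-vs-retest comparison — which are the
universal input of every downstream statistic (ICC, SEM/MDC, bias, MAE,
MAPE, Bland–Altman).  Three modes exist:

``intraday``
    trial 1 vs trial 2 within each day, one comparison per day;
``interday``
    consecutive day-mean pairs (1_2, 2_3, ...) plus the first-vs-last
    day comparison (1_D);
``first_vs_last``
    only the 1_D day-mean comparison.

Missing data are handled complete-case *per comparison*: a subject missing
day 2 is dropped from the 1_2 and 2_3 comparisons but kept everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, SchemaError

#: canonical column order of the long format
COLUMNS = ("subject", "group", "test", "day", "trial", "score")


@dataclass(frozen=True)
class TrialObservation:
    """A single administered trial: one score for one subject in one
    (test, day, trial) design cell."""

    subject_id: str
    group: str
    test: str
    day: int
    trial: int
    score: float
    higher_is_better: bool = False

    def __post_init__(self) -> None:
        if self.day < 1 or self.trial < 1:
            raise IntegrityError(
                f"day and trial are 1-based; got day={self.day}, trial={self.trial}"
            )
        if not np.isfinite(self.score):
            raise IntegrityError(f"non-finite score for subject {self.subject_id}")


@dataclass
class ValidationReport:
    """What the loader/validator did to the raw rows."""

    n_rows: int = 0
    n_missing_dropped: int = 0
    flagged: list[str] = field(default_factory=list)


class LongDataset:
    """Validated long-format repeated-measures dataset.

    Parameters
    ----------
    frame
        DataFrame with columns ``subject, group, test, day, trial, score``.
    higher_is_better
        Optional mapping test name -> bool; tests absent from the mapping
        default to ``False`` (lower scores are better, as for times).
    validation
        Carry-through report from the loader, if any.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        higher_is_better: Mapping[str, bool] | None = None,
        validation: ValidationReport | None = None,
    ) -> None:
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = frame.loc[:, list(COLUMNS)].copy()
        df["subject"] = df["subject"].astype(str)
        df["group"] = df["group"].astype(str)
        df["test"] = df["test"].astype(str)
        try:
            df["day"] = df["day"].astype(int)
            df["trial"] = df["trial"].astype(int)
            df["score"] = df["score"].astype(float)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"day/trial/score not numeric: {exc}") from exc

        if (df["day"] < 1).any() or (df["trial"] < 1).any():
            raise IntegrityError("day and trial indices must be >= 1")
        if not np.isfinite(df["score"]).all():
            raise IntegrityError("scores must be finite")
        dup = df.duplicated(subset=["subject", "test", "day", "trial"])
        if dup.any():
            bad = df.loc[dup, ["subject", "test", "day", "trial"]].iloc[0]
            raise IntegrityError(
                "duplicate (subject, test, day, trial) key: "
                f"{tuple(bad)} (and possibly others)"
            )
        # one group label per subject: groups must partition subjects
        n_groups = df.groupby("subject")["group"].nunique()
        if (n_groups > 1).any():
            raise IntegrityError(
                f"subjects with multiple group labels: "
                f"{list(n_groups[n_groups > 1].index)}"
            )
        # canonical ordering makes every downstream statistic invariant to
        # the row order of the input
        self.frame = df.sort_values(
            ["test", "subject", "day", "trial"], kind="mergesort"
        ).reset_index(drop=True)
        self.higher_is_better = dict(higher_is_better or {})
        self.validation = validation or ValidationReport(n_rows=len(df))

    # ------------------------------------------------------------------
    @property
    def tests(self) -> list[str]:
        return sorted(self.frame["test"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique())

    @property
    def design(self) -> dict[str, tuple[int, int]]:
        """Per test: (number of days, max trials per day) observed."""
        out: dict[str, tuple[int, int]] = {}
        for test, sub in self.frame.groupby("test"):
            out[test] = (int(sub["day"].max()), int(sub["trial"].max()))
        return out

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LongDataset):
            return NotImplemented
        return self.frame.equals(other.frame)

    def observations(self) -> Iterator[TrialObservation]:
        for row in self.frame.itertuples(index=False):
            yield TrialObservation(
                subject_id=row.subject,
                group=row.group,
                test=row.test,
                day=row.day,
                trial=row.trial,
                score=row.score,
                higher_is_better=self.higher_is_better.get(row.test, False),
            )

    def filter_group(self, group: str) -> "LongDataset":
        if group == "overall":
            return self
        sub = self.frame[self.frame["group"] == group]
        if sub.empty:
            raise SchemaError(f"unknown group {group!r}; have {self.groups}")
        return LongDataset(sub, higher_is_better=self.higher_is_better)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_observations(cls, obs: Iterable[TrialObservation]) -> "LongDataset":
        obs = list(obs)
        frame = pd.DataFrame(
            {
                "subject": [o.subject_id for o in obs],
                "group": [o.group for o in obs],
                "test": [o.test for o in obs],
                "day": [o.day for o in obs],
                "trial": [o.trial for o in obs],
                "score": [o.score for o in obs],
            }
        )
        hib = {o.test: o.higher_is_better for o in obs}
        return cls(frame, higher_is_better=hib)


@dataclass(frozen=True)
class PairedComparison:
    """Two aligned score vectors for one test-retest comparison.

    ``x`` is always the chronologically earlier measurement (the reference
    for MAPE); element i of ``x`` and ``y`` belong to the same subject.
    """

    label: str
    kind: str  # intraday | interday | first_vs_last
    x: np.ndarray
    y: np.ndarray
    n: int
    units: str = ""
    subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if len(self.x) != len(self.y) or len(self.x) != self.n:
            raise IntegrityError(
                f"{self.label}: x, y and n disagree "
                f"({len(self.x)}, {len(self.y)}, {self.n})"
            )
        if self.n < 2:
            raise IntegrityError(f"{self.label}: need n >= 2 paired subjects")
        if self.subjects and len(self.subjects) != self.n:
            raise IntegrityError(f"{self.label}: subject list length != n")


def load_long_csv(
    path,
    schema: Mapping[str, str] | None = None,
    higher_is_better: Mapping[str, bool] | None = None,
) -> LongDataset:
    """Read a long-format CSV into a validated :class:`LongDataset`.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8).
    schema
        Optional mapping from canonical names (``subject``, ``group``, ...)
        to the file's column names, for nonstandard headers.
    higher_is_better
        Per-test score direction; defaults to lower-is-better.

    Rows with a missing/unparseable score are dropped and counted in the
    returned dataset's ``validation`` report.
    """
    raw = pd.read_csv(path)
    mapping = {canon: canon for canon in COLUMNS}
    if schema:
        mapping.update(schema)
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"columns not found in {path}: {missing}")
    df = raw.rename(columns={src: canon for canon, src in mapping.items()})
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    n_missing = int(df["score"].isna().sum())
    df = df.dropna(subset=["score"])
    report = ValidationReport(n_rows=len(df), n_missing_dropped=n_missing)
    if n_missing:
        report.flagged.append(f"dropped {n_missing} rows with missing score")
    return LongDataset(df, higher_is_better=higher_is_better, validation=report)


def day_means(ds: LongDataset, test: str) -> pd.DataFrame:
    """Per-subject, per-day mean over the available trials of that day.

    Returns a tidy frame with columns ``subject, group, day, score``.
    Subjects with no trials on a day are simply absent from that day
    (pairing handles them complete-case per comparison).
    """
    sub = ds.frame[ds.frame["test"] == test]
    if sub.empty:
        raise SchemaError(f"unknown test {test!r}; have {ds.tests}")
    out = (
        sub.groupby(["subject", "group", "day"], as_index=False)["score"]
        .mean()
        .sort_values(["subject", "day"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def _paired_from_wide(
    wide: pd.DataFrame, col_x, col_y, label: str, kind: str, units: str
) -> PairedComparison | None:
    both = wide[[col_x, col_y]].dropna()
    if len(both) < 2:
        warnings.warn(
            f"comparison {label!r} skipped: fewer than 2 complete-case subjects",
            stacklevel=3,
        )
        return None
    return PairedComparison(
        label=label,
        kind=kind,
        x=both[col_x].to_numpy(),
        y=both[col_y].to_numpy(),
        n=len(both),
        units=units,
        subjects=tuple(both.index.astype(str)),
    )


def make_pairs(
    ds: LongDataset, test: str, mode: str, units: str = ""
) -> list[PairedComparison]:
    """Build all test-retest comparisons of one mode for one test.

    ``intraday`` compares trial 1 with trial 2 within each day (labels
    ``"<test> 1"`` ... ``"<test> D"``); ``interday`` compares consecutive
    day means (``"<test> 1_2"`` ... ``"<test> (D-1)_D"``) and appends the
    first-vs-last comparison ``"<test> 1_D"``; ``first_vs_last`` returns
    only the latter.  Complete-case subjects only; comparisons with fewer
    than two complete cases are skipped with a warning.
    """
    if mode not in {"intraday", "interday", "first_vs_last"}:
        raise ValueError(f"unknown mode {mode!r}")
    sub = ds.frame[ds.frame["test"] == test]
    if sub.empty:
        raise SchemaError(f"unknown test {test!r}; have {ds.tests}")

    pairs: list[PairedComparison] = []
    if mode == "intraday":
        wide = sub.pivot_table(
            index=["subject", "day"], columns="trial", values="score"
        )
        if 2 not in wide.columns:
            raise IntegrityError(
                f"intraday pairing for {test!r} requires 2 trials per day"
            )
        for day in sorted(sub["day"].unique()):
            w = wide.xs(day, level="day")
            p = _paired_from_wide(w, 1, 2, f"{test} {day}", "intraday", units)
            if p is not None:
                pairs.append(p)
        return pairs

    dm = day_means(ds, test)
    wide = dm.pivot_table(index="subject", columns="day", values="score")
    days = sorted(int(d) for d in wide.columns)
    if len(days) < 2:
        raise IntegrityError(f"interday pairing for {test!r} requires >= 2 days")
    first, last = days[0], days[-1]
    if mode == "interday":
        for d0, d1 in zip(days[:-1], days[1:]):
            p = _paired_from_wide(
                wide, d0, d1, f"{test} {d0}_{d1}", "interday", units
            )
            if p is not None:
                pairs.append(p)
        if last - first == 1:
            # with only two days the 1_2 comparison IS first-vs-last
            return pairs
    p = _paired_from_wide(
        wide, first, last, f"{test} {first}_{last}", "first_vs_last", units
    )
    if p is not None:
        pairs.append(p)
    return pairs
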