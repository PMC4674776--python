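"""Trial-level escape-latency records for water-maze cohorts.

The unit of observation is one swim trial: a mouse, its genotype-by-treatment
group, the training day, the trial-of-day, the escape latency in seconds, and
whether the trial timed out (right-censoring at the cutoff, 60 s by default).
All downstream modules consume :class:`CohortData`; raw CSV files are only
touched here.

CSV schema (comma-separated, UTF-8, header row)::

    mouse_id,genotype,treatment,day,trial,latency_s,censored

with ``censored`` encoded 0/1 and days/trials 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["mouse_id", "genotype", "treatment", "day", "trial", "latency_s", "censored"]

#: Tolerance for "latency equals the censor limit" when reading files.
_LIMIT_ATOL = 1e-9


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A record violates a domain invariant; the message is row-addressable."""


@dataclass(frozen=True)
class TrialRecord:
    """One escape-latency observation.

    ``censored`` means the mouse did not find the platform within the cutoff;
    the recorded latency then equals the cutoff exactly and the true latency
    is only known to exceed it.
    """

    mouse_id: str
    genotype: str
    treatment: str
    day: int
    trial: int
    latency: float
    censored: bool

    @property
    def group(self) -> tuple[str, str]:
        return (self.genotype, self.treatment)


@dataclass
class CohortData:
    """A validated collection of trial records for one study cohort.

    ``groups`` is the ordered list of (genotype, treatment) pairs present;
    every mouse belongs to exactly one group and no (mouse, day, trial) key
    repeats.  Unbalanced designs (missing trials) are permitted.

    Simulated cohorts may carry nonpositive latencies (the Gaussian model has
    no lower bound); empirical files are validated strictly positive at load
    time — see :func:`load_trials`.
    """

    records: list[TrialRecord]
    groups: list[tuple[str, str]] = field(default_factory=list)
    n_days: int = 0
    trials_per_day: int = 4
    censor_limit: float = 60.0

    def __post_init__(self) -> None:
        if not self.groups:
            seen: list[tuple[str, str]] = []
            for r in self.records:
                if r.group not in seen:
                    seen.append(r.group)
            self.groups = seen
        if self.n_days == 0 and self.records:
            self.n_days = max(r.day for r in self.records)
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self, require_positive: bool = False) -> None:
        keys: set[tuple[str, int, int]] = set()
        mouse_group: dict[str, tuple[str, str]] = {}
        group_set = set(self.groups)
        for i, r in enumerate(self.records):
            where = f"record {i} (mouse {r.mouse_id!r}, day {r.day}, trial {r.trial})"
            if r.day < 1:
                raise ValidationError(f"{where}: day must be >= 1, got {r.day}")
            if not 1 <= r.trial <= self.trials_per_day:
                raise ValidationError(
                    f"{where}: trial must be in 1..{self.trials_per_day}, got {r.trial}"
                )
            if not np.isfinite(r.latency):
                raise ValidationError(f"{where}: latency is not finite")
            if r.latency > self.censor_limit:
                raise ValidationError(
                    f"{where}: latency {r.latency} exceeds censor limit {self.censor_limit}"
                )
            if require_positive and r.latency <= 0:
                raise ValidationError(f"{where}: latency must be positive, got {r.latency}")
            if r.censored and r.latency != self.censor_limit:
                raise ValidationError(
                    f"{where}: censored record must sit at the censor limit "
                    f"({self.censor_limit}), got {r.latency}"
                )
            if r.group not in group_set:
                raise ValidationError(f"{where}: group {r.group} not in cohort groups")
            prev = mouse_group.setdefault(r.mouse_id, r.group)
            if prev != r.group:
                raise ValidationError(
                    f"{where}: mouse {r.mouse_id!r} appears in two groups {prev} and {r.group}"
                )
            key = (r.mouse_id, r.day, r.trial)
            if key in keys:
                raise ValidationError(f"{where}: duplicate (mouse, day, trial) key")
            keys.add(key)

    # -- views ----------------------------------------------------------

    @property
    def n_mice(self) -> int:
        return len({r.mouse_id for r in self.records})

    @property
    def mice(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for r in self.records:
            if r.mouse_id not in seen:
                seen.add(r.mouse_id)
                out.append(r.mouse_id)
        return out

    @property
    def days(self) -> list[int]:
        return sorted({r.day for r in self.records})

    def mouse_to_group(self) -> dict[str, tuple[str, str]]:
        return {r.mouse_id: r.group for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": [r.mouse_id for r in self.records],
                "genotype": [r.genotype for r in self.records],
                "treatment": [r.treatment for r in self.records],
                "day": [r.day for r in self.records],
                "trial": [r.trial for r in self.records],
                "latency_s": [r.latency for r in self.records],
                "censored": [int(r.censored) for r in self.records],
            }
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        censor_limit: float = 60.0,
        trials_per_day: int = 4,
        require_positive: bool = False,
    ) -> "CohortData":
        records = [
            TrialRecord(
                mouse_id=str(row.mouse_id),
                genotype=str(row.genotype),
                treatment=str(row.treatment),
                day=int(row.day),
                trial=int(row.trial),
                latency=float(row.latency_s),
                censored=bool(row.censored),
            )
            for row in df.itertuples(index=False)
        ]
        cohort = cls(
            records=records,
            trials_per_day=trials_per_day,
            censor_limit=censor_limit,
        )
        cohort.validate(require_positive=require_positive)
        return cohort


def load_trials(
    path,
    censor_limit: float = 60.0,
    trials_per_day: int = 4,
    require_positive: bool = True,
) -> CohortData:
    """Read a trial-record CSV and return a validated :class:`CohortData`.

    Rows whose latency equals ``censor_limit`` but are flagged uncensored are
    coerced to censored with a warning: a timed-out trial is recorded at the
    cutoff, so the cutoff value is synonymous with censoring.
    """
    df = pd.read_csv(path)
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    try:
        df["day"] = df["day"].astype(int)
        df["trial"] = df["trial"].astype(int)
        df["latency_s"] = df["latency_s"].astype(float)
        df["censored"] = df["censored"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"column with unparseable values in {path}: {exc}") from exc

    at_limit = np.isclose(df["latency_s"], censor_limit, rtol=0.0, atol=_LIMIT_ATOL)
    df.loc[at_limit, "latency_s"] = censor_limit
    to_coerce = at_limit & (df["censored"] == 0)
    if to_coerce.any():
        rows = df.index[to_coerce].tolist()
        warnings.warn(
            f"{int(to_coerce.sum())} row(s) at the censor limit flagged uncensored; "
            f"coerced to censored (rows {rows[:10]}{'...' if len(rows) > 10 else ''})",
            stacklevel=2,
        )
        df.loc[to_coerce, "censored"] = 1
    bad_flag = (df["censored"] == 1) & ~at_limit
    if bad_flag.any():
        i = int(df.index[bad_flag][0])
        raise ValidationError(
            f"row {i}: censored flag set but latency "
            f"{df.loc[i, 'latency_s']} != censor limit {censor_limit}"
        )

    # Row-addressed bound checks before handing off to record validation.
    too_big = df["latency_s"] > censor_limit
    if too_big.any():
        i = int(df.index[too_big][0])
        raise ValidationError(
            f"row {i}: latency {df.loc[i, 'latency_s']} exceeds censor limit {censor_limit}"
        )
    if require_positive:
        nonpos = df["latency_s"] <= 0
        if nonpos.any():
            i = int(df.index[nonpos][0])
            raise ValidationError(
                f"row {i}: latency must be positive, got {df.loc[i, 'latency_s']}"
            )

    return CohortData.from_frame(
        df,
        censor_limit=censor_limit,
        trials_per_day=trials_per_day,
        require_positive=require_positive,
    )


def write_trials(cohort: CohortData, path) -> None:
    """Write a cohort to the canonical CSV schema (round-trips exactly)."""
    cohort.to_frame().to_csv(path, index=False)
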