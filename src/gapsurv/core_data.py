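"""Domain types, validation, CSV I/O and the gap-time decomposition.

A subject in a multi-event oncology trial passes through ordered disease
states: loco-regional relapse (event 1), progression (event 2) and death or
last follow-up (event 3).  Event times ``T_1 <= T_2 <= T_3`` are measured in
days from registration; each carries an indicator (1 = observed, 0 =
censored).  The gap-time decomposition converts the ordered times into the
durations between consecutive events::

    G_1 = T_1,   G_j = T_j - T_{j-1}

The gap machinery is written for any number ``K`` of ordered events even
though the shipped analysis presets use three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "GapTimes",
    "Cohort",
    "GapsurvError",
    "ValidationError",
    "SchemaError",
    "ZeroGapError",
    "DEFAULT_COLUMNS",
    "EVENT_NAMES",
    "ENDPOINTS",
    "compute_gap_times",
    "complete_case_subset",
    "read_event_table",
    "write_event_table",
    "extract_endpoint",
    "gap_matrix",
]


class GapsurvError(Exception):
    """Base class for all package errors."""


class ValidationError(GapsurvError):
    """A record or cohort violates a structural invariant."""


class SchemaError(GapsurvError):
    """An input table does not match the expected schema."""


class ZeroGapError(ValidationError):
    """Two consecutive observed events share the same time.

    Log-time models are undefined at a zero gap, so gap construction fails
    loudly rather than nudging the time by an epsilon.
    """


EVENT_NAMES = ("relapse", "progression", "death")

#: Endpoint code -> index of the event time that defines it.
#: LRC: registration to first loco-regional relapse; PFS: enrolment to
#: progression; OS: registration to death or last follow-up.
ENDPOINTS = {"lrc": 0, "pfs": 1, "os": 2}

DEFAULT_COLUMNS = {
    "subject_id": "subject_id",
    "arm": "arm",
    "age": "age",
    "gender": "gender",
    "t_relapse": "t_relapse",
    "d_relapse": "d_relapse",
    "t_progression": "t_progression",
    "d_progression": "d_progression",
    "t_death": "t_death",
    "d_death": "d_death",
}


@dataclass(frozen=True)
class SubjectRecord:
    """One patient's ordered event times, indicators and covariates.

    Parameters
    ----------
    subject_id : str
        Opaque identifier, unique within a cohort.
    arm : int
        Binary treatment code, 0 = Arm-A (reference), 1 = Arm-B.
    age : float
        Age in years, or a binarised age-group code.
    gender : int
        Binary gender code.
    event_times : tuple of float
        Ordered times in days from registration; for a censored event the
        recorded time is the censoring time.
    event_indicators : tuple of int
        1 = event observed, 0 = censored at that time.  Events are ordered
        and death is terminal, so a 0 at position ``j`` forces 0 at every
        later position.
    """

    subject_id: str
    arm: int
    age: float
    gender: int
    event_times: tuple[float, ...]
    event_indicators: tuple[int, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.event_times)
        inds = tuple(int(d) for d in self.event_indicators)
        object.__setattr__(self, "event_times", times)
        object.__setattr__(self, "event_indicators", inds)
        if len(times) != len(inds):
            raise ValidationError(
                f"subject {self.subject_id!r}: {len(times)} times but "
                f"{len(inds)} indicators"
            )
        if len(times) == 0:
            raise ValidationError(f"subject {self.subject_id!r}: no events")
        if self.arm not in (0, 1):
            raise ValidationError(
                f"subject {self.subject_id!r}: arm must be 0 or 1, got {self.arm}"
            )
        if any(d not in (0, 1) for d in inds):
            raise ValidationError(
                f"subject {self.subject_id!r}: indicators must be 0/1"
            )
        if any(not math.isfinite(t) for t in times):
            raise ValidationError(
                f"subject {self.subject_id!r}: non-finite event time"
            )
        if times[0] <= 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: first event time must be "
                f"strictly positive, got {times[0]}"
            )
        for j in range(1, len(times)):
            if times[j] < times[j - 1]:
                raise ValidationError(
                    f"subject {self.subject_id!r}: event times not ordered "
                    f"({times[j - 1]} then {times[j]})"
                )
        # death (or any later event) cannot be observed after censoring
        seen_censored = False
        for j, d in enumerate(inds):
            if seen_censored and d == 1:
                raise ValidationError(
                    f"subject {self.subject_id!r}: event {j + 1} observed "
                    "after an earlier censored event"
                )
            if d == 0:
                seen_censored = True

    @property
    def n_events_observed(self) -> int:
        return int(sum(self.event_indicators))

    @property
    def complete(self) -> bool:
        """True when every ordered event was observed."""
        return all(d == 1 for d in self.event_indicators)


@dataclass(frozen=True)
class GapTimes:
    """The gap-time decomposition of one record.

    ``gaps`` holds only the observed gaps (durations between consecutive
    observed events); gaps beyond the last observed event are unobserved
    and not represented.  ``complete`` flags that every event was observed.
    """

    gaps: tuple[float, ...]
    complete: bool

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gaps):
            raise ValidationError("negative gap")


def compute_gap_times(record: SubjectRecord) -> GapTimes:
    """Decompose ordered event times into gap times.

    ``G_1 = T_1`` and ``G_j = T_j - T_{j-1}`` for each observed event ``j``.
    A zero gap between two observed events raises :class:`ZeroGapError`
    because the downstream log-time models require positive gaps.
    """
    n_obs = record.n_events_observed
    gaps: list[float] = []
    prev = 0.0
    for j in range(n_obs):
        g = record.event_times[j] - prev
        if g <= 0:
            raise ZeroGapError(
                f"subject {record.subject_id!r}: zero gap between observed "
                f"events {j} and {j + 1} (times {prev} and "
                f"{record.event_times[j]})"
            )
        gaps.append(g)
        prev = record.event_times[j]
    return GapTimes(gaps=tuple(gaps), complete=record.complete)


@dataclass(frozen=True)
class Cohort:
    """A collection of subject records plus arm labels.

    ``n_dropped`` counts input rows excluded for missing values during
    ingestion (rows with any missing mapped value are not analysed).
    """

    records: tuple[SubjectRecord, ...]
    arm_labels: Mapping[int, str] = field(
        default_factory=lambda: {0: "Arm-A", 1: "Arm-B"}
    )
    n_dropped: int = 0

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def arm_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for r in self.records:
            counts[r.arm] = counts.get(r.arm, 0) + 1
        return counts

    def subset(self, predicate) -> "Cohort":
        kept = tuple(r for r in self.records if predicate(r))
        return replace(self, records=kept, n_dropped=0)

    def by_arm(self, arm: int) -> "Cohort":
        return self.subset(lambda r: r.arm == arm)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "arm": r.arm,
                "age": r.age,
                "gender": r.gender,
            }
            for j, name in enumerate(EVENT_NAMES[: len(r.event_times)]):
                row[f"t_{name}"] = r.event_times[j]
                row[f"d_{name}"] = r.event_indicators[j]
            rows.append(row)
        return pd.DataFrame(rows)


def complete_case_subset(cohort: Cohort) -> Cohort:
    """Records with all ordered events observed; the input is unmodified.

    The gap analyses condition on every state being reached, so they run on
    this subset only.  May return an empty cohort.
    """
    return cohort.subset(lambda r: r.complete)


def read_event_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    arm_labels: Mapping[int, str] | None = None,
) -> Cohort:
    """Read a per-patient event table from CSV into a validated cohort.

    Parameters
    ----------
    path : path
        Comma-separated file with a header row, UTF-8.
    dialect : mapping, optional
        Maps canonical column names (keys of :data:`DEFAULT_COLUMNS`) to the
        source file's headers, for arbitrary source schemas.

    Rows with any missing mapped value are dropped and counted in
    ``Cohort.n_dropped`` — records with missing observations are not
    analysed.  Unused extra columns are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    colmap = dict(DEFAULT_COLUMNS)
    if dialect:
        unknown = set(dialect) - set(colmap)
        if unknown:
            raise SchemaError(f"unknown dialect keys: {sorted(unknown)}")
        colmap.update(dialect)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"unreadable CSV {path}: {exc}") from exc
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; present: "
            f"{list(df.columns)}"
        )

    numeric_keys = [k for k in colmap if k != "subject_id"]
    for key in numeric_keys:
        src = colmap[key]
        coerced = pd.to_numeric(df[src], errors="coerce")
        bad = coerced.isna() & df[src].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[src].iloc[row]!r} in column "
                f"{src!r} at data row {row}"
            )
        df[src] = coerced

    mapped = df[[colmap[k] for k in colmap]]
    keep = mapped.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    df = df.loc[keep]

    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row[colmap["subject_id"]]),
                arm=int(row[colmap["arm"]]),
                age=float(row[colmap["age"]]),
                gender=int(row[colmap["gender"]]),
                event_times=(
                    float(row[colmap["t_relapse"]]),
                    float(row[colmap["t_progression"]]),
                    float(row[colmap["t_death"]]),
                ),
                event_indicators=(
                    int(row[colmap["d_relapse"]]),
                    int(row[colmap["d_progression"]]),
                    int(row[colmap["d_death"]]),
                ),
            )
        )
    kwargs = {"records": tuple(records), "n_dropped": n_dropped}
    if arm_labels is not None:
        kwargs["arm_labels"] = dict(arm_labels)
    return Cohort(**kwargs)


def write_event_table(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to CSV in the canonical schema.

    Numeric fields survive a read/write round trip bit-exactly (times are
    written with full float precision).
    """
    df = cohort.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def extract_endpoint(
    cohort: Cohort, endpoint: str
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Times, event indicators and covariates for one survival endpoint.

    ``endpoint`` is one of ``lrc``, ``pfs``, ``os``.  Each endpoint measures
    time from registration to its defining event; subjects whose defining
    event was not observed contribute their recorded time as censored.
    """
    key = endpoint.lower()
    if key not in ENDPOINTS:
        raise ValidationError(
            f"unknown endpoint {endpoint!r}; expected one of {sorted(ENDPOINTS)}"
        )
    j = ENDPOINTS[key]
    times = np.array([r.event_times[j] for r in cohort], dtype=float)
    events = np.array([r.event_indicators[j] for r in cohort], dtype=int)
    covs = pd.DataFrame(
        {
            "arm": [r.arm for r in cohort],
            "age": [r.age for r in cohort],
            "gender": [r.gender for r in cohort],
        }
    )
    return times, events, covs


def gap_matrix(cohort: Cohort, gap_index: Sequence[int] = (1, 2)) -> pd.DataFrame:
    """Complete-case gap times as a tidy frame.

    ``gap_index`` picks which gaps (0-based into the ``G_1..G_K`` sequence)
    enter the analysis; the default pair is relapse→progression (index 1)
    and progression→death (index 2), the two transition durations the gap
    analyses model.  Columns: subject_id, arm, then ``gap{i+1}`` per index.
    """
    rows = []
    for r in complete_case_subset(cohort):
        g = compute_gap_times(r).gaps
        row = {"subject_id": r.subject_id, "arm": r.arm}
        for i in gap_index:
            row[f"gap{i + 1}"] = g[i]
        rows.append(row)
    return pd.DataFrame(rows)
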