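"""Data model and I/O for multi-type recurrent event histories.

A subject's follow-up is represented as an ordered sequence of *at-risk
intervals* (a counting-process representation).  Interval ``j`` of subject
``i`` is the triplet ``(start, stop, indicator)`` together with the event
type observed at ``stop`` (or ``censor``) and the covariate values in force
over the interval.  On the *age-calendar* timescale the first interval
starts at the entry age (age at surgery — delayed entry / left truncation),
and interval ``j+1`` starts where interval ``j`` stopped.  The *gap*
timescale resets every interval to start at 0, keeping its duration; the
*surgery-calendar* timescale shifts the origin to the entry age.

The on-disk format is a plain CSV with one row per interval
(``subject_id,entry,exit,status,event_type,rank,<covariates...>``) plus a
YAML/JSON sidecar declaring the covariate schema (names, levels, reference
level) and the timescale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EventType",
    "RiskInterval",
    "SubjectHistory",
    "Cohort",
    "CovariateSpec",
    "CovariateSchema",
    "GapTimeSummary",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "to_timescale",
    "prior_event_covariates",
    "summarize_gap_times",
]

TIMESCALES = ("age_calendar", "surgery_calendar", "gap")


class CohortValidationError(ValueError):
    """Raised when an event-history table violates a structural invariant."""


class EventType(str, Enum):
    """The event types a subject may experience.

    ``breast_cancer_death`` and ``censor`` are terminal: no at-risk interval
    may start after either.  Death from a cause other than the disease under
    study is encoded as ``censor``.
    """

    locoregional = "locoregional"
    contralateral = "contralateral"
    metastasis = "metastasis"
    second_cancer = "second_cancer"
    breast_cancer_death = "breast_cancer_death"
    censor = "censor"

    @property
    def terminal(self) -> bool:
        return self in (EventType.breast_cancer_death, EventType.censor)


#: event types that count as failures (everything except censoring)
FAILURE_TYPES = tuple(t for t in EventType if t is not EventType.censor)
#: non-terminal (recurrent) event types
RECURRENT_TYPES = tuple(t for t in FAILURE_TYPES if not t.terminal)


@dataclass(frozen=True)
class RiskInterval:
    """One at-risk period: the triplet (start, stop, indicator) plus metadata.

    ``indicator`` is 1 when the interval ends in an observed failure of
    ``type`` and 0 when it ends in censoring; times are decimal years.
    """

    start: float
    stop: float
    indicator: int
    type: EventType
    rank: int
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stop > self.start:
            raise CohortValidationError(
                f"interval (rank {self.rank}): stop <= start ({self.stop} <= {self.start})"
            )
        if self.indicator not in (0, 1):
            raise CohortValidationError(f"indicator must be 0 or 1, got {self.indicator}")
        if (self.indicator == 0) != (self.type is EventType.censor):
            raise CohortValidationError(
                f"indicator {self.indicator} inconsistent with event type {self.type.value}"
            )

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass(frozen=True)
class SubjectHistory:
    """All at-risk intervals of one subject, ordered by rank."""

    subject_id: str
    intervals: tuple[RiskInterval, ...]
    entry_age: float

    def __post_init__(self) -> None:
        if not self.intervals:
            raise CohortValidationError(f"subject {self.subject_id}: no intervals")
        for j, iv in enumerate(self.intervals, start=1):
            if iv.rank != j:
                raise CohortValidationError(
                    f"subject {self.subject_id}: ranks must be 1,2,... (found {iv.rank} at position {j})"
                )
            if j < len(self.intervals) and iv.type.terminal:
                raise CohortValidationError(
                    f"subject {self.subject_id}: interval after terminal event "
                    f"{iv.type.value} at rank {j}"
                )

    @property
    def n_events(self) -> int:
        return sum(iv.indicator for iv in self.intervals)

    def validate_calendar(self) -> None:
        """Check contiguity in a calendar representation."""
        prev_stop = None
        for iv in self.intervals:
            if prev_stop is not None and not np.isclose(iv.start, prev_stop, atol=1e-9):
                raise CohortValidationError(
                    f"subject {self.subject_id}: interval rank {iv.rank} starts at "
                    f"{iv.start}, expected {prev_stop} (contiguity)"
                )
            prev_stop = iv.stop


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: categorical (levels + reference) or numeric (levels=None)."""

    name: str
    levels: tuple[str, ...] | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.levels is not None:
            if self.reference is None:
                object.__setattr__(self, "reference", self.levels[0])
            if self.reference not in self.levels:
                raise CohortValidationError(
                    f"covariate {self.name}: reference {self.reference!r} not in levels"
                )

    @property
    def is_categorical(self) -> bool:
        return self.levels is not None

    def dummy_columns(self) -> list[str]:
        if not self.is_categorical:
            return [self.name]
        return [f"{self.name}[{lv}]" for lv in self.levels if lv != self.reference]


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate declarations shared by all subjects of a cohort."""

    specs: tuple[CovariateSpec, ...] = ()

    def __getitem__(self, name: str) -> CovariateSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def with_spec(self, spec: CovariateSpec) -> "CovariateSchema":
        specs = tuple(s for s in self.specs if s.name != spec.name) + (spec,)
        return CovariateSchema(specs)

    def to_dict(self) -> dict:
        return {
            "covariates": [
                {
                    "name": s.name,
                    "levels": list(s.levels) if s.levels is not None else None,
                    "reference": s.reference,
                }
                for s in self.specs
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSchema":
        specs = []
        for item in d.get("covariates", []):
            levels = item.get("levels")
            specs.append(
                CovariateSpec(
                    name=item["name"],
                    levels=tuple(str(lv) for lv in levels) if levels is not None else None,
                    reference=str(item["reference"]) if item.get("reference") is not None else None,
                )
            )
        return cls(tuple(specs))

    @classmethod
    def from_file(cls, path: str | Path) -> "CovariateSchema":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class Cohort:
    """A collection of subject histories sharing one covariate schema."""

    subjects: tuple[SubjectHistory, ...]
    schema: CovariateSchema = field(default_factory=CovariateSchema)
    timescale: str = "age_calendar"

    def __post_init__(self) -> None:
        if len(self.subjects) < 1:
            raise CohortValidationError("cohort must contain at least one subject")
        if self.timescale not in TIMESCALES:
            raise CohortValidationError(f"unknown timescale {self.timescale!r}")
        if self.timescale != "gap":
            for s in self.subjects:
                s.validate_calendar()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_events(self) -> int:
        return sum(s.n_events for s in self.subjects)

    def intervals_frame(self) -> pd.DataFrame:
        """All intervals as a tidy frame (one row per at-risk period)."""
        rows = []
        for s in self.subjects:
            for iv in s.intervals:
                row = {
                    "subject_id": s.subject_id,
                    "entry": iv.start,
                    "exit": iv.stop,
                    "status": iv.indicator,
                    "event_type": iv.type.value,
                    "rank": iv.rank,
                    "entry_age": s.entry_age,
                }
                row.update(iv.covariates)
                rows.append(row)
        return pd.DataFrame(rows)

    def design_matrix(self, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
        """Dummy-coded design matrix for the requested covariates.

        Categorical covariates expand to ``len(levels) - 1`` indicator
        columns against the declared reference level.
        """
        frame = self.intervals_frame()
        cols: list[np.ndarray] = []
        names: list[str] = []
        for name in covariates:
            if name not in self.schema:
                raise KeyError(f"covariate {name!r} not in schema")
            spec = self.schema[name]
            if name not in frame.columns:
                raise CohortValidationError(f"covariate {name!r} missing from intervals")
            values = frame[name]
            if spec.is_categorical:
                values = values.astype(str)
                bad = set(values) - set(spec.levels)
                if bad:
                    raise CohortValidationError(
                        f"covariate {name!r}: values {sorted(bad)} not in declared levels"
                    )
                for lv in spec.levels:
                    if lv == spec.reference:
                        continue
                    cols.append((values == lv).to_numpy(dtype=float))
                    names.append(f"{name}[{lv}]")
            else:
                v = pd.to_numeric(values, errors="coerce")
                if v.isna().any():
                    i = int(v.isna().idxmax())
                    raise CohortValidationError(
                        f"covariate {name!r}: non-numeric/missing value at row {i}"
                    )
                cols.append(v.to_numpy(dtype=float))
                names.append(name)
        X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
        return X, names

    def column_blocks(self, covariates: Sequence[str]) -> dict[str, list[str]]:
        """Map covariate name -> its dummy column names (for block-wise tests)."""
        return {name: self.schema[name].dummy_columns() for name in covariates}


# ---------------------------------------------------------------------------
# I/O


REQUIRED_COLUMNS = ("subject_id", "entry", "exit", "status", "event_type", "rank")


def read_cohort(
    path: str | Path,
    schema: CovariateSchema | str | Path | None = None,
    timescale: str | None = None,
) -> Cohort:
    """Read an event-history CSV and validate it into a :class:`Cohort`.

    Parameters
    ----------
    path:
        CSV with mandatory header ``subject_id,entry,exit,status,event_type,rank``
        and one column per declared covariate (plus an optional ``entry_age``
        column, required for non-age timescales).
    schema:
        A :class:`CovariateSchema`, or path to a YAML/JSON sidecar.  When
        omitted, a sidecar ``<path stem>.schema.yaml`` next to the CSV is used
        if present, otherwise the schema is empty.
    timescale:
        Overrides the sidecar's declared timescale (default ``age_calendar``).
    """
    path = Path(path)
    sidecar_ts = None
    if schema is None:
        candidate = path.with_suffix("").with_suffix(".schema.yaml")
        schema = candidate if candidate.exists() else CovariateSchema()
    if isinstance(schema, (str, Path)):
        spath = Path(schema)
        data = (
            json.loads(spath.read_text())
            if spath.suffix == ".json"
            else yaml.safe_load(spath.read_text())
        )
        sidecar_ts = data.get("timescale")
        schema = CovariateSchema.from_dict(data)

    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")
    for name in schema.names:
        if name not in df.columns:
            raise CohortValidationError(f"{path}: missing covariate column {name!r}")

    ts = timescale or sidecar_ts or "age_calendar"
    valid_types = {t.value for t in EventType}
    subjects = []
    # preserve first-appearance order of subjects
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("rank")
        intervals = []
        for idx, row in g.iterrows():
            et = str(row["event_type"])
            if et not in valid_types:
                raise CohortValidationError(
                    f"{path} row {idx}: unknown event type {et!r}"
                )
            cov = {}
            for name in schema.names:
                val = row[name]
                if pd.isna(val):
                    raise CohortValidationError(
                        f"{path} row {idx} (subject {sid}): missing covariate {name!r}"
                    )
                cov[name] = str(val) if schema[name].is_categorical else float(val)
            try:
                intervals.append(
                    RiskInterval(
                        start=float(row["entry"]),
                        stop=float(row["exit"]),
                        indicator=int(row["status"]),
                        type=EventType(et),
                        rank=int(row["rank"]),
                        covariates=cov,
                    )
                )
            except CohortValidationError as e:
                raise CohortValidationError(f"{path} row {idx} (subject {sid}): {e}") from e
        if "entry_age" in g.columns and not g["entry_age"].isna().all():
            entry_age = float(g["entry_age"].iloc[0])
        elif ts == "age_calendar":
            entry_age = float(intervals[0].start)
        else:
            raise CohortValidationError(
                f"{path}: entry_age column required for timescale {ts!r}"
            )
        try:
            subjects.append(SubjectHistory(str(sid), tuple(intervals), entry_age))
        except CohortValidationError as e:
            raise CohortValidationError(f"{path} subject {sid}: {e}") from e
    return Cohort(tuple(subjects), schema, ts)


def write_cohort(
    cohort: Cohort, path: str | Path, schema_path: str | Path | None = None
) -> tuple[Path, Path]:
    """Write a cohort to CSV plus a YAML schema sidecar; inverse of :func:`read_cohort`."""
    path = Path(path)
    schema_path = (
        Path(schema_path)
        if schema_path is not None
        else path.with_suffix("").with_suffix(".schema.yaml")
    )
    frame = cohort.intervals_frame()
    lead = list(REQUIRED_COLUMNS) + ["entry_age"]
    frame = frame[lead + [c for c in frame.columns if c not in lead]]
    # %.17g guarantees exact binary round-trip of doubles through text
    frame.to_csv(path, index=False, float_format="%.17g")
    sidecar = cohort.schema.to_dict()
    sidecar["timescale"] = cohort.timescale
    schema_path.write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path, schema_path


# ---------------------------------------------------------------------------
# Timescale transforms


def to_timescale(cohort: Cohort, target: str) -> Cohort:
    """Re-express every at-risk interval on another timescale.

    Durations and indicators are preserved exactly under all transforms:
    *gap* resets each interval's start to 0; *surgery_calendar* shifts the
    origin to the entry age; *age_calendar* restores absolute ages using the
    stored entry age.
    """
    if target not in TIMESCALES:
        raise CohortValidationError(f"unknown timescale {target!r}")
    if target == cohort.timescale:
        return cohort

    def convert(s: SubjectHistory) -> SubjectHistory:
        # first recover absolute ages, then project onto the target scale
        if cohort.timescale == "age_calendar":
            starts = [iv.start for iv in s.intervals]
        elif cohort.timescale == "surgery_calendar":
            starts = [iv.start + s.entry_age for iv in s.intervals]
        else:  # gap: rebuild contiguous ages from durations
            starts = []
            t = s.entry_age
            for iv in s.intervals:
                starts.append(t)
                t += iv.duration
        new = []
        for iv, a in zip(s.intervals, starts):
            if target == "age_calendar":
                ns, ne = a, a + iv.duration
            elif target == "surgery_calendar":
                ns, ne = a - s.entry_age, a - s.entry_age + iv.duration
            else:
                ns, ne = 0.0, iv.duration
            new.append(replace(iv, start=ns, stop=ne))
        return replace(s, intervals=tuple(new))

    return Cohort(tuple(convert(s) for s in cohort.subjects), cohort.schema, target)


# ---------------------------------------------------------------------------
# Prior-event covariates


PRIOR_COUNT_LEVELS = ("0", "1", "2", "3plus")
FIRST_EVENT_LEVELS = ("none", "locoregional", "contralateral", "metastasis", "second_cancer")

_CODINGS = ("count_classes", "count_linear", "first_event_type")


def prior_event_covariates(
    cohort: Cohort,
    coding: str | Iterable[str] = "count_classes",
    *,
    use_most_recent: bool = False,
) -> Cohort:
    """Attach event-dependence covariates derived from each subject's past.

    ``count_classes`` adds the number of prior events in four classes
    {0, 1, 2, >=3} (dummy-coded as 3 indicators against class 0);
    ``count_linear`` adds the raw prior-event count as a quantitative
    covariate; ``first_event_type`` adds the type of the subject's first
    event (reference level: no previous event).  With ``use_most_recent``
    the type covariate tracks the most recent prior event instead of the
    first one.
    """
    codings = (coding,) if isinstance(coding, str) else tuple(coding)
    for c in codings:
        if c not in _CODINGS:
            raise ValueError(f"unknown coding {c!r}; expected one of {_CODINGS}")

    schema = cohort.schema
    if "count_classes" in codings:
        schema = schema.with_spec(
            CovariateSpec("prior_count", PRIOR_COUNT_LEVELS, reference="0")
        )
    if "count_linear" in codings:
        schema = schema.with_spec(CovariateSpec("prior_count_linear"))
    if "first_event_type" in codings:
        schema = schema.with_spec(
            CovariateSpec("first_event_type", FIRST_EVENT_LEVELS, reference="none")
        )

    new_subjects = []
    for s in cohort.subjects:
        new_intervals = []
        for iv in s.intervals:
            n_prior = iv.rank - 1
            cov = dict(iv.covariates)
            if "count_classes" in codings:
                cov["prior_count"] = PRIOR_COUNT_LEVELS[min(n_prior, 3)]
            if "count_linear" in codings:
                cov["prior_count_linear"] = float(n_prior)
            if "first_event_type" in codings:
                if n_prior == 0:
                    cov["first_event_type"] = "none"
                else:
                    ref = s.intervals[iv.rank - 2] if use_most_recent else s.intervals[0]
                    cov["first_event_type"] = ref.type.value
            new_intervals.append(replace(iv, covariates=cov))
        new_subjects.append(replace(s, intervals=tuple(new_intervals)))
    return Cohort(tuple(new_subjects), schema, cohort.timescale)


# ---------------------------------------------------------------------------
# Descriptive gap-time summary


@dataclass(frozen=True)
class GapTimeSummary:
    """Mean gap times between successive events, by transition and event type."""

    table: pd.DataFrame
    events_per_subject_mean: float
    events_per_subject_range: tuple[int, int]
    n_subjects: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.table.to_string(index=False)}\n"
            f"events per subject: mean {self.events_per_subject_mean:.2f}, "
            f"range {self.events_per_subject_range[0]}-{self.events_per_subject_range[1]} "
            f"(N={self.n_subjects})"
        )


def summarize_gap_times(cohort: Cohort) -> GapTimeSummary:
    """Tabulate gap times between successive events.

    For each transition (entry to 1st event, 1st to 2nd, ...) and each event
    type (including censoring): the number of subjects whose interval of that
    rank ended that way, the percentage of the column, and the mean and SD of
    the gap (interval duration).  A pooled "any" column aggregates over all
    ranks.  Column counts for a transition sum to the number of subjects at
    risk for that transition.
    """
    frame = cohort.intervals_frame()
    if frame.empty:
        raise CohortValidationError("empty cohort")
    frame = frame.assign(gap=frame["exit"] - frame["entry"])

    def block(g: pd.DataFrame, transition: str) -> list[dict]:
        total = len(g)
        rows = []
        for et in list(EventType):
            sub = g[g["event_type"] == et.value]
            rows.append(
                {
                    "transition": transition,
                    "event_type": et.value,
                    "n": len(sub),
                    "pct": 100.0 * len(sub) / total if total else np.nan,
                    "mean_gap": sub["gap"].mean() if len(sub) else np.nan,
                    "sd_gap": sub["gap"].std(ddof=1) if len(sub) > 1 else np.nan,
                }
            )
        rows.append(
            {
                "transition": transition,
                "event_type": "TOTAL",
                "n": total,
                "pct": 100.0,
                "mean_gap": g["gap"].mean(),
                "sd_gap": g["gap"].std(ddof=1) if total > 1 else np.nan,
            }
        )
        return rows

    rows: list[dict] = []
    for rank in sorted(frame["rank"].unique()):
        rows.extend(block(frame[frame["rank"] == rank], f"{rank - 1}->{rank}"))
    rows.extend(block(frame, "any"))

    counts = frame.groupby("subject_id", sort=False)["status"].sum()
    # subjects are guaranteed >= 1 interval, so counts covers everyone
    return GapTimeSummary(
        table=pd.DataFrame(rows),
        events_per_subject_mean=float(frame["status"].sum() / cohort.n_subjects),
        events_per_subject_range=(int(counts.min()), int(counts.max())),
        n_subjects=cohort.n_subjects,
    )
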