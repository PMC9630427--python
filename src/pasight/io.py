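"""Sighting-table data model, readers/writers, inclusion filters and GBI construction.

The atomic observation is one identified individual in one group sighting on
one date at one planar location.  Tables are plain CSV (UTF-8, ISO-8601 dates,
one row per ``(group_id, individual_id)``).  A *study year* is a 365-day bin
counted from the study window's first date (year 1 = the first 365 days),
configurable to calendar years.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_CLASSES",
    "ADULT_MALE_CLASSES",
    "STATES",
    "STAGES",
    "SightingsError",
    "SightingTable",
    "GroupByIndividualMatrix",
    "read_sightings",
    "write_sightings",
    "build_gbi",
    "filter_females_first_two_years",
    "filter_glmm_males",
]

AGE_CLASSES = ("subadult", "21-30", "31-40", "41-50", "51-60")
ADULT_MALE_CLASSES = ("21-30", "31-40", "41-50", "51-60")
STATES = ("foraging", "musth")
STAGES = ("early", "peak", "late", "none")

COLUMNS = [
    "date",
    "x",
    "y",
    "group_id",
    "individual_id",
    "sex",
    "age_class",
    "state",
    "musth_stage",
]


class SightingsError(ValueError):
    """Raised for schema violations in sighting tables."""


def _validate(df: pd.DataFrame, study_start: dt.date, study_end: dt.date) -> None:
    for i, row in enumerate(df.itertuples(index=False)):
        if row.sex not in ("F", "M"):
            raise SightingsError(f"row {i}: unknown sex {row.sex!r}")
        if row.age_class not in AGE_CLASSES:
            raise SightingsError(f"row {i}: unknown age_class {row.age_class!r}")
        if row.state not in STATES:
            raise SightingsError(f"row {i}: unknown state {row.state!r}")
        if row.musth_stage not in STAGES:
            raise SightingsError(f"row {i}: unknown musth_stage {row.musth_stage!r}")
        if (row.state == "musth") != (row.musth_stage != "none"):
            raise SightingsError(
                f"row {i}: field musth_stage={row.musth_stage!r} inconsistent "
                f"with state={row.state!r}"
            )
        if row.sex == "F" and row.state != "foraging":
            raise SightingsError(f"row {i}: female with state {row.state!r}")
        d = row.date.date() if hasattr(row.date, "date") else row.date
        if not (study_start <= d <= study_end):
            raise SightingsError(
                f"row {i}: field date {d} outside study window "
                f"[{study_start}, {study_end}]"
            )
    if df.duplicated(["group_id", "individual_id"]).any():
        j = int(np.nonzero(df.duplicated(["group_id", "individual_id"]).to_numpy())[0][0])
        raise SightingsError(f"row {j}: duplicate (group_id, individual_id) pair")


@dataclass
class SightingTable:
    """Ordered collection of sighting records plus the declared study window.

    ``records`` holds one row per individual per group sighting with columns
    ``date, x, y, group_id, individual_id, sex, age_class, state, musth_stage``.
    ``study_start`` / ``study_end`` are the first and last observable dates.
    """

    records: pd.DataFrame
    study_start: dt.date
    study_end: dt.date
    calendar_years: bool = field(default=False)

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SightingsError(f"missing column(s): {', '.join(missing)}")
        df = df[COLUMNS]
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        _validate(df, self.study_start, self.study_end)
        df = df.sort_values(["date", "group_id", "individual_id"], kind="stable")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def study_year(self, dates: pd.Series) -> pd.Series:
        """Map dates to 1-based study years (365-day bins, or calendar years)."""
        d = pd.to_datetime(dates)
        if self.calendar_years:
            return d.dt.year - self.study_start.year + 1
        start = pd.Timestamp(self.study_start)
        return (d - start).dt.days // 365 + 1

    @property
    def n_years(self) -> int:
        span = (self.study_end - self.study_start).days + 1
        return int(np.ceil(span / 365))

    def subset(self, ids: Iterable[str]) -> "SightingTable":
        ids = set(ids)
        df = self.records[self.records["individual_id"].isin(ids)]
        return SightingTable(df, self.study_start, self.study_end, self.calendar_years)


def write_sightings(table: SightingTable, path: str | Path) -> None:
    """Write a sighting table as CSV; a ``# study_window:`` header comment keeps the window."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# study_window: {table.study_start.isoformat()} {table.study_end.isoformat()}\n")
        out = table.records.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(fh, index=False)


def read_sightings(
    path: str | Path,
    study_start: dt.date | None = None,
    study_end: dt.date | None = None,
    calendar_years: bool = False,
) -> SightingTable:
    """Read a sighting CSV.

    The study window is taken from the ``# study_window:`` header comment when
    present, else from the arguments, else from the data's date range.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# study_window:"):
            parts = first.split(":", 1)[1].split()
            study_start = dt.date.fromisoformat(parts[0])
            study_end = dt.date.fromisoformat(parts[1])
            df = pd.read_csv(fh, dtype={"group_id": str, "individual_id": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, dtype={"group_id": str, "individual_id": str})
    if df.empty and "date" not in df.columns:
        # header-only file written without records still carries columns
        df = pd.DataFrame(columns=COLUMNS)
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, KeyError) as exc:
        raise SightingsError(f"unparseable date column: {exc}") from exc
    if study_start is None:
        if df.empty:
            raise SightingsError("empty file and no study window declared")
        study_start = df["date"].min().date()
        study_end = df["date"].max().date()
    assert study_end is not None
    return SightingTable(df, study_start, study_end, calendar_years)


@dataclass
class GroupByIndividualMatrix:
    """Binary groups x individuals incidence matrix (rows = sampling events)."""

    matrix: np.ndarray  # shape (n_groups, n_individuals), dtype int8
    group_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("GBI must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("GBI entries must be 0/1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def column_sums(self) -> dict[str, int]:
        return dict(zip(self.individual_ids, self.matrix.sum(axis=0).tolist()))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.group_ids, columns=self.individual_ids).to_csv(path)

    def to_mtx(self, path: str | Path) -> None:
        from scipy import io as spio
        from scipy import sparse

        spio.mmwrite(str(path), sparse.csr_matrix(self.matrix))


def build_gbi(table: SightingTable, subjects: Sequence[str]) -> GroupByIndividualMatrix:
    """Build the group-by-individual matrix restricted to ``subjects``.

    One row per group sighting containing at least one subject; row order
    follows (date, group_id) and is invariant to input record order.
    """
    subjects = list(dict.fromkeys(subjects))
    if not subjects:
        raise ValueError("subjects must be non-empty")
    df = table.records
    df = df[df["individual_id"].isin(subjects)]
    if df.empty:
        return GroupByIndividualMatrix(np.zeros((0, len(subjects)), dtype=np.int8), [], subjects)
    col = {s: j for j, s in enumerate(subjects)}
    groups = df.groupby("group_id", sort=False)
    order = df.drop_duplicates("group_id")[["date", "group_id"]].sort_values(
        ["date", "group_id"], kind="stable"
    )["group_id"].tolist()
    mat = np.zeros((len(order), len(subjects)), dtype=np.int8)
    row = {g: i for i, g in enumerate(order)}
    for g, sub in groups:
        for ind in sub["individual_id"]:
            mat[row[g], col[ind]] = 1
    return GroupByIndividualMatrix(mat, order, subjects)


def filter_females_first_two_years(
    table: SightingTable, known_deaths: Iterable[str] = ()
) -> list[str]:
    """Adult females seen in both study year 1 and study year 2, minus known deaths.

    Mirrors the inclusion rule that subjects must have been available for
    observation over the full study: present in each of the first two years,
    with individuals later known to have died removed.
    """
    df = table.records
    adult_f = df[(df["sex"] == "F") & (df["age_class"] != "subadult")].copy()
    if adult_f.empty:
        return []
    adult_f["year"] = table.study_year(adult_f["date"])
    seen = adult_f.groupby("individual_id")["year"].agg(set)
    keep = sorted(i for i, ys in seen.items() if {1, 2} <= ys)
    dead = set(known_deaths)
    return [i for i in keep if i not in dead]


def filter_glmm_males(
    roster: pd.DataFrame, sighting_counts: Mapping[str, int]
) -> list[str]:
    """Inclusion filter for the male BSI mixed-model frame.

    Drops the oldest age class (51-60) and males seen only once, for whom the
    between-sightings interval is undefined.  ``roster`` needs columns
    ``individual_id`` and ``age_class``; order is preserved.  Idempotent.
    """
    out = []
    for row in roster.itertuples(index=False):
        if row.age_class == "51-60":
            continue
        if sighting_counts.get(row.individual_id, 0) <= 1:
            continue
        out.append(row.individual_id)
    return out
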