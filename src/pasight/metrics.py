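"""PA-use statistics: between-sightings intervals, musth strategies and male-week scoring.

The between-sightings interval (BSI) is the number of days elapsed between
consecutive sightings of an individual.  Its mean, taken over the first to the
last sighting, measures how continuously an individual uses the observed area:
short mean BSI suggests residency near the study area, long mean BSI is
compatible with ranging far outside it.  Multiple sightings on one day
collapse to one date (BSI is defined in whole days elapsed) and the mean is
undefined — flagged, not zero — for individuals with fewer than two distinct
sighting days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SightingTable

__all__ = [
    "FORAGING_ONLY",
    "MUSTH_ONLY",
    "FORAGING_AND_MUSTH",
    "STRATEGIES",
    "BSISummary",
    "MaleWeekMatrix",
    "MusthBout",
    "StrategyYearTable",
    "compute_bsi",
    "classify_strategy",
    "male_week_scores",
    "musth_bouts",
    "residency_flag",
    "tabulate_strategy_by_years",
]

FORAGING_ONLY = "foraging_only"
MUSTH_ONLY = "musth_only"
FORAGING_AND_MUSTH = "foraging_and_musth"
STRATEGIES = (MUSTH_ONLY, FORAGING_ONLY, FORAGING_AND_MUSTH)

#: Short field codes for the three strategies.
STRATEGY_CODES = {MUSTH_ONLY: "m", FORAGING_ONLY: "f", FORAGING_AND_MUSTH: "f+m"}


@dataclass
class BSISummary:
    """Per-individual sighting-interval summary.

    ``mean_bsi`` is None when fewer than two distinct sighting days exist.
    ``yearly_mean_bsi`` maps study year to the mean of within-year gaps only
    (undefined years omitted); the overall mean uses all first-to-last gaps
    including cross-year ones.
    """

    individual_id: str
    n_sightings: int
    n_days: int
    mean_bsi: float | None
    first_date: dt.date | None
    last_date: dt.date | None
    years_seen: frozenset[int]
    yearly_mean_bsi: dict[int, float] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.mean_bsi is not None


def _mean_gap(day_numbers: np.ndarray) -> float | None:
    if len(day_numbers) < 2:
        return None
    return float(np.diff(day_numbers).mean())


def compute_bsi(
    records: pd.DataFrame,
    study_start: dt.date,
    calendar_years: bool = False,
) -> BSISummary:
    """Summarise the between-sightings intervals for one individual.

    ``records`` must all carry the same ``individual_id``.  The mean BSI over
    distinct sighting days equals ``(last - first) / (n_days - 1)`` — an
    algebraic identity of averaging consecutive gaps — and is at least 1 day.
    """
    ids = records["individual_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"records mix individual IDs: {sorted(ids)}")
    if records.empty:
        raise ValueError("no records supplied")
    dates = pd.to_datetime(records["date"]).dt.normalize()
    days = np.unique((dates - pd.Timestamp(study_start)).dt.days.to_numpy())
    if calendar_years:
        day_dates = pd.Timestamp(study_start) + pd.to_timedelta(days, unit="D")
        year_of_day = (day_dates.year - study_start.year + 1).to_numpy()
    else:
        year_of_day = days // 365 + 1
    yearly: dict[int, float] = {}
    for y in np.unique(year_of_day):
        m = _mean_gap(days[year_of_day == y])
        if m is not None:
            yearly[int(y)] = m
    years_seen = frozenset(int(v) for v in np.unique(year_of_day))
    return BSISummary(
        individual_id=str(ids[0]),
        n_sightings=len(records),
        n_days=len(days),
        mean_bsi=_mean_gap(days),
        first_date=dates.min().date(),
        last_date=dates.max().date(),
        years_seen=years_seen,
        yearly_mean_bsi=yearly,
    )


def classify_strategy(records: pd.DataFrame) -> str:
    """Classify a mature male's PA-use strategy from his sighting states.

    foraging_only if never seen in musth; musth_only if every sighting is in
    musth; foraging_and_musth otherwise.  Order-invariant.
    """
    if records.empty:
        raise ValueError("cannot classify a male with zero sightings")
    musth = (records["state"] == "musth").to_numpy()
    if not musth.any():
        return FORAGING_ONLY
    if musth.all():
        return MUSTH_ONLY
    return FORAGING_AND_MUSTH


@dataclass
class MaleWeekMatrix:
    """Males x study-weeks score matrix: 0 unseen, 1 seen foraging only, 2 musth seen.

    Weeks are consecutive 7-day bins anchored at ``week_origin``.
    """

    scores: np.ndarray  # (n_males, n_weeks) int8
    male_ids: list[str]
    week_origin: dt.date

    @property
    def n_weeks(self) -> int:
        return self.scores.shape[1]

    def male_weeks_seen(self, ids: Iterable[str] | None = None) -> int:
        """Number of male-week cells with score >= 1."""
        return int((self._sub(ids) >= 1).sum())

    def musth_weeks(self, ids: Iterable[str] | None = None) -> int:
        """Number of male-week cells scored 2 (musth seen at any time that week)."""
        return int((self._sub(ids) == 2).sum())

    def foraging_weeks(self, ids: Iterable[str] | None = None) -> int:
        return int((self._sub(ids) == 1).sum())

    def per_strategy_totals(self, labels: Mapping[str, str]) -> pd.DataFrame:
        rows = []
        for strat in STRATEGIES:
            ids = [m for m in self.male_ids if labels.get(m) == strat]
            rows.append(
                {
                    "strategy": strat,
                    "male_weeks_seen": self.male_weeks_seen(ids),
                    "musth_weeks": self.musth_weeks(ids),
                }
            )
        return pd.DataFrame(rows).set_index("strategy")

    def _sub(self, ids: Iterable[str] | None) -> np.ndarray:
        if ids is None:
            return self.scores
        idx = {m: i for i, m in enumerate(self.male_ids)}
        rows = [idx[i] for i in ids if i in idx]
        return self.scores[rows]


def male_week_scores(
    table: SightingTable,
    males: Sequence[str],
    week_origin: dt.date | None = None,
) -> MaleWeekMatrix:
    """Score each male's presence per 7-day bin.

    A week scores 2 if it contains at least one musth sighting, 1 if the male
    was seen but never in musth, 0 if unseen.  ``week_origin`` defaults to the
    study start and must not postdate the first sighting.
    """
    origin = week_origin or table.study_start
    df = table.records[table.records["individual_id"].isin(set(males))]
    if not df.empty and df["date"].min().date() < origin:
        raise ValueError("week_origin postdates the first sighting")
    n_weeks = max(1, ((table.study_end - origin).days // 7) + 1)
    scores = np.zeros((len(males), n_weeks), dtype=np.int8)
    row = {m: i for i, m in enumerate(males)}
    if not df.empty:
        week = ((df["date"] - pd.Timestamp(origin)).dt.days // 7).to_numpy()
        musth = (df["state"] == "musth").to_numpy()
        for ind, w, mu in zip(df["individual_id"], week, musth):
            i = row[ind]
            scores[i, w] = max(scores[i, w], 2 if mu else 1)
    return MaleWeekMatrix(scores, list(males), origin)


@dataclass
class MusthBout:
    """A maximal run of musth sightings uninterrupted by non-musth sightings."""

    individual_id: str
    start: dt.date
    end: dt.date
    duration: int  # days elapsed between first and last musth sighting of the run
    complete: bool  # bracketed by non-musth sightings on both sides

    def __post_init__(self) -> None:
        assert self.duration >= 0


def musth_bouts(records: pd.DataFrame) -> list[MusthBout]:
    """Split one male's dated sighting sequence into musth bouts.

    A bout is complete only when observed from beginning to end: bracketed by
    non-musth sightings before and after, with no intervening non-musth
    sighting inside.  Duration is days elapsed between the bout's first and
    last musth sighting (0 for a single-sighting bout).
    """
    if records.empty:
        return []
    ids = records["individual_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"records mix individual IDs: {sorted(ids)}")
    df = records.sort_values("date", kind="stable")
    dates = pd.to_datetime(df["date"]).dt.normalize().tolist()
    musth = (df["state"] == "musth").tolist()
    bouts: list[MusthBout] = []
    i, n = 0, len(dates)
    while i < n:
        if not musth[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and musth[j + 1]:
            j += 1
        start, end = dates[i].date(), dates[j].date()
        complete = i > 0 and j < n - 1
        bouts.append(
            MusthBout(str(ids[0]), start, end, (end - start).days, complete)
        )
        i = j + 1
    return bouts


def residency_flag(summary: BSISummary, bsi_cutoff: float = 90.0) -> bool:
    """Possible resident: mean BSI strictly below the cutoff and seen in >= 2 study years.

    An undefined BSI (single sighting) cannot evidence residency and returns False.
    """
    if summary.mean_bsi is None:
        return False
    return summary.mean_bsi < bsi_cutoff and len(summary.years_seen) >= 2


@dataclass
class StrategyYearTable:
    """Counts of males by (number of study years seen) x strategy, with column percentages."""

    counts: pd.DataFrame  # index: years-seen frequency desc; columns: strategies

    def percent(self, rounding: str = "nearest", decimals: int = 1) -> pd.DataFrame:
        """Within-strategy column percentages; columns sum to 100 up to rounding."""
        totals = self.counts.sum(axis=0)
        pct = 100.0 * self.counts / totals.replace(0, np.nan)
        if rounding == "nearest":
            return pct.round(decimals)
        if rounding == "truncate":
            factor = 10.0**decimals
            return np.trunc(pct * factor) / factor
        raise ValueError(f"unknown rounding mode {rounding!r}")

    def strategy_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def tabulate_strategy_by_years(
    labels: Mapping[str, str],
    years_seen: Mapping[str, Iterable[int]],
    max_years: int | None = None,
) -> StrategyYearTable:
    """Cross-tabulate strategy against the number of distinct study years seen."""
    if set(labels) != set(years_seen):
        raise ValueError("labels and years_seen must cover the same males")
    freqs = {m: len(set(ys)) for m, ys in years_seen.items()}
    top = max_years or (max(freqs.values()) if freqs else 1)
    index = list(range(top, 0, -1))
    counts = pd.DataFrame(0, index=index, columns=list(STRATEGIES))
    for m, strat in labels.items():
        counts.loc[freqs[m], strat] += 1
    counts.index.name = "years_seen"
    return StrategyYearTable(counts)
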