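"""Synthetic fission–fusion sighting generator with retained ground truth.

Emulates longitudinal individual-ID sightings from a protected area with
seasonal turnover: females belong to social communities and move in and out
of the observation area in alternating residency bouts (exponential bout
lengths), partially synchronised within a community; present community
members split into daily groups by a Chinese-restaurant-style random
partition; mature males cycle through annual musth windows whose mean
duration grows with age and use the area in a foraging state, a musth state,
or both, according to their strategy.  Detection is imperfect and per-day.

All randomness flows from a single seed through counter-based substreams
(one per individual, community-day, and male-day), so adding individuals
does not perturb the draws of earlier ones.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import ADULT_MALE_CLASSES, SightingTable

__all__ = ["SimConfig", "GroundTruth", "ConfigError", "simulate_population", "simulate_sightings", "simulate"]

# substream kinds for SeedSequence spawn keys
_GLOBAL, _INDIV, _COMM, _COMM_DAY, _MALE_DAY = 0, 1, 2, 3, 4


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


def _default_sizes() -> list[int]:
    # 16 communities spanning 2..22 members, 130 females in total
    return [22, 15, 12, 11, 10, 9, 9, 8, 7, 6, 5, 4, 4, 3, 3, 2]


@dataclass
class SimConfig:
    """Study conditions for the synthetic sighting generator.

    Defaults emulate the situation the analysis was designed for: a ~308 km²
    park whose observable area hosts roughly a third to a half of the
    population at any time (high seasonal turnover), 16 female communities of
    2–22 members, and 216 mature males of whom a minority use the area only
    in musth.
    """

    study_start: dt.date = dt.date(2010, 1, 1)
    study_days: int = 6 * 365
    n_communities: int = 16
    community_sizes: list[int] = field(default_factory=_default_sizes)
    n_males: int = 216
    male_age_class_probs: tuple[float, ...] = (0.45, 0.35, 0.19, 0.01)
    residency_mean_in: float = 60.0
    residency_mean_out: float = 120.0
    residency_mixing_rho: float = 0.9
    detection_prob: float = 0.5
    grouping_concentration: float = 1.0
    musth_duration_means: Mapping[str, float] = field(
        default_factory=lambda: {"21-30": 24.5, "31-40": 32.5, "41-50": 45.0, "51-60": 45.0}
    )
    musth_annual: bool = True
    strategy_probs: tuple[float, float, float] = (0.45, 0.11, 0.44)  # f, m, f+m
    centroid_sd: float = 2000.0
    arena_size: float = 15000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.study_start, str):
            self.study_start = dt.date.fromisoformat(self.study_start)
        self.community_sizes = list(self.community_sizes)
        if self.study_days < 730:
            raise ConfigError("study_days must be >= 730 (analysis needs 2 years)")
        if len(self.community_sizes) != self.n_communities:
            raise ConfigError("community_sizes length must equal n_communities")
        if any(s < 2 for s in self.community_sizes):
            raise ConfigError("community_sizes entries must be >= 2")
        for name, probs in (
            ("male_age_class_probs", self.male_age_class_probs),
            ("strategy_probs", self.strategy_probs),
        ):
            if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ConfigError(f"{name} must be probabilities summing to 1")
        if not (0 <= self.residency_mixing_rho <= 1):
            raise ConfigError("residency_mixing_rho must be in [0, 1]")
        if not (0 <= self.detection_prob <= 1):
            raise ConfigError("detection_prob must be in [0, 1]")
        if self.grouping_concentration < 0:
            raise ConfigError("grouping_concentration must be >= 0")
        if self.residency_mean_in <= 0 or self.residency_mean_out <= 0:
            raise ConfigError("residency bout means must be positive")
        for cls in ADULT_MALE_CLASSES:
            if cls not in self.musth_duration_means:
                raise ConfigError(f"musth_duration_means missing age class {cls}")

    @property
    def n_females(self) -> int:
        return sum(self.community_sizes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["musth_duration_means"] = dict(self.musth_duration_means)
        d["male_age_class_probs"] = list(self.male_age_class_probs)
        d["strategy_probs"] = list(self.strategy_probs)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """True latent state per simulated individual, for parameter-recovery tests."""

    community: dict[str, int]  # females only
    strategy: dict[str, str]  # males only, codes f / m / f+m
    musth_windows: dict[str, list[tuple[int, int]]]  # male -> [(start_day, end_day)) offsets
    centroid: dict[str, tuple[float, float]]
    residency: dict[str, np.ndarray]  # id -> bool presence per study day

    def to_json(self, path: str | Path) -> None:
        payload = {
            "community": self.community,
            "strategy": self.strategy,
            "musth_windows": self.musth_windows,
            "centroid": self.centroid,
            "residency": {k: np.flatnonzero(v).tolist() for k, v in self.residency.items()},
            "n_days": len(next(iter(self.residency.values()))) if self.residency else 0,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        n_days = raw["n_days"]
        res = {}
        for k, days in raw["residency"].items():
            arr = np.zeros(n_days, dtype=bool)
            arr[days] = True
            res[k] = arr
        return cls(
            community={k: int(v) for k, v in raw["community"].items()},
            strategy=raw["strategy"],
            musth_windows={k: [tuple(w) for w in v] for k, v in raw["musth_windows"].items()},
            centroid={k: tuple(v) for k, v in raw["centroid"].items()},
            residency=res,
        )


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _bout_schedule(rng: np.random.Generator, mean_in: float, mean_out: float, n_days: int) -> np.ndarray:
    """Alternating in/out residency bouts with exponential lengths (>= 1 day)."""
    sched = np.zeros(n_days, dtype=bool)
    p_in = mean_in / (mean_in + mean_out)
    state = bool(rng.random() < p_in)
    day = 0
    while day < n_days:
        mean = mean_in if state else mean_out
        length = max(1, int(np.ceil(rng.exponential(mean))))
        if state:
            sched[day : day + length] = True
        day += length
        state = not state
    return sched


def _crp_partition(rng: np.random.Generator, items: list[str], alpha: float) -> list[list[str]]:
    """Chinese-restaurant random partition; alpha -> 0 gives a single group."""
    groups: list[list[str]] = []
    for k, item in enumerate(items):
        if not groups:
            groups.append([item])
            continue
        weights = np.array([len(g) for g in groups] + [alpha], dtype=float)
        choice = rng.choice(len(groups) + 1, p=weights / weights.sum())
        if choice == len(groups):
            groups.append([item])
        else:
            groups[choice].append(item)
    return groups


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the roster (sex, age class, community, strategy, centroid) and latent truth.

    Deterministic given ``config.seed``; each individual's draws come from a
    dedicated substream keyed by its index.
    """
    g_rng = _stream(config.seed, _GLOBAL)
    n_days = config.study_days
    centers = g_rng.uniform(0, config.arena_size, size=(config.n_communities, 2))

    community: dict[str, int] = {}
    strategy: dict[str, str] = {}
    windows: dict[str, list[tuple[int, int]]] = {}
    centroid: dict[str, tuple[float, float]] = {}
    residency: dict[str, np.ndarray] = {}
    rows = []

    comm_sched = [
        _bout_schedule(_stream(config.seed, _COMM, c), config.residency_mean_in, config.residency_mean_out, n_days)
        for c in range(config.n_communities)
    ]

    idx = 0
    for c, size in enumerate(config.community_sizes):
        for _ in range(size):
            ind = f"F{idx:03d}"
            rng = _stream(config.seed, _INDIV, idx)
            own = _bout_schedule(rng, config.residency_mean_in, config.residency_mean_out, n_days)
            take_comm = rng.random(n_days) < config.residency_mixing_rho
            sched = np.where(take_comm, comm_sched[c], own)
            cent = centers[c] + rng.normal(0, config.centroid_sd, 2)
            age = rng.choice(ADULT_MALE_CLASSES)  # adult age bin; unused for females downstream
            community[ind] = c
            centroid[ind] = (float(cent[0]), float(cent[1]))
            residency[ind] = sched
            rows.append((ind, "F", str(age), c, None, cent[0], cent[1]))
            idx += 1

    strat_codes = ("f", "m", "f+m")
    for m in range(config.n_males):
        ind = f"M{m:03d}"
        rng = _stream(config.seed, _INDIV, idx)
        age = str(rng.choice(ADULT_MALE_CLASSES, p=list(config.male_age_class_probs)))
        strat = str(rng.choice(strat_codes, p=list(config.strategy_probs)))
        sched = _bout_schedule(rng, config.residency_mean_in, config.residency_mean_out, n_days)
        cent = rng.uniform(0, config.arena_size, 2)
        wins: list[tuple[int, int]] = []
        if config.musth_annual:
            mean_dur = float(config.musth_duration_means[age])
            n_years = int(np.ceil(n_days / 365))
            for yr in range(n_years):
                dur = max(1, int(np.ceil(rng.gamma(shape=4.0, scale=mean_dur / 4.0))))
                start = int(yr * 365 + rng.integers(0, 365))
                end = min(start + dur, n_days)
                if start < n_days:
                    wins.append((start, end))
        strategy[ind] = strat
        windows[ind] = wins
        centroid[ind] = (float(cent[0]), float(cent[1]))
        residency[ind] = sched
        rows.append((ind, "M", age, None, strat, cent[0], cent[1]))
        idx += 1

    roster = pd.DataFrame(
        rows,
        columns=["individual_id", "sex", "age_class", "community", "strategy", "centroid_x", "centroid_y"],
    )
    truth = GroundTruth(community, strategy, windows, centroid, residency)
    return roster, truth


def _male_presence(truth: GroundTruth, ind: str, strat: str, n_days: int) -> tuple[np.ndarray, np.ndarray]:
    """(present, in_musth) boolean day vectors for one male under his strategy."""
    in_musth = np.zeros(n_days, dtype=bool)
    for a, b in truth.musth_windows[ind]:
        in_musth[a:b] = True
    sched = truth.residency[ind]
    if strat == "f":
        present = sched & ~in_musth  # leaves the area for musth elsewhere
        musth_state = np.zeros(n_days, dtype=bool)
    elif strat == "m":
        present = in_musth
        musth_state = in_musth
    else:  # f+m
        present = sched | in_musth
        musth_state = in_musth
    return present, musth_state


def _stage_for(day: int, windows: list[tuple[int, int]]) -> str:
    for a, b in windows:
        if a <= day < b:
            frac = (day - a) / max(b - a, 1)
            return "early" if frac < 1 / 3 else ("peak" if frac < 2 / 3 else "late")
    return "none"


def simulate_sightings(
    roster: pd.DataFrame, truth: GroundTruth, config: SimConfig
) -> SightingTable:
    """Generate the dated, located group-sighting table.

    Each day, present members of a community are partitioned into groups by a
    Chinese-restaurant process with the configured concentration; each present
    individual is then detected independently with ``detection_prob`` (draws
    from its own day-keyed substream), and the detected members of a group
    form the observed group sighting.  Present males form singleton groups.
    A group's location is the mean of its members' true activity centres plus
    isotropic noise (sd = centroid_sd/2).
    """
    n_days = config.study_days
    loc_sd = config.centroid_sd / 2.0
    info = roster.set_index("individual_id")
    members_of = {
        c: [i for i in roster[roster["sex"] == "F"]["individual_id"] if truth.community[i] == c]
        for c in range(config.n_communities)
    }
    males = roster[roster["sex"] == "M"]["individual_id"].tolist()
    male_idx = {m: i for i, m in enumerate(males)}
    presence = {}
    musth_state = {}
    for m in males:
        presence[m], musth_state[m] = _male_presence(truth, m, truth.strategy[m], n_days)
    # per-individual detection draws from each individual's own substream
    females = roster[roster["sex"] == "F"]["individual_id"].tolist()
    detect = {
        i: _stream(config.seed, _MALE_DAY, k).random(n_days) < config.detection_prob
        for k, i in enumerate(females + males)
    }
    male_detect = {m: detect[m] for m in males}

    rows = []
    gid = 0
    start = pd.Timestamp(config.study_start)
    for day in range(n_days):
        date = start + pd.Timedelta(days=day)
        for c in range(config.n_communities):
            here = [i for i in members_of[c] if truth.residency[i][day]]
            if not here:
                continue
            rng = _stream(config.seed, _COMM_DAY, c, day)
            groups = _crp_partition(rng, here, config.grouping_concentration)
            for grp in groups:
                grp = [i for i in grp if detect[i][day]]
                if not grp:
                    continue
                cents = np.array([truth.centroid[i] for i in grp])
                loc = cents.mean(axis=0) + rng.normal(0, loc_sd, 2)
                gname = f"g{gid:07d}"
                gid += 1
                for i in grp:
                    rows.append(
                        (date, loc[0], loc[1], gname, i, "F", info.at[i, "age_class"], "foraging", "none")
                    )
        for m in males:
            if not presence[m][day] or not male_detect[m][day]:
                continue
            rng = _stream(config.seed, _MALE_DAY, male_idx[m], day)
            loc = np.asarray(truth.centroid[m]) + rng.normal(0, loc_sd, 2)
            if musth_state[m][day]:
                state, stage = "musth", _stage_for(day, truth.musth_windows[m])
            else:
                state, stage = "foraging", "none"
            gname = f"g{gid:07d}"
            gid += 1
            rows.append((date, loc[0], loc[1], gname, m, "M", info.at[m, "age_class"], state, stage))

    df = pd.DataFrame(
        rows,
        columns=["date", "x", "y", "group_id", "individual_id", "sex", "age_class", "state", "musth_stage"],
    )
    end = config.study_start + dt.timedelta(days=n_days - 1)
    return SightingTable(df, config.study_start, end)


def simulate(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth, SightingTable]:
    """Convenience wrapper: population then sightings."""
    roster, truth = simulate_population(config)
    table = simulate_sightings(roster, truth, config)
    return roster, truth, table
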