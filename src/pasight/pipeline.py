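"""End-to-end orchestration: simulate -> filter -> metrics -> networks -> matrix stats.

``run_male_analysis`` produces the male report section: strategy labels and
their tabulation across years seen, male-week totals with the exact binomial
comparison of the resident subset, the strategy x age cross-tabulation with
an independence test, and musth bout durations by age class.

``run_female_analysis`` runs the female pipeline: first-two-years inclusion
filter, per-year group-by-individual matrices, SRI networks, Louvain
communities with reciprocal-majority persistence, yearly BSI vectors, the
three pairwise matrices, and the MRQAP regression of BSI similarity on
association controlling for centroid distance.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import matrix_stats, metrics, network
from .io import SightingTable, build_gbi, filter_females_first_two_years, filter_glmm_males
from .simulate import SimConfig, simulate

log = logging.getLogger("pasight")

__all__ = ["RunConfig", "run_male_analysis", "run_female_analysis", "run_all"]


@dataclass
class RunConfig:
    """Thresholds and seeds for a reproducible end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    resident_bsi_days: float = 90.0
    min_overlap: int = 3
    n_perm: int = 999
    seed: int = 0
    rounding: str = "nearest"
    n_network_years: int = 2  # periods used for community detection / matching
    calendar_years: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (dt.date, dt.datetime, pd.Timestamp)):
        return obj.isoformat()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, frozenset):
        return sorted(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def male_metrics_table(
    table: SightingTable,
    males: Iterable[str],
    age_classes: Mapping[str, str],
    config: RunConfig,
) -> pd.DataFrame:
    """Per-male metrics: sightings, mean BSI, years seen, strategy, residency."""
    rows = []
    df = table.records
    for m in males:
        sub = df[df["individual_id"] == m]
        if sub.empty:
            continue
        s = metrics.compute_bsi(sub, table.study_start, config.calendar_years)
        strat = metrics.classify_strategy(sub)
        rows.append(
            {
                "individual_id": m,
                "age_class": age_classes.get(m),
                "n_sightings": s.n_sightings,
                "n_days": s.n_days,
                "mean_bsi": s.mean_bsi,
                "years_seen": len(s.years_seen),
                "strategy": strat,
                "resident": metrics.residency_flag(s, config.resident_bsi_days),
            }
        )
    return pd.DataFrame(rows)


def run_male_analysis(
    table: SightingTable, roster: pd.DataFrame, config: RunConfig
) -> dict:
    """Male PA-use report: strategies, male-weeks, binomial test, musth durations."""
    mature = roster[(roster["sex"] == "M") & (roster["age_class"] != "subadult")]
    ages = dict(zip(mature["individual_id"], mature["age_class"]))
    seen_males = [
        m for m in mature["individual_id"] if (table.records["individual_id"] == m).any()
    ]
    df = table.records
    labels: dict[str, str] = {}
    years: dict[str, set[int]] = {}
    summaries: dict[str, metrics.BSISummary] = {}
    for m in seen_males:
        sub = df[df["individual_id"] == m]
        labels[m] = metrics.classify_strategy(sub)
        s = metrics.compute_bsi(sub, table.study_start, config.calendar_years)
        summaries[m] = s
        years[m] = set(s.years_seen)

    strat_table = metrics.tabulate_strategy_by_years(labels, years, max_years=table.n_years)
    week = metrics.male_week_scores(table, seen_males)
    residents = [
        m for m in seen_males
        if metrics.residency_flag(summaries[m], config.resident_bsi_days)
    ]
    total_weeks = week.male_weeks_seen()
    musth_weeks = week.musth_weeks()
    res_weeks = week.male_weeks_seen(residents)
    res_musth = week.musth_weeks(residents)
    if musth_weeks > 0 and res_weeks > 0:
        binom_p = matrix_stats.exact_binomial_test(
            res_musth, res_weeks, musth_weeks / total_weeks
        )
    else:
        binom_p = None  # degenerate: nothing to compare

    # strategy x age cross-tab and independence test
    cross = pd.crosstab(
        pd.Series({m: ages[m] for m in seen_males}, name="age_class"),
        pd.Series(labels, name="strategy"),
    )
    test = None
    nonzero = cross.loc[(cross.sum(axis=1) > 0), (cross.sum(axis=0) > 0)]
    if nonzero.shape[0] >= 2 and nonzero.shape[1] >= 2:
        test = matrix_stats.contingency_independence_test(
            nonzero.to_numpy(), seed=config.seed
        )

    # complete musth bouts, duration by age class
    bouts = []
    for m in seen_males:
        for b in metrics.musth_bouts(df[df["individual_id"] == m]):
            if b.complete:
                bouts.append({"individual_id": m, "age_class": ages[m], "duration": b.duration})
    bout_df = pd.DataFrame(bouts, columns=["individual_id", "age_class", "duration"])
    dur_summary = (
        bout_df.groupby("age_class")["duration"].median().to_dict() if len(bout_df) else {}
    )

    glmm_males = filter_glmm_males(
        mature[mature["individual_id"].isin(seen_males)],
        {m: summaries[m].n_days for m in seen_males},
    )
    frame = matrix_stats.build_glmm_frame(table, glmm_males, labels, ages)

    return {
        "n_mature_males": len(seen_males),
        "strategy_totals": strat_table.strategy_totals().to_dict(),
        "strategy_by_years_counts": strat_table.counts,
        "strategy_by_years_percent": strat_table.percent(config.rounding),
        "male_weeks": {
            "total_seen": total_weeks,
            "musth": musth_weeks,
            "musth_percent": 100.0 * musth_weeks / total_weeks if total_weeks else None,
            "resident_seen": res_weeks,
            "resident_musth": res_musth,
            "resident_musth_percent": 100.0 * res_musth / res_weeks if res_weeks else None,
            "n_residents": len(residents),
            "binomial_p": binom_p,
        },
        "strategy_age_crosstab": cross,
        "strategy_age_test": test,
        "musth_duration_median_by_age": dur_summary,
        "n_complete_bouts": int(len(bout_df)),
        "glmm_frame_males": len(glmm_males),
        "glmm_frame_rows": len(frame),
    }


def run_female_analysis(
    table: SightingTable,
    config: RunConfig,
    known_deaths: Iterable[str] = (),
) -> dict:
    """Female PA-use report: communities, persistence, and the MRQAP regression."""
    females = filter_females_first_two_years(table, known_deaths)
    if len(females) < 2:
        raise ValueError("fewer than 2 qualifying females")
    df = table.records
    fem_df = df[df["individual_id"].isin(females)].copy()
    fem_df["year"] = table.study_year(fem_df["date"])

    partitions = []
    for year in range(1, config.n_network_years + 1):
        sub = SightingTable(
            fem_df[fem_df["year"] == year].drop(columns="year"),
            table.study_start,
            table.study_end,
            config.calendar_years,
        )
        present = sorted(sub.records["individual_id"].unique())
        if len(present) < 2:
            continue
        gbi = build_gbi(sub, present)
        assoc = network.sri_matrix(gbi, period=f"year{year}")
        partitions.append(network.detect_communities(assoc, seed=config.seed))

    if len(partitions) >= 2:
        dyn = network.match_communities(partitions[0], partitions[1])
        assignment = dyn.consensus_assignment()
    elif partitions:
        assignment = dict(partitions[0].membership)
    else:
        assignment = {}

    # yearly BSI vectors over the whole study
    yearly = {}
    years_seen = {}
    for fid in females:
        sub = fem_df[fem_df["individual_id"] == fid].drop(columns="year")
        s = metrics.compute_bsi(sub, table.study_start, config.calendar_years)
        yearly[fid] = s.yearly_mean_bsi
        years_seen[fid] = set(s.years_seen)
    yearly_df = pd.DataFrame.from_dict(yearly, orient="index").reindex(
        columns=range(1, table.n_years + 1)
    ).loc[females]

    comm_summary = network.community_summary(assignment, years_seen)

    # pairwise matrices for MRQAP: SRI over all years pooled
    full_table = table.subset(females)
    gbi_all = build_gbi(full_table, females)
    assoc_all = network.sri_matrix(gbi_all, period="all")
    sri_pm = matrix_stats.PairwiseMatrix(assoc_all.sri, females, "sri")
    dep = matrix_stats.bsi_correlation_matrix(yearly_df, config.min_overlap)
    dist = matrix_stats.centroid_distance_matrix(full_table, females)
    result = matrix_stats.mrqap(
        dep, [sri_pm, dist], n_perm=config.n_perm, seed=config.seed
    )

    return {
        "n_females": len(females),
        "n_partitions": len(partitions),
        "partitions": [
            {"period": p.period, "n_communities": p.n_communities, "modularity": p.modularity}
            for p in partitions
        ],
        "community_summary": comm_summary,
        "community_sizes": sorted(comm_summary["size"].tolist(), reverse=True)
        if len(comm_summary)
        else [],
        "mrqap": result,
    }


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate under ``config.sim`` and run both analysis arms; optionally write outputs."""
    roster, truth, table = simulate(config.sim)
    log.info("simulated %d records (seed=%d)", len(table), config.sim.seed)
    report = {
        "config": {"seed": config.seed, "sim_seed": config.sim.seed, "n_perm": config.n_perm},
        "male": run_male_analysis(table, roster, config),
        "female": run_female_analysis(table, config),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_sightings

        write_sightings(table, out / "sightings.csv")
        truth.to_json(out / "ground_truth.json")
        roster.to_csv(out / "roster.csv", index=False)
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report
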