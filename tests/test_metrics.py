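import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pasight import metrics
from pasight.metrics import (
    FORAGING_AND_MUSTH,
    FORAGING_ONLY,
    MUSTH_ONLY,
    classify_strategy,
    compute_bsi,
    male_week_scores,
    musth_bouts,
    residency_flag,
    tabulate_strategy_by_years,
)
from conftest import START, make_table


def records_for(ind, day_state_pairs, sex="M", age="21-30"):
    rows = [(d, ind, sex, age, s) for d, s in day_state_pairs]
    return make_table(rows, study_days=8 * 365).records


class TestBSI:
    @pytest.mark.parametrize(
        "days,expected",
        [([0, 10, 30], 15.0), ([5], None), ([5, 6, 7, 8], 1.0)],
    )
    def test_mean_bsi_examples(self, days, expected):
        recs = records_for("A", [(d, "foraging") for d in days], sex="F")
        s = compute_bsi(recs, START)
        assert s.mean_bsi == expected

    def test_same_day_sightings_collapse(self):
        recs = records_for("A", [(0, "foraging"), (0, "foraging"), (10, "foraging")], sex="F")
        s = compute_bsi(recs, START)
        assert s.n_days == 2 and s.mean_bsi == 10.0

    def test_mixed_ids_rejected(self):
        recs = pd.concat(
            [records_for("A", [(0, "foraging")], sex="F"), records_for("B", [(1, "foraging")], sex="F")]
        )
        with pytest.raises(ValueError, match="mix"):
            compute_bsi(recs, START)

    def test_yearly_means_use_within_year_gaps(self):
        recs = records_for("A", [(0, "foraging"), (10, "foraging"), (400, "foraging"), (420, "foraging")], sex="F")
        s = compute_bsi(recs, START)
        assert s.yearly_mean_bsi == {1: 10.0, 2: 20.0}
        assert s.mean_bsi == pytest.approx(420 / 3)
        assert s.years_seen == frozenset({1, 2})

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.sets(st.integers(min_value=0, max_value=2000), min_size=2, max_size=40))
    def test_mean_gap_identity(self, days):
        """Mean of consecutive gaps equals (last - first)/(n - 1) on distinct days."""
        recs = records_for("A", [(d, "foraging") for d in sorted(days)], sex="F")
        s = compute_bsi(recs, START)
        days = sorted(days)
        assert s.mean_bsi == pytest.approx((days[-1] - days[0]) / (len(days) - 1))
        assert s.mean_bsi >= 1.0


class TestStrategy:
    @pytest.mark.parametrize(
        "states,expected",
        [
            (["foraging", "foraging"], FORAGING_ONLY),
            (["musth"], MUSTH_ONLY),
            (["foraging", "musth"], FORAGING_AND_MUSTH),
        ],
    )
    def test_classification(self, states, expected):
        recs = records_for("M1", list(enumerate(states)))
        assert classify_strategy(recs) == expected

    def test_order_invariant(self):
        recs = records_for("M1", [(0, "musth"), (5, "foraging"), (9, "musth")])
        assert classify_strategy(recs) == classify_strategy(recs.iloc[::-1])

    def test_zero_sightings_error(self):
        with pytest.raises(ValueError):
            classify_strategy(records_for("M1", []).head(0))

    def test_simulated_musth_only_males_recovered(self, small_sim):
        """Males generated with strategy m are classified musth_only whenever
        all their emitted sightings fall inside musth windows."""
        cfg, roster, truth, table = small_sim
        df = table.records
        checked = 0
        for m, strat in truth.strategy.items():
            sub = df[df.individual_id == m]
            if strat != "m" or sub.empty:
                continue
            days = (pd.to_datetime(sub.date) - pd.Timestamp(cfg.study_start)).dt.days
            in_window = days.apply(
                lambda d: any(a <= d < b for a, b in truth.musth_windows[m])
            )
            assert in_window.all()
            assert classify_strategy(sub) == MUSTH_ONLY
            checked += 1
        assert checked > 0


class TestMaleWeeks:
    def test_musth_any_time_in_week_scores_two(self):
        t = make_table(
            [(0, "M1", "M", "21-30", "musth"), (4, "M1", "M", "21-30", "foraging")]
        )
        w = male_week_scores(t, ["M1"])
        assert w.scores[0, 0] == 2

    def test_no_sightings_all_zero(self):
        t = make_table([], study_days=730)
        w = male_week_scores(t, [f"M{i}" for i in range(10)])
        assert w.male_weeks_seen() == 0 and (w.scores == 0).all()

    def test_three_distinct_bins(self):
        t = make_table([(d, "M1", "M", "21-30", "foraging") for d in (0, 7, 21)])
        w = male_week_scores(t, ["M1"])
        assert w.male_weeks_seen() == 3 and w.musth_weeks() == 0

    def test_partition_of_male_weeks(self, small_sim):
        _, roster, _, table = small_sim
        males = roster[roster.sex == "M"].individual_id.tolist()
        w = male_week_scores(table, males)
        assert w.male_weeks_seen() == w.musth_weeks() + w.foraging_weeks()


class TestMusthBouts:
    def test_single_bracketed_bout(self):
        recs = records_for(
            "M1", [(90, "foraging"), (100, "musth"), (110, "musth"), (120, "musth"), (130, "foraging")]
        )
        bouts = musth_bouts(recs)
        assert len(bouts) == 1
        b = bouts[0]
        assert b.duration == 20 and b.complete

    def test_interrupted_run_splits(self):
        recs = records_for("M1", [(100, "musth"), (105, "foraging"), (110, "musth")])
        bouts = musth_bouts(recs)
        assert len(bouts) == 2
        assert not bouts[0].complete and not bouts[1].complete

    def test_degenerate_single_sighting_bout(self):
        recs = records_for("M1", [(90, "foraging"), (100, "musth"), (110, "foraging")])
        (b,) = musth_bouts(recs)
        assert b.duration == 0 and b.complete

    def test_run_splitting_matches_oracle(self):
        """Bout boundaries agree with a direct run-splitting oracle on random sequences."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(1, 25)
            days = np.sort(rng.choice(2800, size=n, replace=False))
            states = rng.choice(["foraging", "musth"], size=n)
            recs = records_for("M1", list(zip(days.tolist(), states.tolist())))
            # oracle: group consecutive musth entries
            runs = []
            cur = []
            for d, s in zip(days, states):
                if s == "musth":
                    cur.append(d)
                elif cur:
                    runs.append(cur)
                    cur = []
            if cur:
                runs.append(cur)
            got = musth_bouts(recs)
            assert [b.duration for b in got] == [r[-1] - r[0] for r in runs]


class TestResidency:
    @pytest.mark.parametrize(
        "bsi,years,expected",
        [(30.0, {1, 2, 3}, True), (30.0, {1}, False), (90.0, {1, 2}, False), (None, {1, 2}, False)],
    )
    def test_flag(self, bsi, years, expected):
        s = metrics.BSISummary("A", 5, 5, bsi, START, START, frozenset(years))
        assert residency_flag(s) is expected


class TestStrategyYearTable:
    def test_foraging_only_percentages(self):
        labels = {}
        years = {}
        k = 0
        # 99 foraging-only males: 11 seen in all 6 years, 38 in one, rest in two
        for n_years, count in [(6, 11), (1, 38), (2, 50)]:
            for _ in range(count):
                labels[f"m{k}"] = FORAGING_ONLY
                years[f"m{k}"] = set(range(1, n_years + 1))
                k += 1
        tab = tabulate_strategy_by_years(labels, years, max_years=6)
        pct = tab.percent()
        assert pct.loc[6, FORAGING_ONLY] == pytest.approx(11.1, abs=0.05)
        assert pct.loc[1, FORAGING_ONLY] == pytest.approx(38.4, abs=0.05)

    def test_single_male(self):
        tab = tabulate_strategy_by_years({"m": MUSTH_ONLY}, {"m": {1}})
        assert tab.counts.loc[1, MUSTH_ONLY] == 1
        assert tab.counts.to_numpy().sum() == 1

    def test_columns_sum_to_100(self):
        rng = np.random.default_rng(0)
        labels = {f"m{i}": rng.choice(metrics.STRATEGIES) for i in range(60)}
        years = {m: set(rng.choice(6, size=rng.integers(1, 6), replace=False) + 1) for m in labels}
        pct = tabulate_strategy_by_years(labels, years).percent(decimals=8)
        sums = pct.sum(axis=0)
        for strat in metrics.STRATEGIES:
            if (pd.Series(labels) == strat).any():
                assert sums[strat] == pytest.approx(100.0, abs=1e-6)
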