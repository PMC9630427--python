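import numpy as np
import pytest

from pasight.io import GroupByIndividualMatrix
from pasight.network import (
    CommunityPartition,
    community_summary,
    detect_communities,
    match_communities,
    propagate_communities,
    sri_matrix,
)


def gbi_from_rows(rows, ids):
    return GroupByIndividualMatrix(np.asarray(rows, dtype=np.int8), [f"g{i}" for i in range(len(rows))], ids)


def assoc_from_matrix(mat, ids):
    from pasight.network import AssociationMatrix

    m = np.asarray(mat, dtype=float)
    return AssociationMatrix(m, np.zeros_like(m, dtype=int), np.ones_like(m, dtype=int), ids)


class TestSRI:
    def test_always_together(self):
        gbi = gbi_from_rows([[1, 1]] * 5, ["A", "B"])
        assert sri_matrix(gbi).sri[0, 1] == 1.0

    def test_toy_counts(self):
        # x=2 joint rows, one row with only A, one with only B -> 2/4
        gbi = gbi_from_rows([[1, 1], [1, 1], [1, 0], [0, 1]], ["A", "B"])
        a = sri_matrix(gbi)
        assert a.sri[0, 1] == 0.5
        assert a.x[0, 1] == 2 and a.denom[0, 1] == 4

    def test_never_together(self):
        gbi = gbi_from_rows([[1, 0], [0, 1]], ["A", "B"])
        assert sri_matrix(gbi).sri[0, 1] == 0.0

    def test_symmetric_bounded_and_row_permutation_invariant(self):
        rng = np.random.default_rng(2)
        rows = (rng.random((40, 8)) < 0.3).astype(np.int8)
        rows = rows[rows.sum(axis=1) > 0]
        ids = [f"i{k}" for k in range(8)]
        a = sri_matrix(gbi_from_rows(rows, ids))
        assert np.allclose(a.sri, a.sri.T)
        assert (a.sri >= 0).all() and (a.sri <= 1).all()
        perm = rng.permutation(len(rows))
        b = sri_matrix(gbi_from_rows(rows[perm], ids))
        assert np.allclose(a.sri, b.sri)

    def test_day_level_units_count_seen_apart(self):
        # same day, two different groups: both seen but apart -> x=0, denom=1
        gbi = gbi_from_rows([[1, 0], [0, 1]], ["A", "B"])
        a = sri_matrix(gbi, sampling_unit="day", group_dates=["d0", "d0"])
        assert a.denom[0, 1] == 1 and a.sri[0, 1] == 0.0
        # and a joint day counts once in both x and denom
        gbi2 = gbi_from_rows([[1, 1], [1, 0], [0, 1]], ["A", "B"])
        a2 = sri_matrix(gbi2, sampling_unit="day", group_dates=["d0", "d1", "d1"])
        assert a2.x[0, 1] == 1 and a2.denom[0, 1] == 2 and a2.sri[0, 1] == 0.5

    def test_empty_gbi_rejected(self):
        with pytest.raises(ValueError):
            sri_matrix(gbi_from_rows(np.zeros((0, 2)), ["A", "B"]))


class TestCommunities:
    def test_two_cliques_split(self):
        ids = list("ABCDEFGH")
        m = np.zeros((8, 8))
        m[:4, :4] = 1.0
        m[4:, 4:] = 1.0
        np.fill_diagonal(m, 0)
        part = detect_communities(assoc_from_matrix(m, ids), seed=0)
        comms = part.communities()
        assert len(comms) == 2
        assert {frozenset(c) for c in comms.values()} == {
            frozenset("ABCD"),
            frozenset("EFGH"),
        }
        assert part.modularity > 0

    def test_uniform_complete_graph_single_community(self):
        ids = list("ABCDE")
        m = np.ones((5, 5)) - np.eye(5)
        part = detect_communities(assoc_from_matrix(m, ids), seed=1)
        assert part.n_communities == 1

    def test_planted_three_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(9)
        sizes = [10, 8, 7]
        truth = np.repeat(np.arange(3), sizes)
        n = truth.size
        ids = [f"i{k}" for k in range(n)]
        aris = []
        for seed in range(10):
            m = np.where(truth[:, None] == truth[None, :], 0.6, 0.02)
            noise = rng.normal(0, 0.02, (n, n))
            m = np.clip(m + (noise + noise.T) / 2, 0, 1)
            np.fill_diagonal(m, 0)
            part = detect_communities(assoc_from_matrix(m, ids), seed=seed)
            pred = [part.membership[i] for i in ids]
            aris.append(adjusted_rand_score(truth, pred))
        assert np.median(aris) > 0.9

    def test_disconnected_components_never_merged(self):
        rng = np.random.default_rng(3)
        n = 12
        ids = [f"i{k}" for k in range(n)]
        m = np.zeros((n, n))
        for block in (slice(0, 6), slice(6, 12)):
            sub = rng.random((6, 6)) * 0.5
            m[block, block] = (sub + sub.T) / 2
        np.fill_diagonal(m, 0)
        part = detect_communities(assoc_from_matrix(m, ids), seed=4)
        left = {part.membership[i] for i in ids[:6]}
        right = {part.membership[i] for i in ids[6:]}
        assert left.isdisjoint(right)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        m = rng.random((15, 15))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"i{k}" for k in range(15)]
        a = assoc_from_matrix(m, ids)
        p1 = detect_communities(a, seed=42)
        p2 = detect_communities(a, seed=42)
        assert p1.membership == p2.membership

    def test_empty_network_warns_singletons(self):
        m = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="empty network"):
            part = detect_communities(assoc_from_matrix(m, ["A", "B", "C"]), seed=0)
        assert part.n_communities == 3

    def test_agrees_with_igraph_on_modular_graph(self):
        """Independent cross-check: igraph's Louvain finds the same partition
        on a clearly modular weighted graph."""
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(12)
        sizes = [6, 6, 6]
        truth = np.repeat(np.arange(3), sizes)
        n = truth.size
        m = np.where(truth[:, None] == truth[None, :], 0.8, 0.05)
        np.fill_diagonal(m, 0)
        ids = [f"i{k}" for k in range(n)]
        ours = detect_communities(assoc_from_matrix(m, ids), seed=0)
        g = igraph.Graph.Weighted_Adjacency(m.tolist(), mode="undirected")
        theirs = g.community_multilevel(weights="weight")
        ours_labels = [ours.membership[i] for i in ids]
        theirs_labels = theirs.membership
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(ours_labels, theirs_labels) == 1.0


def part(d, period=""):
    return CommunityPartition(d, period)


class TestMatching:
    def test_majority_match(self):
        p1 = part({1: 0, 2: 0, 3: 0})
        p2 = part({1: 0, 2: 0, 4: 0})
        m = match_communities(p1, p2)
        assert m.matches == {0: 0}

    def test_insufficient_overlap_no_match(self):
        p1 = part({1: 0, 2: 0})
        p2 = part({1: 0, 3: 0, 4: 0, 5: 0})
        m = match_communities(p1, p2)
        assert m.matches == {}
        assert m.persistent[0] == 1  # unmatched cluster gets a fresh ID

    def test_exactly_half_does_not_match(self):
        p1 = part({1: 0, 2: 0})
        p2 = part({1: 0, 3: 0})
        # overlap 1 == |A|/2 == |B|/2: strict majority fails
        assert match_communities(p1, p2).matches == {}

    def test_identity_on_identical_partitions(self):
        p = part({i: i % 3 for i in range(9)})
        m = match_communities(p, p)
        assert m.matches == {0: 0, 1: 1, 2: 2}
        assert m.consensus_assignment() == p.membership

    def test_random_partitions_match_set_oracle(self):
        """Reciprocal-majority matching agrees with direct set arithmetic and
        is one-to-one (a set cannot have two disjoint strict majorities)."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            a = {i: int(rng.integers(0, 4)) for i in range(n)}
            b = {i: int(rng.integers(0, 4)) for i in rng.permutation(n)[: rng.integers(2, n + 1)]}
            m = match_communities(part(a), part(b))
            # oracle
            ca, cb = {}, {}
            for i, c in a.items():
                ca.setdefault(c, set()).add(i)
            for i, c in b.items():
                cb.setdefault(c, set()).add(i)
            expected = {}
            for la, ma in ca.items():
                for lb, mb in cb.items():
                    inter = len(ma & mb)
                    if inter > len(ma) / 2 and inter > len(mb) / 2:
                        assert la not in expected
                        expected[la] = lb
            assert m.matches == expected
            assert len(set(m.matches.values())) == len(m.matches)


class TestSummary:
    def test_propagate_and_sizes(self, small_sim):
        cfg, roster, truth, table = small_sim
        assignment = {i: c for i, c in truth.community.items()}
        summary = community_summary(assignment)
        assert summary["size"].sum() == len(assignment)
        assert sorted(summary["size"]) == sorted(cfg.community_sizes)

    def test_single_pair_community(self):
        s = community_summary({"a": 0, "b": 0})
        assert s.loc[0, "size"] == 2

    def test_propagate_chains_persistent_ids(self):
        p1 = part({1: 0, 2: 0, 3: 1, 4: 1}, "y1")
        p2 = part({1: 0, 2: 0, 3: 1, 4: 1}, "y2")
        p3 = part({1: 5, 2: 5, 9: 5}, "y3")
        df = propagate_communities([p1, p2, p3])
        y3 = df[df.period == "y3"]
        assert set(y3.persistent_id) == {0}  # {1,2,9} majority-matches {1,2}
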