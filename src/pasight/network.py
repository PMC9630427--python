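"""SRI association matrices, yearly networks, Louvain communities and dynamic matching.

The simple ratio index (SRI) between two individuals is the proportion of
sampling units in which the pair was seen together out of all sampling units
in which at least one of the pair was seen.  With group sightings as the
sampling unit the classic "seen apart in the same unit" term is structurally
zero; a day-level option makes it enter the denominator.

Communities are detected per period by weighted-modularity Louvain, and
tracked across periods by reciprocal majority: clusters in consecutive years
are the same social community iff their intersection exceeds half of *each*
cluster ("more than half" read strictly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import GroupByIndividualMatrix

__all__ = [
    "AssociationMatrix",
    "CommunityPartition",
    "DynamicCommunityMap",
    "sri_matrix",
    "detect_communities",
    "match_communities",
    "propagate_communities",
    "community_summary",
]


@dataclass
class AssociationMatrix:
    """Symmetric SRI matrix with its co-occurrence components.

    ``x[i, j]`` counts sampling units containing both individuals; ``denom``
    counts units containing at least one of the pair (plus, for day-level
    units, days on which both were seen but in different groups).
    """

    sri: np.ndarray
    x: np.ndarray
    denom: np.ndarray
    ids: list[str]
    period: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.sri, float)
        if not np.allclose(s, s.T):
            raise ValueError("association matrix must be symmetric")
        if (s < -1e-12).any() or (s > 1 + 1e-12).any():
            raise ValueError("SRI values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        iu, ju = np.triu_indices(self.n, k=1)
        for i, j in zip(iu, ju):
            w = self.sri[i, j]
            if w > 0:
                g.add_edge(self.ids[i], self.ids[j], weight=float(w))
        return g

    def to_edgelist(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.n, k=1)
        return pd.DataFrame(
            {
                "id_i": [self.ids[i] for i in iu],
                "id_j": [self.ids[j] for j in ju],
                "sri": self.sri[iu, ju],
                "period": self.period,
            }
        )


def sri_matrix(
    gbi: GroupByIndividualMatrix,
    period: str = "",
    sampling_unit: str = "group",
    group_dates: Sequence | None = None,
) -> AssociationMatrix:
    """Compute pairwise simple ratio indices from a group-by-individual matrix.

    With ``sampling_unit="group"`` each GBI row is one unit: SRI = x / (x + yA
    + yB) where x counts joint rows and yA, yB rows with exactly one of the
    pair.  With ``sampling_unit="day"`` rows sharing a date are one unit and
    days on which both were seen in different groups also enter the
    denominator; ``group_dates`` must then give one date per GBI row.
    """
    if gbi.matrix.shape[0] == 0:
        raise ValueError("GBI is empty")
    g = gbi.matrix.astype(np.int64)
    if sampling_unit == "group":
        x = g.T @ g  # joint counts; diagonal = per-individual totals
        n_i = np.diag(x).copy()
        denom = n_i[:, None] + n_i[None, :] - x
    elif sampling_unit == "day":
        if group_dates is None or len(group_dates) != g.shape[0]:
            raise ValueError("day-level SRI needs one date per GBI row")
        dates = pd.Series(group_dates)
        seen = np.zeros((dates.nunique(), g.shape[1]), dtype=np.int64)
        together = np.zeros((g.shape[1], g.shape[1]), dtype=np.int64)
        for d, (_, idx) in enumerate(dates.groupby(dates).groups.items()):
            sub = g[np.asarray(idx)]
            seen[d] = sub.max(axis=0)
            together += ((sub.T @ sub) > 0).astype(np.int64)
        np.fill_diagonal(together, 0)
        x = together
        si = seen.sum(axis=0)
        both_days = seen.T @ seen  # days both seen (same group or not)
        # days at least one was seen = x + yAB + yA + yB, the classic SRI denominator
        denom = si[:, None] + si[None, :] - both_days
    else:
        raise ValueError(f"unknown sampling_unit {sampling_unit!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        sri = np.where(denom > 0, x / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(sri, 0.0)
    xx = x.copy()
    np.fill_diagonal(xx, 0)
    return AssociationMatrix(sri, xx, denom, list(gbi.individual_ids), period)


@dataclass
class CommunityPartition:
    """Mapping individual -> community label for one period, with modularity."""

    membership: dict[str, int]
    period: str = ""
    modularity: float = 0.0

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for ind, c in self.membership.items():
            out.setdefault(c, set()).add(ind)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def detect_communities(
    assoc: AssociationMatrix, seed: int = 0, resolution: float = 1.0
) -> CommunityPartition:
    """Louvain weighted-modularity communities of an SRI network.

    Deterministic given ``seed``.  Individuals with no positive-weight edge
    become singletons.  Labels are contiguous integers ordered by (size
    descending, smallest member id).
    """
    if assoc.n < 2:
        raise ValueError("need at least 2 individuals")
    g = assoc.to_graph()
    if g.number_of_edges() == 0:
        warnings.warn("empty network: returning singleton partition", stacklevel=2)
        membership = {ind: i for i, ind in enumerate(sorted(g.nodes))}
        return CommunityPartition(membership, assoc.period, 0.0)
    comms = nx.community.louvain_communities(g, weight="weight", seed=int(seed), resolution=resolution)
    mod = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
    ordered = sorted(comms, key=lambda c: (-len(c), min(c)))
    membership = {ind: lbl for lbl, c in enumerate(ordered) for ind in sorted(c)}
    return CommunityPartition(membership, assoc.period, float(mod))


@dataclass
class DynamicCommunityMap:
    """Reciprocal-majority matches between two consecutive partitions.

    ``matches`` maps period-t labels to period-t+1 labels (one-to-one on
    matched pairs).  ``persistent`` maps every period-t+1 label to a
    persistent community ID: matched clusters inherit the earlier cluster's
    persistent ID, unmatched clusters receive fresh IDs.
    """

    matches: dict[int, int]
    persistent: dict[int, int]
    earlier: CommunityPartition = field(repr=False)
    later: CommunityPartition = field(repr=False)

    def consensus_assignment(self) -> dict[str, int]:
        """Assign each individual a community from the two-period consensus.

        Individuals present in the later period take their later cluster's
        persistent ID; individuals seen only in the earlier period keep their
        earlier label.  This realises assignment "based on the first 2 years"
        when the map spans study years 1 and 2.
        """
        out: dict[str, int] = {}
        for ind, c in self.earlier.membership.items():
            out[ind] = c
        for ind, c in self.later.membership.items():
            out[ind] = self.persistent[c]
        return out


def match_communities(
    p_t: CommunityPartition,
    p_t1: CommunityPartition,
    persistent_of_earlier: Mapping[int, int] | None = None,
    next_fresh_id: int | None = None,
) -> DynamicCommunityMap:
    """Match clusters across consecutive periods by reciprocal majority.

    Clusters A (period t) and B (period t+1) are the same community iff
    |A ∩ B| > |A|/2 and |A ∩ B| > |B|/2; an exactly-half overlap does not
    match.  At most one B can match a given A (two disjoint strict majorities
    of a set are impossible), so the mapping is one-to-one.
    """
    comms_t = p_t.communities()
    comms_t1 = p_t1.communities()
    pers_earlier = dict(persistent_of_earlier or {c: c for c in comms_t})
    matches: dict[int, int] = {}
    for a, members_a in comms_t.items():
        for b, members_b in comms_t1.items():
            inter = len(members_a & members_b)
            if inter * 2 > len(members_a) and inter * 2 > len(members_b):
                matches[a] = b
                break
    fresh = next_fresh_id
    if fresh is None:
        fresh = (max(pers_earlier.values()) + 1) if pers_earlier else 0
    persistent: dict[int, int] = {}
    matched_b = {b: a for a, b in matches.items()}
    for b in sorted(comms_t1):
        if b in matched_b:
            persistent[b] = pers_earlier[matched_b[b]]
        else:
            persistent[b] = fresh
            fresh += 1
    return DynamicCommunityMap(matches, persistent, p_t, p_t1)


def propagate_communities(partitions: Sequence[CommunityPartition]) -> pd.DataFrame:
    """Chain reciprocal-majority matching across >= 2 periods.

    Returns a long table (individual, period, community, persistent_id) in
    which persistent IDs flow forward through matched clusters and fresh IDs
    are issued to unmatched ones.
    """
    if not partitions:
        return pd.DataFrame(columns=["individual", "period", "community", "persistent_id"])
    rows = []
    pers = {c: c for c in partitions[0].communities()}
    fresh = (max(pers.values()) + 1) if pers else 0
    for ind, c in partitions[0].membership.items():
        rows.append((ind, partitions[0].period, c, pers[c]))
    for earlier, later in zip(partitions, partitions[1:]):
        m = match_communities(earlier, later, pers, fresh)
        pers = m.persistent
        fresh = max(max(pers.values(), default=-1) + 1, fresh)
        for ind, c in later.membership.items():
            rows.append((ind, later.period, c, pers[c]))
    return pd.DataFrame(rows, columns=["individual", "period", "community", "persistent_id"])


def community_summary(
    assignment: Mapping[str, int], years_seen: Mapping[str, Iterable[int]] | None = None
) -> pd.DataFrame:
    """Per-community size, member list and (optionally) mean years seen."""
    rows = []
    by_comm: dict[int, list[str]] = {}
    for ind, c in assignment.items():
        by_comm.setdefault(c, []).append(ind)
    for c in sorted(by_comm):
        members = sorted(by_comm[c])
        row = {"community": c, "size": len(members), "members": ",".join(members)}
        if years_seen is not None:
            counts = [len(set(years_seen[m])) for m in members if m in years_seen]
            row["mean_years_seen"] = float(np.mean(counts)) if counts else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
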