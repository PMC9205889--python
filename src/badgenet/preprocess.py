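"""Badge-stream preprocessing.

Turns raw per-minute detection and movement streams into gap-merged
interaction episodes, filtered participant sets, per-organization weighted
interaction networks, activity-classified sub-networks, and CES-D totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .synthgen import MINUTES_PER_DAY, POSITIVE_ITEMS_DEFAULT, Roster

__all__ = [
    "DataError",
    "InteractionNetwork",
    "merge_episodes",
    "episode_movement",
    "filter_participants",
    "build_network",
    "build_networks",
    "classify_activity",
    "subnetwork_by_activity",
    "score_cesd",
    "wear_minutes",
    "interaction_minutes",
]

#: Default merge rule: an empty interval shorter than 5 minutes joins two
#: detection runs into one episode; exactly 5 empty minutes splits them.
GAP_LIMIT_DEFAULT = 5

#: Participant retention thresholds: at least 5 h of device wear and at
#: least 1 h of face-to-face interaction time.
MIN_WEAR_MINUTES = 300
MIN_INTERACTION_MINUTES = 60

EPISODE_COLUMNS = [
    "org_id",
    "person_u",
    "person_v",
    "start_minute",
    "end_minute",
    "duration",
]


class DataError(ValueError):
    """Raised on malformed badge records (self-detections, cross-org dyads...)."""


@dataclass
class InteractionNetwork:
    """Per-organization undirected interaction network.

    Edge weight is the average number of interaction episodes per day
    (``episodes / n_days``); isolated retained persons stay as nodes.
    """

    org: str
    graph: nx.Graph
    n_days: int

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()


def merge_episodes(
    detections: pd.DataFrame, gap_limit: int = GAP_LIMIT_DEFAULT
) -> pd.DataFrame:
    """Merge per-minute dyadic detections into interaction episodes.

    Two detection minutes ``m1 < m2`` of the same dyad belong to the same
    episode iff the empty interval between them (``m2 - m1 - 1`` minutes)
    is shorter than ``gap_limit``. Detections recorded by either member of
    the dyad count; episodes span ``[first, last + 1)``.

    Returns an episode frame with columns org_id, person_u, person_v,
    start_minute, end_minute, duration (person_u < person_v).
    """
    if gap_limit < 0:
        raise ValueError("gap_limit must be >= 0")
    if len(detections) == 0:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    d = detections
    if (d["person_id"] == d["counterpart_id"]).any():
        bad = d.index[d["person_id"] == d["counterpart_id"]][0]
        raise DataError(f"self-detection record at row {bad}")
    u = np.minimum(d["person_id"], d["counterpart_id"])
    v = np.maximum(d["person_id"], d["counterpart_id"])
    dyads = pd.DataFrame(
        {"org_id": d["org_id"].to_numpy(), "person_u": u, "person_v": v,
         "minute": d["minute"].to_numpy()}
    ).drop_duplicates(["person_u", "person_v", "minute"])
    dyads = dyads.sort_values(["person_u", "person_v", "minute"], kind="stable")

    same_dyad = (
        (dyads["person_u"] == dyads["person_u"].shift())
        & (dyads["person_v"] == dyads["person_v"].shift())
    ).to_numpy()
    gap = dyads["minute"].diff().to_numpy()
    # merge iff m2 - m1 - 1 < gap_limit  <=>  m2 - m1 <= gap_limit
    new_episode = ~same_dyad | (gap > gap_limit)
    ep_id = np.cumsum(new_episode)
    episodes = (
        dyads.assign(_ep=ep_id)
        .groupby("_ep", sort=True)
        .agg(
            org_id=("org_id", "first"),
            person_u=("person_u", "first"),
            person_v=("person_v", "first"),
            start_minute=("minute", "min"),
            end_minute=("minute", "max"),
        )
        .reset_index(drop=True)
    )
    episodes["end_minute"] = episodes["end_minute"] + 1  # half-open
    episodes["duration"] = episodes["end_minute"] - episodes["start_minute"]
    return episodes[EPISODE_COLUMNS]


def episode_movement(episodes: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Attach per-member mean zero-cross counts to each episode.

    The mean is taken over the movement samples available inside the
    episode's minute span; an episode member with no in-span samples gets
    NaN (and the episode is later skipped by activity classification).

    Adds columns movement_u and movement_v.
    """
    out = episodes.copy()
    if len(episodes) == 0:
        out["movement_u"] = pd.Series(dtype=float)
        out["movement_v"] = pd.Series(dtype=float)
        return out
    durations = episodes["duration"].to_numpy()
    ep_idx = np.repeat(np.arange(len(episodes)), durations)
    minute = np.repeat(episodes["start_minute"].to_numpy(), durations)
    offs = np.arange(len(minute)) - np.repeat(
        np.cumsum(durations) - durations, durations
    )
    minute = minute + offs
    lookup = samples.set_index(["person_id", "minute"])["zero_cross"]
    for side in ("u", "v"):
        person = np.repeat(episodes[f"person_{side}"].to_numpy(), durations)
        idx = pd.MultiIndex.from_arrays([person, minute])
        vals = lookup.reindex(idx).to_numpy(dtype=float)
        means = (
            pd.DataFrame({"_ep": ep_idx, "val": vals})
            .groupby("_ep")["val"]
            .mean()  # NaN-skipping; all-NaN span stays NaN
        )
        out[f"movement_{side}"] = means.reindex(range(len(episodes))).to_numpy()
    return out


def wear_minutes(samples: pd.DataFrame) -> pd.Series:
    """Device wear time per person = number of minutes with any movement sample."""
    if len(samples) == 0:
        return pd.Series(dtype=int, name="wear_minutes")
    return (
        samples.groupby("person_id")["minute"].nunique().rename("wear_minutes")
    )


def interaction_minutes(episodes: pd.DataFrame) -> pd.Series:
    """Total face-to-face interaction minutes per person (sum of episode durations)."""
    if len(episodes) == 0:
        return pd.Series(dtype=int, name="interaction_minutes")
    per_side = [
        episodes.groupby(f"person_{s}")["duration"].sum() for s in ("u", "v")
    ]
    total = per_side[0].add(per_side[1], fill_value=0).astype(int)
    total.index.name = "person_id"
    return total.rename("interaction_minutes")


def filter_participants(
    episodes: pd.DataFrame,
    wear: pd.Series | Mapping[str, int],
    min_wear: int = MIN_WEAR_MINUTES,
    min_interaction: int = MIN_INTERACTION_MINUTES,
) -> set[str]:
    """Apply the data-sufficiency exclusion rule.

    A person is retained iff wear time is at least ``min_wear`` minutes
    (5 h) AND total interaction time is at least ``min_interaction``
    minutes (1 h); "less than" is strict, so the boundary values are kept.
    """
    wear = pd.Series(wear, dtype=float)
    inter = interaction_minutes(episodes)
    persons = wear.index.union(inter.index)
    wear = wear.reindex(persons, fill_value=0)
    inter = inter.reindex(persons, fill_value=0)
    keep = (wear >= min_wear) & (inter >= min_interaction)
    return set(persons[keep])


def _org_days(episodes: pd.DataFrame) -> pd.Series:
    day = episodes["start_minute"] // MINUTES_PER_DAY
    return episodes.assign(_day=day).groupby("org_id")["_day"].nunique()


def build_network(
    episodes: pd.DataFrame,
    nodes: Iterable[str],
    org: str,
    n_days: int,
    weight_by: str = "episodes",
) -> InteractionNetwork:
    """Build one organization's weighted interaction network.

    ``w_ij`` = (number of merged episodes of the dyad) / ``n_days``; with
    ``weight_by="minutes"`` the numerator is total interaction minutes
    instead (sensitivity analysis). Nodes are the retained persons of the
    organization; isolated persons are kept as degree-0 nodes.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if weight_by not in ("episodes", "minutes"):
        raise ValueError("weight_by must be 'episodes' or 'minutes'")
    nodes = list(nodes)
    node_set = set(nodes)
    g = nx.Graph(org=org)
    g.add_nodes_from(nodes)
    if len(episodes):
        if (episodes["org_id"] != org).any():
            raise DataError(f"episode from another organization passed to {org}")
        sub = episodes[
            episodes["person_u"].isin(node_set) & episodes["person_v"].isin(node_set)
        ]
        if weight_by == "episodes":
            w = sub.groupby(["person_u", "person_v"]).size()
        else:
            w = sub.groupby(["person_u", "person_v"])["duration"].sum()
        for (a, b), cnt in w.items():
            g.add_edge(a, b, weight=cnt / n_days)
    return InteractionNetwork(org=org, graph=g, n_days=n_days)


def build_networks(
    episodes: pd.DataFrame,
    roster: Roster,
    retained: set[str] | None = None,
    n_days: int | None = None,
    weight_by: str = "episodes",
) -> dict[str, InteractionNetwork]:
    """Build one network per organization from an episode table.

    ``n_days`` defaults, per organization, to the number of distinct
    calendar days with any detected episode.
    """
    org_of = roster.org_of
    if len(episodes):
        bad = episodes["org_id"] != episodes["person_u"].map(org_of)
        bad |= episodes["org_id"] != episodes["person_v"].map(org_of)
        if bad.any():
            raise DataError("cross-organization dyad in episode table")
    days = _org_days(episodes) if len(episodes) else pd.Series(dtype=int)
    nets = {}
    for org, sub in roster.table.groupby("org_id", sort=True):
        persons = sub["person_id"].tolist()
        if retained is not None:
            persons = [p for p in persons if p in retained]
        nd = n_days if n_days is not None else int(days.get(org, 1))
        org_eps = episodes[episodes["org_id"] == org] if len(episodes) else episodes
        nets[org] = build_network(org_eps, persons, org, max(nd, 1), weight_by)
    return nets


def classify_activity(episodes: pd.DataFrame, threshold: float) -> pd.Series:
    """Classify episodes as active / inactive / mixed by joint movement level.

    Both member means >= threshold -> "active"; both < threshold ->
    "inactive"; one of each -> "mixed"; any undefined mean ->
    "unclassifiable".
    """
    mu = episodes["movement_u"].to_numpy(dtype=float)
    mv = episodes["movement_v"].to_numpy(dtype=float)
    out = np.where(
        np.isnan(mu) | np.isnan(mv),
        "unclassifiable",
        np.where(
            (mu >= threshold) & (mv >= threshold),
            "active",
            np.where((mu < threshold) & (mv < threshold), "inactive", "mixed"),
        ),
    )
    return pd.Series(out, index=episodes.index, name="activity")


def subnetwork_by_activity(
    episodes: pd.DataFrame,
    threshold: float,
    mode: str,
) -> tuple[pd.DataFrame, float]:
    """Select the episode subset defining an activity sub-network.

    ``mode="active_net"`` removes the inactive episodes (mixed episodes are
    retained); ``mode="inactive_net"`` removes the active ones. Returns the
    retained episodes and the fraction of classifiable episodes removed.
    Unclassifiable episodes are dropped from both the subset and the
    denominator.
    """
    if mode not in ("active_net", "inactive_net"):
        raise ValueError("mode must be 'active_net' or 'inactive_net'")
    cls = classify_activity(episodes, threshold)
    classifiable = cls != "unclassifiable"
    removed_class = "inactive" if mode == "active_net" else "active"
    keep = classifiable & (cls != removed_class)
    n_class = int(classifiable.sum())
    removed_fraction = (
        float((cls == removed_class).sum()) / n_class if n_class else 0.0
    )
    return episodes[keep], removed_fraction


def score_cesd(
    items: Sequence[int] | pd.DataFrame,
    positive_items: Sequence[int] = POSITIVE_ITEMS_DEFAULT,
) -> int | pd.Series:
    """Score a CES-D response: sum of 16 negative items plus the four
    positive items reverse-keyed (3 - raw). Totals range 0-60.

    Accepts a single 20-vector or a frame with item_01..item_20 columns
    (vectorized; returns a Series in the latter case).
    """
    pos = set(positive_items)
    if len(pos) != 4 or not pos.issubset(range(1, 21)):
        raise ValueError("positive_items must be 4 distinct indices in 1..20")
    if isinstance(items, pd.DataFrame):
        cols = [f"item_{i:02d}" for i in range(1, 21)]
        arr = items[cols].to_numpy()
    else:
        arr = np.asarray(items).reshape(1, -1)
    if arr.shape[1] != 20:
        raise ValueError("a CES-D response has exactly 20 items")
    if ((arr < 0) | (arr > 3)).any():
        raise ValueError("CES-D item values must be in 0..3")
    scored = arr.copy().astype(int)
    for p in pos:
        scored[:, p - 1] = 3 - scored[:, p - 1]
    totals = scored.sum(axis=1)
    if isinstance(items, pd.DataFrame):
        return pd.Series(totals, index=items.index, name="cesd_total")
    return int(totals[0])
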