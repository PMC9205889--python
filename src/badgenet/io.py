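"""CSV / GraphML interchange.

All interchange is plain CSV with documented headers; networks can also be
exported as GraphML with org / community node attributes. Timestamps are
integer epoch-minutes and intervals are half-open everywhere.

Schemas
-------
detections.csv : org_id, person_id, counterpart_id, minute
movement.csv   : person_id, minute, zero_cross
cesd.csv       : person_id, item_01..item_20
episodes.csv   : org_id, person_u, person_v, start_minute, end_minute, duration
edges.csv      : org_id, person_u, person_v, weight   (person_u < person_v)
features.csv   : person_id, org_id, the 11 canonical feature columns, cesd_total
partition.csv  : person_id, community
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .preprocess import DataError, EPISODE_COLUMNS, InteractionNetwork

__all__ = [
    "read_detections",
    "read_movement",
    "read_cesd",
    "read_episodes",
    "write_edges_csv",
    "write_network_graphml",
    "write_partition_csv",
]

_DETECTION_COLS = ["org_id", "person_id", "counterpart_id", "minute"]
_MOVEMENT_COLS = ["person_id", "minute", "zero_cross"]
_ITEM_COLS = [f"item_{i:02d}" for i in range(1, 21)]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")


def _line(df_index: int) -> int:
    # +2: one for the header row, one for 1-based numbering
    return df_index + 2


def read_detections(path) -> pd.DataFrame:
    """Read and validate a per-minute detection stream."""
    df = pd.read_csv(path)
    _check_columns(df, _DETECTION_COLS, path)
    bad = df.index[df["person_id"] == df["counterpart_id"]]
    if len(bad):
        raise DataError(f"{path}: self-detection at line {_line(bad[0])}")
    if df["minute"].isna().any() or (df["minute"] % 1 != 0).any():
        bad = df.index[df["minute"].isna() | (df["minute"] % 1 != 0)][0]
        raise DataError(f"{path}: non-integer minute at line {_line(bad)}")
    df["minute"] = df["minute"].astype(int)
    return df[_DETECTION_COLS]


def read_movement(path) -> pd.DataFrame:
    """Read and validate a per-minute body-movement stream."""
    df = pd.read_csv(path)
    _check_columns(df, _MOVEMENT_COLS, path)
    if (df["zero_cross"] < 0).any():
        bad = df.index[df["zero_cross"] < 0][0]
        raise DataError(f"{path}: negative zero_cross at line {_line(bad)}")
    df["minute"] = df["minute"].astype(int)
    df["zero_cross"] = df["zero_cross"].astype(int)
    return df[_MOVEMENT_COLS]


def read_cesd(path) -> pd.DataFrame:
    """Read and validate CES-D responses (20 items, each 0-3)."""
    df = pd.read_csv(path)
    _check_columns(df, ["person_id", *_ITEM_COLS], path)
    items = df[_ITEM_COLS]
    bad_mask = items.isna() | (items < 0) | (items > 3)
    if bad_mask.any().any():
        bad = df.index[bad_mask.any(axis=1)][0]
        raise DataError(f"{path}: CES-D item outside 0..3 at line {_line(bad)}")
    for c in _ITEM_COLS:
        df[c] = df[c].astype(int)
    return df


def read_episodes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, EPISODE_COLUMNS, path)
    return df[list(df.columns)]


def write_edges_csv(net: InteractionNetwork, path) -> None:
    """Write a weighted edge list, canonically sorted (min id first)."""
    rows = []
    for u, v, d in net.graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append((net.org, a, b, repr(float(d.get("weight", 1.0)))))
    rows.sort()
    df = pd.DataFrame(rows, columns=["org_id", "person_u", "person_v", "weight"])
    df.to_csv(path, index=False)


def write_network_graphml(
    net: InteractionNetwork, path, community_of: Mapping | None = None
) -> None:
    """Export as GraphML; node attributes carry org and (optionally) community."""
    g = net.graph.copy()
    for n in g.nodes:
        g.nodes[n]["org"] = net.org
        if community_of is not None and n in community_of:
            g.nodes[n]["community"] = int(community_of[n])
    nx.write_graphml(g, Path(path))


def write_partition_csv(community_of: Mapping, path) -> None:
    df = pd.DataFrame(
        sorted(community_of.items()), columns=["person_id", "community"]
    )
    df.to_csv(path, index=False)
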