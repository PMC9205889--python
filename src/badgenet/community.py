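"""Weighted modularity and Louvain community detection.

Modularity of a partition {c_i} of a weighted undirected graph:

    Q = (1/2W) * sum_{i,j} (w_ij - s_i s_j / 2W) * delta(c_i, c_j)

with the sum over ordered node pairs, s_i the node strength and
W the total edge weight. Louvain maximizes Q greedily in two phases
(local node moves, then community aggregation) iterated to convergence;
because results depend on the node-visit order, detection is run as a
randomized-order ensemble.

For detection (only), edge weights are first raised to a sub-linear power
(default exponent 1/4) to damp the heavy tail of interaction frequencies;
all member-level metrics keep the original weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import InteractionNetwork

__all__ = [
    "Partition",
    "modularity",
    "louvain",
    "transform_weights",
    "detect_ensemble",
    "COMMUNITY_EXPONENT_DEFAULT",
    "ENSEMBLE_RUNS_DEFAULT",
]

#: Weight exponent applied before detection.
COMMUNITY_EXPONENT_DEFAULT = 0.25
#: Size of the randomized-order detection ensemble.
ENSEMBLE_RUNS_DEFAULT = 5000


@dataclass(frozen=True)
class Partition:
    """A node -> community assignment together with its modularity."""

    community_of: dict
    q: float

    def communities(self) -> dict:
        out: dict = {}
        for n, c in self.community_of.items():
            out.setdefault(c, set()).add(n)
        return out

    def sizes(self) -> list[int]:
        return sorted(len(m) for m in self.communities().values())


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, InteractionNetwork) else net


def modularity(net, community_of: Mapping) -> float:
    """Evaluate Q exactly on the given partition.

    Ordered-pair form; self-pairs contribute only through the null term
    (w_ii = 0 on observation graphs). Raises if the graph has no edge
    weight (W = 0) or the partition misses a node.
    """
    g = _as_graph(net)
    missing = [n for n in g.nodes if n not in community_of]
    if missing:
        raise ValueError(f"partition does not cover node {missing[0]!r}")
    w2 = 2.0 * sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True))
    if w2 <= 0:
        raise ValueError("modularity undefined on a graph with zero total weight")
    within = 0.0
    for u, v, d in g.edges(data=True):
        if u != v and community_of[u] == community_of[v]:
            within += 2.0 * d.get("weight", 1.0)  # ordered pairs
    strength: dict = {}
    for n in g.nodes:
        strength[n] = sum(d.get("weight", 1.0) for d in g[n].values())
    s_by_comm: dict = {}
    for n, c in community_of.items():
        if n in strength:
            s_by_comm[c] = s_by_comm.get(c, 0.0) + strength[n]
    q = within / w2 - sum((s / w2) ** 2 for s in s_by_comm.values())
    return float(q)


def transform_weights(net, exponent: float = COMMUNITY_EXPONENT_DEFAULT):
    """Return a copy with each w_ij replaced by w_ij ** exponent.

    The map is monotone, so edge-weight rankings are preserved. Used only
    as a preconditioner for community detection; metrics always see the
    original weights.
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    g = _as_graph(net)
    h = g.copy()
    for _, _, d in h.edges(data=True):
        d["weight"] = float(d.get("weight", 1.0)) ** exponent
    if isinstance(net, InteractionNetwork):
        return InteractionNetwork(org=net.org, graph=h, n_days=net.n_days)
    return h


# ---------------------------------------------------------------------------
# Louvain


def _one_level(adj, self_w, strength, w2, rng):
    """Greedy local moves on one aggregation level.

    adj: list of dicts neighbour->ordered weight (no self entries);
    self_w: per-node internal (self-loop) ordered weight; strength
    includes self-loop weight. Returns (community array, improved flag).

    Move rule: relocate a node to the neighbouring community with maximal
    positive modularity gain; ties broken by lowest community id; no move
    on non-positive gain.
    """
    n = len(adj)
    comm = np.arange(n)
    comm_strength = strength.copy()
    improved = False
    while True:
        moved_any = False
        for i in rng.permutation(n):
            ci = comm[i]
            # ordered weight from i to each neighbouring community
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            comm_strength[ci] -= strength[i]
            stay_gain = links.get(ci, 0.0) - comm_strength[ci] * strength[i] / w2
            best_c, best_gain = ci, stay_gain
            for c in sorted(links):  # ascending id => ties keep the lowest id
                gain = links[c] - comm_strength[c] * strength[i] / w2
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            if best_c != ci and best_gain > stay_gain + 1e-12:
                comm[i] = best_c
                comm_strength[best_c] += strength[i]
                moved_any = True
                improved = True
            else:
                comm_strength[ci] += strength[i]
        if not moved_any:
            break
    return comm, improved


def louvain(net, seed: int = 0) -> Partition:
    """Louvain two-phase modularity maximization.

    Node-visit order is shuffled by ``seed``; the returned Q is recomputed
    exactly from the final partition with :func:`modularity`.
    """
    g = _as_graph(net)
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}

    adj: list[dict[int, float]] = [dict() for _ in nodes]
    self_w = np.zeros(len(nodes))
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        if u == v:
            self_w[index[u]] += 2.0 * w
        else:
            adj[index[u]][index[v]] = adj[index[u]].get(index[v], 0.0) + w
            adj[index[v]][index[u]] = adj[index[v]].get(index[u], 0.0) + w
    strength = self_w + np.array([sum(a.values()) for a in adj])
    w2 = strength.sum()
    if w2 <= 0:
        raise ValueError("louvain requires positive total edge weight")

    assignment = np.arange(len(nodes))  # original node -> current meta-node
    while True:
        comm, improved = _one_level(adj, self_w, strength, w2, rng)
        if not improved:
            break
        # relabel communities 0..K-1 in ascending id order (deterministic)
        uniq = np.unique(comm)
        relabel = {c: i for i, c in enumerate(uniq)}
        comm = np.array([relabel[c] for c in comm])
        assignment = comm[assignment]
        # aggregate
        k = len(uniq)
        new_adj: list[dict[int, float]] = [dict() for _ in range(k)]
        new_self = np.zeros(k)
        for i, neigh in enumerate(adj):
            ci = comm[i]
            new_self[ci] += self_w[i]
            for j, w in neigh.items():
                cj = comm[j]
                if ci == cj:
                    new_self[ci] += w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
        adj, self_w = new_adj, new_self
        strength = self_w + np.array([sum(a.values()) for a in adj])
        if k == 1:
            break

    community_of = {n: int(assignment[index[n]]) for n in nodes}
    # canonical labels in node order
    relabel: dict[int, int] = {}
    for n in nodes:
        c = community_of[n]
        if c not in relabel:
            relabel[c] = len(relabel)
    community_of = {n: relabel[c] for n, c in community_of.items()}
    return Partition(community_of=community_of, q=modularity(g, community_of))


def detect_ensemble(
    net,
    n_runs: int = ENSEMBLE_RUNS_DEFAULT,
    seed: int = 0,
) -> tuple[list[Partition], pd.DataFrame]:
    """Randomized-order Louvain ensemble.

    Runs ``n_runs`` independent detections with distinct visit orders and
    summarizes each run's community count, mean community size and Q.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    partitions = [louvain(net, seed=int(s)) for s in child_seeds]
    summary = pd.DataFrame(
        {
            "run": np.arange(n_runs),
            "n_communities": [len(p.communities()) for p in partitions],
            "mean_size": [float(np.mean(p.sizes())) for p in partitions],
            "q": [p.q for p in partitions],
        }
    )
    return partitions, summary
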