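"""The 11 social-network characteristics.

Individual scale: Degree (number of interaction partners) and Weight
(total interactions per day, s_i = sum_j w_ij). Surrounding scale: the
unweighted clustering coefficient and its Barrat, Onnela and Zhang weighted
variants — deliberately computed on *unnormalized* daily interaction
frequencies so values are comparable across organizations. Organizational
scale: closeness, betweenness (unweighted and weighted) and eigenvector
centrality (unweighted and weighted).

Conventions
-----------
* All weighted clustering sums run over ordered neighbour pairs (j, k).
* <w_i> in the Barrat coefficient is the node's mean edge weight s_i/k_i.
* Nodes with degree < 2 get clustering 0 (configurable exclusion happens
  at the analysis layer, not here).
* Weighted shortest-path distance is 1/w_ij: a stronger tie is a shorter
  distance. Configurable via ``distance``.
* Closeness/betweenness on disconnected graphs are computed per connected
  component with component-local n; eigenvector centrality is the
  principal eigenvector of each component, non-negative with unit
  Euclidean norm per component. Components without edges get 0.
"""

from __future__ import annotations

from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import DataError, InteractionNetwork

__all__ = [
    "FEATURE_COLUMNS",
    "degree_strength",
    "clustering_unweighted",
    "clustering_barrat",
    "clustering_onnela",
    "clustering_zhang",
    "closeness",
    "betweenness",
    "eigenvector",
    "node_metrics",
    "feature_table",
]

#: Canonical feature-column names, in presentation order.
FEATURE_COLUMNS = [
    "Degree",
    "Weight",
    "Clustering",
    "Clustering w(B)",
    "Clustering w(O)",
    "Clustering w(Z)",
    "Closeness",
    "Betweenness",
    "Betweenness w",
    "Eigenvector",
    "Eigenvector w",
]


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, InteractionNetwork) else net


def _matrices(g: nx.Graph):
    nodes = list(g.nodes)
    w = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    np.fill_diagonal(w, 0.0)
    a = (w > 0).astype(float)
    return nodes, w, a


def degree_strength(net) -> tuple[dict, dict]:
    """(k_i, s_i): neighbour count and summed edge weight per node."""
    g = _as_graph(net)
    k = {n: g.degree(n) for n in g.nodes}
    s = {n: float(sum(d.get("weight", 1.0) for d in g[n].values())) for n in g.nodes}
    return k, s


def clustering_unweighted(net) -> dict:
    """C_i = 2 T_i / (k_i (k_i - 1)); 0 for degree < 2."""
    g = _as_graph(net)
    nodes, w, a = _matrices(g)
    k = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # 2*T_i as ordered pairs
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return dict(zip(nodes, c))


def clustering_barrat(net) -> dict:
    """Barrat weighted clustering.

    (1/(k_i(k_i-1))) * sum_{j,k} (1/<w_i>) ((w_ij + w_ik)/2) a_ij a_jk a_ik
    with <w_i> = s_i / k_i; the ordered-pair numerator equals (W A A)_ii
    by symmetry. Scale-invariant in the weights.
    """
    g = _as_graph(net)
    nodes, w, a = _matrices(g)
    k = a.sum(axis=1)
    s = w.sum(axis=1)
    num = np.einsum("ij,jk,ki->i", w, a, a)
    # <w_i> k_i (k_i-1) = s_i (k_i - 1)
    denom = s * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where((k > 1) & (denom > 0), num / denom, 0.0)
    return dict(zip(nodes, c))


def clustering_onnela(net) -> dict:
    """Onnela weighted clustering on unnormalized weights.

    (1/(k_i(k_i-1))) * sum_{j,k} (w_ij w_jk w_ik)^(1/3); positively
    homogeneous of degree 1 in the weights (no max-weight normalization).
    """
    g = _as_graph(net)
    nodes, w, a = _matrices(g)
    k = a.sum(axis=1)
    w3 = np.cbrt(w)
    num = np.einsum("ij,jk,ki->i", w3, w3, w3)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, num / denom, 0.0)
    return dict(zip(nodes, c))


def clustering_zhang(net) -> dict:
    """Zhang weighted clustering on unnormalized weights.

    sum_{j,k} w_ij w_jk w_ik / sum_{j != k} w_ij w_ik — a w_ij w_ik
    weighted mean of the indirect frequency w_jk; 0 when the denominator
    vanishes.
    """
    g = _as_graph(net)
    nodes, w, a = _matrices(g)
    num = np.einsum("ij,jk,ki->i", w, w, w)
    s = w.sum(axis=1)
    denom = s**2 - (w**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, num / denom, 0.0)
    return dict(zip(nodes, c))


def closeness(net) -> dict:
    """Closeness_i = (n - 1) / sum_j d(j, i) over unweighted shortest paths.

    Computed within each connected component with n the component size;
    isolated nodes get 0.
    """
    g = _as_graph(net)
    return {n: float(v) for n, v in nx.closeness_centrality(g, wf_improved=False).items()}


def _weighted_with_distance(g: nx.Graph, distance: Callable[[float], float]):
    h = g.copy()
    for u, v, d in h.edges(data=True):
        d["distance"] = distance(d.get("weight", 1.0))
    return h


def betweenness(net, weighted: bool = False, distance=None) -> dict:
    """Normalized betweenness centrality, per connected component.

    Betweenness_i = (2/((n-1)(n-2))) sum_{j<k} sigma_jk(i)/sigma_jk with n
    the component size; endpoints excluded. In weighted mode shortest
    paths use Dijkstra on distance = 1/w_ij (configurable).
    """
    g = _as_graph(net)
    if weighted:
        g = _weighted_with_distance(g, distance or (lambda w: 1.0 / w))
        kw = {"weight": "distance"}
    else:
        kw = {"weight": None}
    out = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        vals = nx.betweenness_centrality(sub, normalized=True, **kw)
        out.update({n: float(v) for n, v in vals.items()})
    return out


def eigenvector(net, weighted: bool = False, tol: float = 1e-14,
                max_iter: int = 100_000) -> dict:
    """Principal-eigenvector centrality, unit Euclidean norm per component.

    Solved by shifted power iteration (shift ensures convergence on
    bipartite components); components with no edges get 0.
    """
    g = _as_graph(net)
    nodes, w, a = _matrices(g)
    mat_full = w if weighted else a
    out = {n: 0.0 for n in nodes}
    index = {n: i for i, n in enumerate(nodes)}
    for comp in nx.connected_components(g):
        comp = list(comp)
        if len(comp) < 2:
            continue
        idx = np.array([index[n] for n in comp])
        m = mat_full[np.ix_(idx, idx)]
        shift = m.sum(axis=1).max() + 1.0
        mm = m + shift * np.eye(len(comp))
        v = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
        for _ in range(max_iter):
            nv = mm @ v
            nv /= np.linalg.norm(nv)
            if np.linalg.norm(nv - v) < tol:
                v = nv
                break
            v = nv
        else:  # pragma: no cover
            raise ArithmeticError("eigenvector iteration failed to converge")
        v = np.abs(v)
        v /= np.linalg.norm(v)
        for n, val in zip(comp, v):
            out[n] = float(val)
    return out


def node_metrics(net, distance=None) -> pd.DataFrame:
    """All 11 characteristics for one organization's network."""
    g = _as_graph(net)
    k, s = degree_strength(g)
    cols = {
        "Degree": k,
        "Weight": s,
        "Clustering": clustering_unweighted(g),
        "Clustering w(B)": clustering_barrat(g),
        "Clustering w(O)": clustering_onnela(g),
        "Clustering w(Z)": clustering_zhang(g),
        "Closeness": closeness(g),
        "Betweenness": betweenness(g, weighted=False),
        "Betweenness w": betweenness(g, weighted=True, distance=distance),
        "Eigenvector": eigenvector(g, weighted=False),
        "Eigenvector w": eigenvector(g, weighted=True),
    }
    df = pd.DataFrame({name: pd.Series(vals) for name, vals in cols.items()})
    df = df.loc[list(g.nodes)]
    df.index.name = "person_id"
    return df.reset_index()


def feature_table(
    networks: Mapping[str, InteractionNetwork] | InteractionNetwork,
    cesd: pd.DataFrame | None = None,
    distance=None,
) -> pd.DataFrame:
    """Join the 11 metrics with organization labels and CES-D totals.

    ``cesd`` is a frame with person_id and cesd_total (persons lacking a
    response get NaN and are flagged for the correlation layer). Raises on
    duplicate person ids across networks.
    """
    if isinstance(networks, InteractionNetwork):
        networks = {networks.org: networks}
    frames = []
    for org in sorted(networks):
        df = node_metrics(networks[org], distance=distance)
        df.insert(1, "org_id", org)
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["person_id", "org_id", *FEATURE_COLUMNS])
    if out["person_id"].duplicated().any():
        dup = out["person_id"][out["person_id"].duplicated()].iloc[0]
        raise DataError(f"duplicate person id across networks: {dup}")
    if cesd is not None and len(out):
        totals = cesd.set_index("person_id")["cesd_total"]
        out["cesd_total"] = out["person_id"].map(totals)
    elif cesd is not None:
        out["cesd_total"] = pd.Series(dtype=float)
    return out
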