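"""Independent brute-force oracles for the network metrics.

Everything here is written from the defining formulas with explicit loops
(triangle enumeration, Floyd-Warshall shortest paths with path counting,
dense eigensolver) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

INF = float("inf")
TOL = 1e-9


def random_weighted_graph(rng, n, p=0.4, binary=False):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = 1.0 if binary else float(rng.uniform(0.5, 3.0))
                g.add_edge(i, j, weight=w)
    return g


def _w(g):
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for u, v, d in g.edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = d.get("weight", 1.0)
    return nodes, w


def clustering_oracle(g, variant):
    """Triple-loop evaluation of the four clustering definitions."""
    nodes, w = _w(g)
    a = (w > 0).astype(float)
    n = len(nodes)
    out = {}
    for i in range(n):
        k = a[i].sum()
        num = 0.0
        zden = 0.0
        for j in range(n):
            for l in range(n):
                if j == l or j == i or l == i:
                    continue
                if variant == "unweighted":
                    num += a[i, j] * a[j, l] * a[l, i]
                elif variant == "barrat":
                    num += ((w[i, j] + w[i, l]) / 2.0) * a[i, j] * a[j, l] * a[l, i]
                elif variant == "onnela":
                    num += (w[i, j] * w[j, l] * w[l, i]) ** (1.0 / 3.0)
                elif variant == "zhang":
                    num += w[i, j] * w[j, l] * w[l, i]
                    zden += w[i, j] * w[i, l]
        if variant == "unweighted":
            out[nodes[i]] = num / (k * (k - 1)) if k > 1 else 0.0
        elif variant == "barrat":
            s = w[i].sum()
            mean_w = s / k if k > 0 else 0.0
            denom = mean_w * k * (k - 1)
            out[nodes[i]] = num / denom if k > 1 and denom > 0 else 0.0
        elif variant == "onnela":
            out[nodes[i]] = num / (k * (k - 1)) if k > 1 else 0.0
        else:
            out[nodes[i]] = num / zden if zden > 0 else 0.0
    return out


def _floyd_warshall(w, weighted):
    n = len(w)
    dist = np.full((n, n), INF)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                dist[i, j] = 1.0 / w[i, j] if weighted else 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def closeness_oracle(g):
    """(n_c - 1) / sum of unweighted shortest distances, per component."""
    nodes, w = _w(g)
    dist = _floyd_warshall(w, weighted=False)
    out = {}
    for i, node in enumerate(nodes):
        reach = [j for j in range(len(nodes)) if j != i and dist[i, j] < INF]
        if not reach:
            out[node] = 0.0
        else:
            out[node] = len(reach) / sum(dist[i, j] for j in reach)
    return out


def _path_counts(w, dist, weighted):
    """sigma[j, k]: number of shortest paths, by DP over the distance matrix."""
    n = len(w)
    sigma = np.zeros((n, n))
    order = []
    for j in range(n):
        ks = [k for k in range(n) if dist[j, k] < INF]
        for k in sorted(ks, key=lambda k: dist[j, k]):
            if k == j:
                sigma[j, j] = 1.0
                continue
            total = 0.0
            for m in range(n):
                if w[m, k] > 0:
                    step = 1.0 / w[m, k] if weighted else 1.0
                    if abs(dist[j, m] + step - dist[j, k]) < TOL:
                        total += sigma[j, m]
            sigma[j, k] = total
    return sigma


def betweenness_oracle(g, weighted=False):
    """Pair-summation betweenness from the normalized defining formula."""
    nodes, w = _w(g)
    n = len(nodes)
    dist = _floyd_warshall(w, weighted)
    sigma = _path_counts(w, dist, weighted)
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of[node] = ci
    comp_sizes = {}
    for node, ci in comp_of.items():
        comp_sizes[ci] = comp_sizes.get(ci, 0) + 1
    out = {}
    for i, node in enumerate(nodes):
        nc = comp_sizes[comp_of[node]]
        if nc < 3:
            out[node] = 0.0
            continue
        acc = 0.0
        for j in range(n):
            for k in range(j + 1, n):
                if j == i or k == i or sigma[j, k] == 0:
                    continue
                if comp_of[nodes[j]] != comp_of[node] or comp_of[nodes[k]] != comp_of[node]:
                    continue
                if abs(dist[j, i] + dist[i, k] - dist[j, k]) < TOL:
                    acc += sigma[j, i] * sigma[i, k] / sigma[j, k]
        out[node] = 2.0 * acc / ((nc - 1) * (nc - 2))
    return out


def eigenvector_oracle(g, weighted=False):
    """Dense-eigensolver principal vector, unit norm per component."""
    nodes, w = _w(g)
    mat = w if weighted else (w > 0).astype(float)
    idx = {n: i for i, n in enumerate(nodes)}
    out = {n: 0.0 for n in nodes}
    for comp in nx.connected_components(g):
        comp = list(comp)
        if len(comp) < 2:
            continue
        sel = np.array([idx[n] for n in comp])
        m = mat[np.ix_(sel, sel)]
        vals, vecs = np.linalg.eigh(m)
        v = vecs[:, np.argmax(vals)]
        v = np.abs(v)
        v /= np.linalg.norm(v)
        for node, val in zip(comp, v):
            out[node] = float(val)
    return out


def modularity_oracle(g, community_of):
    """Direct ordered-pair evaluation of the weighted modularity formula."""
    nodes, w = _w(g)
    w2 = w.sum()
    q = 0.0
    s = w.sum(axis=1)
    for i, ni in enumerate(nodes):
        for j, nj in enumerate(nodes):
            if community_of[ni] == community_of[nj]:
                q += w[i, j] - s[i] * s[j] / w2
    return q / w2


def all_partitions(items):
    """Every set partition (Bell-number enumeration) of a small list."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part
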