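"""Independent brute-force oracles used to validate the graph statistics.

These deliberately avoid the package's own code paths: shortest paths come
from exhaustive Floyd-Warshall relaxation, clustering from triple
enumeration, modularity from the direct double sum, eigenvector centrality
from a dense eigensolver, and betweenness from networkx's reference
implementation.
"""

import numpy as np


def brute_distances(lengths):
    """All-pairs shortest paths by exhaustive relaxation (Floyd-Warshall)."""
    n = lengths.shape[0]
    d = np.where(lengths > 0, lengths, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def lengths_of(w, variant):
    if variant == "binary":
        return (w > 0).astype(float)
    return np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)


def brute_efficiency(lengths):
    d = brute_distances(lengths)
    n = d.shape[0]
    if n < 2:
        return 0.0
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return inv.sum() / (n * (n - 1))


def brute_local_efficiency(w, variant):
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if len(nbrs) < 2:
            continue
        out[i] = brute_efficiency(lengths_of(w[np.ix_(nbrs, nbrs)], variant))
    return out


def brute_clustering(w, weighted=False):
    n = w.shape[0]
    adj = w > 0
    wmax = w.max() if w.max() > 0 else 1.0
    out = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k < 2:
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h and adj[i, j] and adj[i, h] and adj[j, h]:
                    if weighted:
                        tri += ((w[i, j] / wmax) * (w[i, h] / wmax) * (w[j, h] / wmax)) ** (1.0 / 3.0)
                    else:
                        tri += 1.0
        out[i] = tri / (k * (k - 1))
    return out


def brute_modularity(w, assignment):
    s = w.sum(1)
    two_m = s.sum()
    total = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j]:
                total += w[i, j] - s[i] * s[j] / two_m
    return total / two_m


def brute_eigenvector(w):
    """Principal eigenvector on the largest component via dense eigh."""
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csgraph

    n = w.shape[0]
    _nc, labels = csgraph.connected_components(sp.csr_matrix(w > 0), directed=False)
    keep = np.argmax(np.bincount(labels))
    members = np.flatnonzero(labels == keep)
    out = np.zeros(n)
    if len(members) == 1:
        out[members] = 1.0
        return out
    sub = w[np.ix_(members, members)]
    _vals, vecs = np.linalg.eigh(sub)
    v = np.abs(vecs[:, -1])
    out[members] = v / v.max()
    return out


def nx_betweenness(w, variant):
    """Reference betweenness from networkx (unnormalized, undirected)."""
    import networkx as nx

    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                length = 1.0 if variant == "binary" else 1.0 / w[i, j]
                g.add_edge(i, j, length=length)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(n)])
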