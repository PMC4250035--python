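"""Nodal and global network statistics, and spectral modular decomposition.

The metrics are the standard weighted/binary graph-theoretic measures used
to characterize brain networks:

* **strength** — weighted degree, ``s_i = sum_j W_ij``;
* **clustering coefficient** — Watts–Strogatz triangle density for binary
  graphs; the Onnela geometric-mean generalization for weighted graphs;
* **global / local efficiency** — Latora–Marchiori efficiency, the mean
  inverse shortest-path length; weighted paths use edge lengths ``1/w``;
* **betweenness centrality** — Brandes pair-dependency accumulation,
  unnormalized, endpoints excluded;
* **eigenvector centrality** — principal eigenvector of the weight matrix
  by power iteration;
* **modularity Q** — Newman–Girvan quality of a partition, and community
  detection by recursive leading-eigenvector bisection of the modularity
  matrix with a Kernighan–Lin-style single-node fine-tuning pass after each
  split.

Weighted variants reduce exactly to their binary counterparts when every
edge weight is 1.  Negative weights are rejected by the path-based and
modularity operations: signed-network statistics are not defined here, so
threshold or take absolute values first.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from .core import (
    AdjacencyNetwork,
    ComputationError,
    NodeScalar,
    Ordering,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModulePartition",
    "StatsReport",
    "strength",
    "clustering_coefficient",
    "global_efficiency",
    "local_efficiency",
    "betweenness_centrality",
    "eigenvector_centrality",
    "modularity_Q",
    "detect_modules",
    "compute_all",
]

_FINE_TUNE_TOL = 1e-12   # minimum Q gain for a single-node move
_SPLIT_TOL = 1e-10       # minimum Q contribution to accept a bisection
_POWER_TOL = 1e-10


@dataclass(frozen=True)
class ModulePartition:
    """Node-to-module assignment together with its modularity Q."""

    assignment: np.ndarray
    Q: float

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.int64).ravel()
        if a.size == 0:
            raise ValidationError("empty module assignment")
        ids = np.unique(a)
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValidationError(
                f"module ids must be contiguous 0..M-1, got {ids.tolist()}"
            )
        if not -1.0 - 1e-9 <= self.Q <= 1.0 + 1e-9:
            raise ValidationError(f"modularity Q={self.Q} outside [-1, 1]")
        a = a.copy()
        a.flags.writeable = False
        object.__setattr__(self, "assignment", a)

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module)


def _weights(network: AdjacencyNetwork, require_nonnegative: bool = False) -> np.ndarray:
    w = network.weights
    if require_nonnegative and (w < 0).any():
        raise ComputationError(
            "negative edge weights are not supported by this statistic; "
            "threshold the network or take absolute values first"
        )
    return w


def _relabel(assignment: np.ndarray) -> np.ndarray:
    """Compact module labels to 0..M-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(assignment), dtype=np.int64)
    for i, a in enumerate(assignment):
        out[i] = mapping.setdefault(int(a), len(mapping))
    return out


# ---------------------------------------------------------------------------
# Nodal metrics
# ---------------------------------------------------------------------------


def strength(network: AdjacencyNetwork) -> NodeScalar:
    """Weighted degree: row sum of the weight matrix (diagonal excluded)."""
    return NodeScalar(network.weights.sum(axis=1), "strength")


def clustering_coefficient(
    network: AdjacencyNetwork, variant: str = "binary"
) -> NodeScalar:
    """Per-node clustering coefficient.

    Binary: ``C_i = 2 t_i / (k_i (k_i - 1))`` with ``t_i`` the number of
    triangles through *i* in the graph binarized at weight > 0.  Weighted
    (Onnela): triangle counts are replaced by geometric means of the three
    edge weights normalized by the maximum weight.  Nodes of degree < 2
    get 0.
    """
    w = _weights(network, require_nonnegative=True)
    adj = (w > 0).astype(float)
    k = adj.sum(axis=1)
    if variant == "binary":
        triangles = np.diag(adj @ adj @ adj) / 2.0
    elif variant == "weighted":
        wmax = w.max()
        cube = np.cbrt(w / wmax) if wmax > 0 else w
        triangles = np.diag(cube @ cube @ cube) / 2.0
    else:
        raise ValidationError(f"unknown clustering variant {variant!r}")
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return NodeScalar(c, f"clustering_{variant}")


def _distance_matrix(network: AdjacencyNetwork, variant: str) -> np.ndarray:
    """All-pairs shortest-path distances; weighted edges have length 1/w."""
    w = _weights(network, require_nonnegative=True)
    if variant == "binary":
        graph = sp.csr_matrix((w > 0).astype(float))
        return csgraph.shortest_path(graph, method="D", unweighted=True)
    if variant == "weighted":
        with np.errstate(divide="ignore"):
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
        return csgraph.shortest_path(sp.csr_matrix(lengths), method="D")
    raise ValidationError(f"unknown efficiency variant {variant!r}")


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(network: AdjacencyNetwork, variant: str = "binary") -> float:
    """Mean inverse shortest-path length over all node pairs (1/inf = 0)."""
    return _efficiency_from_distances(_distance_matrix(network, variant))


def local_efficiency(network: AdjacencyNetwork, variant: str = "binary") -> NodeScalar:
    """Global efficiency of each node's neighborhood subgraph.

    The subgraph is induced on the neighbors of *i* (the node itself
    excluded); nodes with fewer than two neighbors get 0.
    """
    w = _weights(network, require_nonnegative=True)
    n = w.shape[0]
    values = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if len(nbrs) < 2:
            continue
        sub = AdjacencyNetwork(
            w[np.ix_(nbrs, nbrs)],
            Ordering(tuple(network.ordering.names[j] for j in nbrs)),
        )
        values[i] = global_efficiency(sub, variant)
    return NodeScalar(values, f"local_efficiency_{variant}")


def betweenness_centrality(
    network: AdjacencyNetwork, variant: str = "binary"
) -> NodeScalar:
    """Unnormalized shortest-path betweenness (Brandes accumulation).

    Each unordered pair of distinct endpoints contributes its shortest-path
    dependency once; endpoints themselves are excluded.  Weighted paths use
    edge lengths ``1/w``.
    """
    w = _weights(network, require_nonnegative=True)
    n = w.shape[0]
    if variant == "binary":
        lengths = (w > 0).astype(float)
    elif variant == "weighted":
        with np.errstate(divide="ignore"):
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    else:
        raise ValidationError(f"unknown betweenness variant {variant!r}")
    nbrs = [np.flatnonzero(lengths[i] > 0) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source Dijkstra with path counting
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        visited = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d, u = heapq.heappop(heap)
            if visited[u]:
                continue
            visited[u] = True
            order.append(u)
            for v in nbrs[u]:
                alt = d + lengths[u, v]
                if alt < dist[v] - 1e-14:
                    dist[v] = alt
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (alt, v))
                elif abs(alt - dist[v]) <= 1e-14 and not visited[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for u in reversed(order):
            for p in preds[u]:
                delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
            if u != s:
                bc[u] += delta[u]
    # undirected: each pair was accumulated from both endpoints
    return NodeScalar(bc / 2.0, f"betweenness_{variant}")


def eigenvector_centrality(network: AdjacencyNetwork) -> NodeScalar:
    """Principal eigenvector of W, normalized to unit maximum.

    Computed by power iteration (tolerance 1e-10) on the largest connected
    component; nodes outside it get 0, with a warning.
    """
    w = _weights(network, require_nonnegative=True)
    n = w.shape[0]
    n_comp, labels = csgraph.connected_components(sp.csr_matrix(w > 0), directed=False)
    values = np.zeros(n)
    sizes = np.bincount(labels)
    keep = int(np.argmax(sizes))
    if n_comp > 1:
        logger.warning(
            "network has %d connected components; eigenvector centrality is "
            "computed on the largest (%d nodes), zeros elsewhere",
            n_comp, sizes[keep],
        )
    members = np.flatnonzero(labels == keep)
    if len(members) == 1:
        values[members] = 1.0
        return NodeScalar(values, "eigenvector")
    sub = w[np.ix_(members, members)]
    # diagonal shift makes the principal eigenvalue strictly dominant
    # (bipartite spectra are symmetric about 0); eigenvectors are unchanged
    shift = sub.sum(axis=1).max()
    x = np.ones(len(members)) / np.sqrt(len(members))
    for _ in range(100000):
        y = sub @ x + shift * x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.abs(y - x).max() < _POWER_TOL:
            x = y
            break
        x = y
    values[members] = x / x.max()
    return NodeScalar(values, "eigenvector")


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------


def modularity_Q(network: AdjacencyNetwork, partition: ModulePartition | np.ndarray) -> float:
    """Newman–Girvan modularity of a partition.

    ``Q = (1/2m) * sum_ij (W_ij - s_i s_j / 2m) delta(c_i, c_j)`` where
    ``s`` is node strength and ``2m`` the total weight.  Zero-weight
    networks have no null model and are rejected.
    """
    w = _weights(network, require_nonnegative=True)
    assignment = partition.assignment if isinstance(partition, ModulePartition) else (
        np.asarray(partition, dtype=np.int64).ravel()
    )
    if len(assignment) != network.n_nodes:
        raise ValidationError(
            f"partition covers {len(assignment)} nodes, network has {network.n_nodes}"
        )
    s = w.sum(axis=1)
    two_m = s.sum()
    if two_m <= 0:
        raise ComputationError("modularity is undefined for a zero-weight network")
    same = assignment[:, None] == assignment[None, :]
    b = w - np.outer(s, s) / two_m
    return float((b * same).sum() / two_m)


def _fine_tune(bg: np.ndarray, sides: np.ndarray) -> np.ndarray:
    """Greedy single-node refinement of a bisection sign vector.

    Repeatedly flips the node whose move most increases ``s^T B s`` until no
    flip gains more than the tolerance.  Scan order is ascending index, so
    the result is deterministic.
    """
    s = sides.copy()
    bs = bg @ s
    diag = np.diag(bg)
    for _ in range(10 * len(s) ** 2 + 10):
        gains = -4.0 * s * bs + 4.0 * diag  # change in s^T B s from flipping each node
        best = int(np.argmax(gains))
        if gains[best] <= _FINE_TUNE_TOL:
            break
        s[best] = -s[best]
        bs += 2.0 * s[best] * bg[:, best]
    return s


def detect_modules(network: AdjacencyNetwork, seed: int = 0) -> ModulePartition:
    """Community detection by spectral modularity maximization.

    Recursively bisects node groups along the leading eigenvector of the
    (generalized) modularity matrix ``B_ij = W_ij - s_i s_j / 2m``; after
    each bisection a fine-tuning pass greedily moves single nodes between
    the halves while modularity improves.  Recursion stops when a split's
    modularity contribution is not positive (<= 1e-10), so the returned
    partition never scores below the trivial single-module partition (Q=0).

    ``seed`` only breaks ties for eigenvector entries that are numerically
    zero; the algorithm is otherwise deterministic.
    """
    w = _weights(network, require_nonnegative=True)
    n = w.shape[0]
    s = w.sum(axis=1)
    two_m = s.sum()
    if two_m <= 0:
        raise ComputationError("module detection is undefined for a zero-weight network")
    b_full = w - np.outer(s, s) / two_m
    rng = np.random.default_rng(seed)

    assignment = np.zeros(n, dtype=np.int64)
    next_id = [1]

    def split(members: np.ndarray) -> None:
        if len(members) < 2:
            return
        bg = b_full[np.ix_(members, members)]
        bg = bg - np.diag(bg.sum(axis=1))  # generalized B(g): rows sum to zero
        eigvals, eigvecs = np.linalg.eigh(bg)
        if eigvals[-1] <= _SPLIT_TOL:
            return
        v = eigvecs[:, -1]
        # deterministic sign convention: flip so the largest-|.| entry is positive
        pivot = int(np.argmax(np.abs(v)))
        if v[pivot] < 0:
            v = -v
        sides = np.where(v > 0, 1.0, -1.0)
        ties = np.abs(v) <= 1e-12
        if ties.any():
            sides[ties] = rng.choice([-1.0, 1.0], size=int(ties.sum()))
        sides = _fine_tune(bg, sides)
        delta_q = float(sides @ bg @ sides) / (2.0 * two_m)
        if delta_q <= _SPLIT_TOL or np.all(sides == sides[0]):
            return
        left = members[sides > 0]
        right = members[sides < 0]
        assignment[right] = next_id[0]
        next_id[0] += 1
        split(left)
        split(right)

    split(np.arange(n))
    assignment = _relabel(assignment)
    return ModulePartition(assignment, modularity_Q(network, assignment))


# ---------------------------------------------------------------------------
# Bundled report
# ---------------------------------------------------------------------------


@dataclass
class StatsReport:
    """All metrics for one network, aligned to its ordering.

    ``nodal`` maps metric name to a :class:`NodeScalar`; ``global_scalars``
    holds global efficiency, mean clustering, and modularity Q; ``errors``
    records metrics that could not be computed (metric name -> message).
    """

    network: AdjacencyNetwork
    nodal: dict[str, NodeScalar] = field(default_factory=dict)
    global_scalars: dict[str, float] = field(default_factory=dict)
    partition: ModulePartition | None = None
    errors: dict[str, str] = field(default_factory=dict)

    def global_summary(self) -> dict[str, float | str]:
        out: dict[str, float | str] = dict(self.global_scalars)
        out.update({f"error_{k}": v for k, v in self.errors.items()})
        return out


def compute_all(network: AdjacencyNetwork, seed: int = 0) -> StatsReport:
    """Compute every statistic, recording per-metric failures by name."""
    report = StatsReport(network)

    def run(name, fn):
        try:
            return fn()
        except ConnviewErrors as exc:
            report.errors[name] = str(exc)
            return None

    for name, fn in [
        ("strength", lambda: strength(network)),
        ("clustering_binary", lambda: clustering_coefficient(network, "binary")),
        ("clustering_weighted", lambda: clustering_coefficient(network, "weighted")),
        ("local_efficiency_binary", lambda: local_efficiency(network, "binary")),
        ("local_efficiency_weighted", lambda: local_efficiency(network, "weighted")),
        ("betweenness_binary", lambda: betweenness_centrality(network, "binary")),
        ("betweenness_weighted", lambda: betweenness_centrality(network, "weighted")),
        ("eigenvector", lambda: eigenvector_centrality(network)),
    ]:
        result = run(name, fn)
        if result is not None:
            report.nodal[name] = result

    for name, fn in [
        ("global_efficiency_binary", lambda: global_efficiency(network, "binary")),
        ("global_efficiency_weighted", lambda: global_efficiency(network, "weighted")),
    ]:
        result = run(name, fn)
        if result is not None:
            report.global_scalars[name] = result

    for key in ("clustering_binary", "clustering_weighted"):
        if key in report.nodal:
            report.global_scalars[f"mean_{key}"] = float(report.nodal[key].values.mean())

    partition = run("modularity", lambda: detect_modules(network, seed=seed))
    if partition is not None:
        report.partition = partition
        report.global_scalars["modularity_Q"] = partition.Q
        report.global_scalars["n_modules"] = float(partition.n_modules)
    return report


ConnviewErrors = (ComputationError, ValidationError)
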