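"""Core network data model.

A brain network is an undirected, weighted graph bound to a *parcellation*:
the adjacency matrix carries the connection weights, and an accompanying
*ordering file* (one region name per line) declares which brain region each
row/column belongs to.  This module defines that data model — orderings,
adjacency matrices, edge thresholding, node isolation, name matching against
a parcellation, and affine coordinate registration — independent of any file
format or rendering concern.

All node indices are 0-based internally; user-facing messages refer to
ordering-file line numbers (line 1 = row/column 1).
"""

from __future__ import annotations

import difflib
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8

__all__ = [
    "ConnviewError",
    "FormatError",
    "ValidationError",
    "ComputationError",
    "Ordering",
    "AdjacencyNetwork",
    "ThresholdSpec",
    "EdgeSet",
    "AffineRegistration",
    "NodeScalar",
    "read_ordering",
    "load_matrix",
    "bind_matrix",
    "threshold_edges",
    "isolate_node",
    "apply_registration",
    "match_nodes",
    "canonical_name",
]


class ConnviewError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ConnviewError):
    """A file could not be parsed in any accepted format."""


class ValidationError(ConnviewError):
    """Input data violates a structural invariant."""


class ComputationError(ConnviewError):
    """A computation is undefined for the given network (e.g. zero weight)."""


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ordering:
    """Ordered list of region (ROI) names defining matrix row/column identity.

    Line *k* of the ordering file names row/column *k* of the adjacency
    matrix.  Names must be unique and non-empty.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) < 1:
            raise ValidationError("ordering must contain at least one name")
        seen: dict[str, int] = {}
        for lineno, name in enumerate(names, start=1):
            if not isinstance(name, str) or not name.strip():
                raise ValidationError(f"ordering entry {lineno} is empty")
            if name in seen:
                raise ValidationError(
                    f"duplicate region name {name!r} (entries {seen[name]} and {lineno})"
                )
            seen[name] = lineno

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        """Index of ``name``, raising with nearest-match suggestions."""
        try:
            return self.names.index(name)
        except ValueError:
            near = difflib.get_close_matches(name, self.names, n=3)
            hint = f"; nearest matches: {', '.join(near)}" if near else ""
            raise ValidationError(f"unknown region name {name!r}{hint}") from None


def read_ordering(path: str | Path) -> Ordering:
    """Read an ordering file: UTF-8 text, one region name per line.

    Blank lines and ``#``-prefixed comment lines are skipped; surrounding
    whitespace is stripped.
    """
    path = Path(path)
    names = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        name = raw.strip()
        if not name or name.startswith("#"):
            continue
        names.append(name)
    if not names:
        raise FormatError(f"ordering file {path} contains no region names")
    return Ordering(tuple(names))


def write_ordering(ordering: Ordering, path: str | Path) -> None:
    Path(path).write_text("\n".join(ordering.names) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Adjacency matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjacencyNetwork:
    """Undirected weighted network: symmetric matrix bound to an Ordering.

    The diagonal is zeroed at construction; self-connections carry no meaning
    for any operation in this package.
    """

    weights: np.ndarray
    ordering: Ordering

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] != len(self.ordering):
            raise ValidationError(
                f"matrix is {w.shape[0]}x{w.shape[1]} but ordering has "
                f"{len(self.ordering)} names"
            )
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"matrix is asymmetric (max |A - A^T| = {asym:g}); "
                "pass symmetrize=True to bind_matrix to coerce"
            )
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def node_index(self, node: int | str) -> int:
        if isinstance(node, str):
            return self.ordering.index(node)
        if not 0 <= node < self.n_nodes:
            raise ValidationError(f"node index {node} out of range [0, {self.n_nodes})")
        return int(node)


def bind_matrix(
    weights: np.ndarray,
    ordering: Ordering,
    symmetrize: bool = False,
) -> AdjacencyNetwork:
    """Bind a square weight matrix to an ordering.

    Row/column *k* of the matrix corresponds to name *k* of the ordering.
    An asymmetric input is an error unless ``symmetrize`` is set, in which
    case it is coerced to ``(A + A.T) / 2`` with a logged warning (this
    preserves total edge weight).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"weight matrix must be square, got shape {w.shape}")
    if w.shape[0] != len(ordering):
        raise ValidationError(
            f"dimension mismatch: matrix is {w.shape[0]}x{w.shape[1]} but "
            f"ordering has {len(ordering)} names"
        )
    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym > SYMMETRY_TOL:
        if not symmetrize:
            i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
            raise ValidationError(
                f"asymmetric matrix: |A[{i},{j}] - A[{j},{i}]| = {asym:g}; "
                "pass symmetrize=True to average with the transpose"
            )
        logger.warning(
            "asymmetric input matrix (max |A - A^T| = %g); symmetrized as (A + A^T)/2",
            asym,
        )
        w = (w + w.T) / 2.0
    return AdjacencyNetwork(w, ordering)


def load_matrix(path: str | Path, variable: str | None = None) -> np.ndarray:
    """Load a 2-D matrix from delimited text, MATLAB ``.mat``, or ``.npy``.

    For ``.mat`` files the single 2-D variable is used, or the one named by
    ``variable``.  Text files may be whitespace- or comma-delimited.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        arr = np.load(path)
    elif suffix == ".mat":
        import scipy.io

        try:
            contents = scipy.io.loadmat(path)
        except Exception as exc:  # noqa: BLE001 - loadmat raises many types
            raise FormatError(f"{path} is not a readable MATLAB v5 file: {exc}") from exc
        if variable is not None:
            if variable not in contents:
                raise FormatError(
                    f"{path} has no variable {variable!r}; found "
                    f"{[k for k in contents if not k.startswith('__')]}"
                )
            arr = contents[variable]
        else:
            arrays = {
                k: v
                for k, v in contents.items()
                if not k.startswith("__") and isinstance(v, np.ndarray) and v.ndim == 2
            }
            if len(arrays) != 1:
                raise FormatError(
                    f"{path} must contain exactly one 2-D variable "
                    f"(found {sorted(arrays)}); name one explicitly"
                )
            arr = next(iter(arrays.values()))
    else:
        try:
            text = path.read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            raise FormatError(
                f"{path}: not a text matrix; accepted formats are delimited "
                "text, MATLAB .mat, and .npy"
            ) from exc
        first = next((ln for ln in text.splitlines() if ln.strip()), "")
        delim = "," if "," in first else None
        try:
            arr = np.loadtxt(path, delimiter=delim, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: could not parse as a numeric matrix: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D matrix, got {arr.ndim}-D")
    return arr


# ---------------------------------------------------------------------------
# Thresholding and edge sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdSpec:
    """How to reduce a dense matrix to a drawable set of connections.

    Modes:

    ``count``
        Keep the ``k`` strongest edges (default ``k=500``, the standard
        cutoff balancing legibility and rendering cost for whole-brain
        matrices).
    ``proportion``
        Keep the top ``ceil(p * E)`` of the ``E`` nonzero edges.
    ``value``
        Keep edges whose (signed or absolute) weight is at least ``v``.

    ``rank_by='signed'`` ranks by raw weight descending; ``'absolute'`` by
    magnitude, which is appropriate for correlation networks where strong
    negative couplings are meaningful.
    """

    mode: Literal["count", "proportion", "value"] = "count"
    k: int = 500
    p: float | None = None
    v: float | None = None
    rank_by: Literal["signed", "absolute"] = "signed"

    def __post_init__(self) -> None:
        if self.mode not in ("count", "proportion", "value"):
            raise ValidationError(f"unknown threshold mode {self.mode!r}")
        if self.rank_by not in ("signed", "absolute"):
            raise ValidationError(f"unknown rank_by {self.rank_by!r}")
        if self.mode == "count" and (not isinstance(self.k, int) or self.k < 1):
            raise ValidationError(f"count mode requires positive integer k, got {self.k!r}")
        if self.mode == "proportion":
            if self.p is None or not 0.0 < self.p <= 1.0:
                raise ValidationError(f"proportion mode requires p in (0, 1], got {self.p!r}")
        if self.mode == "value" and self.v is None:
            raise ValidationError("value mode requires a cutoff v")


@dataclass(frozen=True)
class EdgeSet:
    """Explicit list of undirected weighted edges ``(i, j, w)`` with i < j."""

    edges: tuple[tuple[int, int, float], ...]
    source_n: int

    def __post_init__(self) -> None:
        edges = tuple((int(i), int(j), float(w)) for i, j, w in self.edges)
        object.__setattr__(self, "edges", edges)
        seen = set()
        for i, j, _ in edges:
            if not 0 <= i < j < self.source_n:
                raise ValidationError(
                    f"edge ({i}, {j}) out of range for {self.source_n} nodes"
                )
            if (i, j) in seen:
                raise ValidationError(f"duplicate edge ({i}, {j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}


def _upper_edges(network: AdjacencyNetwork):
    """All nonzero undirected edges of the network as (i, j, w) with i < j."""
    iu, ju = np.triu_indices(network.n_nodes, k=1)
    w = network.weights[iu, ju]
    nz = w != 0.0
    return list(zip(iu[nz].tolist(), ju[nz].tolist(), w[nz].tolist()))


def threshold_edges(network: AdjacencyNetwork, spec: ThresholdSpec | None = None) -> EdgeSet:
    """Apply a threshold, returning the surviving undirected edges.

    Edges are ranked by descending weight (or |weight| in absolute mode);
    rank ties are broken by ascending ``(i, j)`` so the result is
    deterministic.  An empty result is valid.
    """
    if spec is None:
        spec = ThresholdSpec()
    edges = _upper_edges(network)
    key = (lambda e: (-abs(e[2]), e[0], e[1])) if spec.rank_by == "absolute" else (
        lambda e: (-e[2], e[0], e[1])
    )
    ranked = sorted(edges, key=key)
    if spec.mode == "count":
        kept = ranked[: spec.k]
    elif spec.mode == "proportion":
        kept = ranked[: math.ceil(spec.p * len(ranked))]
    else:
        mag = (lambda w: abs(w)) if spec.rank_by == "absolute" else (lambda w: w)
        kept = [e for e in ranked if mag(e[2]) >= spec.v]
    kept.sort(key=lambda e: (e[0], e[1]))
    return EdgeSet(tuple(kept), network.n_nodes)


def isolate_node(
    network: AdjacencyNetwork, edges: EdgeSet, node: int | str
) -> EdgeSet:
    """Restrict an edge set to the connections incident to one node.

    This is the programmatic form of clicking a node in an interactive
    viewer: only that node's connections remain visible.
    """
    idx = network.node_index(node)
    kept = tuple(e for e in edges.edges if idx in (e[0], e[1]))
    return EdgeSet(kept, edges.source_n)


# ---------------------------------------------------------------------------
# Affine registration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffineRegistration:
    """4x4 homogeneous transform from volume space to anatomical mm space."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"registration matrix must be 4x4, got {m.shape}")
        if np.abs(m[3] - np.array([0.0, 0.0, 0.0, 1.0])).max() > 1e-6:
            raise ValidationError(
                f"registration bottom row must be [0, 0, 0, 1], got {m[3].tolist()}"
            )
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValidationError("registration matrix is not invertible")
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    def inverse(self) -> "AffineRegistration":
        return AffineRegistration(np.linalg.inv(self.matrix))


def apply_registration(coords: np.ndarray, reg: AffineRegistration) -> np.ndarray:
    """Map m x 3 coordinates through a homogeneous affine transform."""
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    if c.shape[1] != 3:
        raise ValidationError(f"coordinates must be m x 3, got shape {c.shape}")
    if not np.isfinite(c).all():
        raise ValidationError("coordinates contain non-finite values")
    homo = np.hstack([c, np.ones((c.shape[0], 1))])
    return (homo @ reg.matrix.T)[:, :3]


# ---------------------------------------------------------------------------
# Node scalars
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeScalar:
    """A per-node real value (e.g. strength) aligned to an Ordering."""

    values: np.ndarray
    name: str = "scalar"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise ValidationError("scalar vector is empty")
        if not np.isfinite(v).all():
            raise ValidationError(f"scalar {self.name!r} contains non-finite values")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Name canonicalization and parcellation matching
# ---------------------------------------------------------------------------

# Hemisphere markers accepted as prefix ("lh_X", "lh.X", "Left-X") or suffix
# ("X-lh", "X_rh").  Exact (case-sensitive) matching is always attempted
# before canonicalization.
_HEMI_ALIASES = {"lh": "lh", "rh": "rh", "left": "lh", "right": "rh", "l": "lh", "r": "rh"}
_PREFIX_RE = re.compile(r"^(lh|rh|left|right)[._-](.+)$", re.IGNORECASE)
_SUFFIX_RE = re.compile(r"^(.+)[._-](lh|rh|left|right)$", re.IGNORECASE)


def canonical_name(name: str) -> tuple[str, str]:
    """Canonical ``(hemisphere, base)`` key for a region name.

    ``"lh_precentral"``, ``"precentral-lh"``, ``"LH.Precentral"`` and
    ``"Left-Precentral"`` all canonicalize to ``("lh", "precentral")``.
    Names without a hemisphere marker get hemisphere ``""``.  Separator
    characters ``.-`` inside the base collapse to ``_``.
    """
    name = name.strip()
    hemi = ""
    m = _PREFIX_RE.match(name)
    if m:
        hemi, base = _HEMI_ALIASES[m.group(1).lower()], m.group(2)
    else:
        m = _SUFFIX_RE.match(name)
        if m:
            base, hemi = m.group(1), _HEMI_ALIASES[m.group(2).lower()]
        else:
            base = name
    base = re.sub(r"[.\-\s]+", "_", base.lower()).strip("_")
    return hemi, base


def match_nodes(ordering: Ordering, parcellation) -> dict[int, int]:
    """Match ordering names to parcellation nodes.

    Returns a mapping from ordering index to parcellation node index.
    Exact name matches win; otherwise names are compared case-insensitively
    after canonicalizing hemisphere prefixes/suffixes.  Subcortical names
    (e.g. ``Left-Hippocampus``) canonicalize the same way and resolve to the
    parcellation entries derived from the segmentation volume.
    """
    exact = {node.name: i for i, node in enumerate(parcellation.nodes)}
    canon: dict[tuple[str, str], list[int]] = {}
    for i, node in enumerate(parcellation.nodes):
        canon.setdefault(canonical_name(node.name), []).append(i)

    mapping: dict[int, int] = {}
    unmatched: list[str] = []
    for oi, name in enumerate(ordering.names):
        if name in exact:
            mapping[oi] = exact[name]
            continue
        candidates = canon.get(canonical_name(name), [])
        if len(candidates) == 1:
            mapping[oi] = candidates[0]
        elif len(candidates) > 1:
            names = [parcellation.nodes[c].name for c in candidates]
            raise ValidationError(
                f"ordering name {name!r} matches multiple parcellation nodes: {names}"
            )
        else:
            unmatched.append(name)
    if unmatched:
        raise ValidationError(
            f"{len(unmatched)} ordering name(s) not found in the parcellation: "
            f"{unmatched}"
        )
    return mapping
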