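"""The three linked network views: 3-D brain, connectivity matrix, circle.

One :class:`Scene` holds the full visualization state — parcellation,
network, the active (thresholded/isolated) edge set, optional per-node
scalars, optional module partition, optional cortical surface, and a
:class:`ViewStyle`.  Each renderer draws that single scene, so any
isolation, scalar mapping, or module display appears consistently in all
three images, and each emits a machine-readable *draw log* recording what
it drew (in particular, the number of connection primitives).

Rendering is deliberately non-interactive: the 3-D view is an orthographic
painter's-algorithm projection (depth-sorted triangles, segments, and
discs) rasterized through the Agg backend, so a fixed scene, style, and
camera produce byte-identical image files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib
import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.colors import LinearSegmentedColormap, hsv_to_rgb
from matplotlib.figure import Figure
from matplotlib.patches import Circle, PathPatch, Polygon, Wedge
from matplotlib.path import Path as MplPath

from .core import AdjacencyNetwork, EdgeSet, NodeScalar, ValidationError
from .io import Parcellation
from .stats import ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "ViewStyle",
    "Scene",
    "CAMERA_PRESETS",
    "render_3d",
    "render_matrix",
    "render_circle",
    "apply_scalar_mapping",
    "apply_module_display",
    "export_views",
    "circle_layout",
    "matrix_cell_colors",
]

#: Camera presets as (azimuth, elevation) in degrees for RAS coordinates
#: (x right, y anterior, z superior).
CAMERA_PRESETS: dict[str, tuple[float, float]] = {
    "right-lateral": (0.0, 0.0),
    "left-lateral": (180.0, 0.0),
    "anterior": (90.0, 0.0),
    "posterior": (-90.0, 0.0),
    "dorsal": (0.0, 90.0),
    "ventral": (0.0, -90.0),
}

# Named color profiles.  Edges default to yellow (weak) -> red (strong);
# the blue -> orange alternative suits correlation matrices.  Node scalars
# run light green (low) -> dark green (high).
_EDGE_PROFILES = {
    "yellow-red": [(1.0, 0.92, 0.25), (0.85, 0.05, 0.05)],
    "blue-orange": [(0.15, 0.35, 0.85), (1.0, 0.55, 0.05)],
}
_SCALAR_PROFILES = {
    "greens": [(0.78, 0.95, 0.72), (0.0, 0.32, 0.05)],
}


def _colormap(name: str, profiles: dict) -> matplotlib.colors.Colormap:
    if name in profiles:
        return LinearSegmentedColormap.from_list(name, profiles[name])
    return matplotlib.colormaps[name]


@dataclass(frozen=True)
class ViewStyle:
    """Shared visual parameters for the three renderers.

    ``scalar_size_range`` is the (min, max) node disc radius in millimetres
    of anatomical space (the 3-D view's native unit; the circle view scales
    it relative to the circle radius).  ``edge_norm='rank'`` maps weights to
    colors by rank among the active edges, which is robust to outliers;
    ``'linear'`` uses min-max normalization.
    """

    edge_colormap: str = "yellow-red"
    node_default_color: tuple[float, float, float] = (0.25, 0.35, 0.8)
    scalar_colormap: str = "greens"
    scalar_size_range: tuple[float, float] = (2.0, 7.0)
    background: tuple[float, float, float] = (1.0, 1.0, 1.0)
    image_size: tuple[int, int] = (640, 480)
    surface_opacity: float = 0.15
    edge_norm: str = "rank"
    circle_start_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValidationError(f"image size must be positive, got {self.image_size}")
        if not 0.0 <= self.surface_opacity <= 1.0:
            raise ValidationError(
                f"surface opacity must be in [0, 1], got {self.surface_opacity}"
            )
        if self.edge_norm not in ("rank", "linear"):
            raise ValidationError(f"unknown edge_norm {self.edge_norm!r}")

    def edge_cmap(self):
        return _colormap(self.edge_colormap, _EDGE_PROFILES)

    def scalar_cmap(self):
        return _colormap(self.scalar_colormap, _SCALAR_PROFILES)


@dataclass(frozen=True)
class Scene:
    """Complete state shared by the three renderers.

    The parcellation must be index-aligned with the network ordering (use
    :func:`connview.core.match_nodes` to reorder an arbitrary parcellation
    first).  ``node_colors``, when set (module display), overrides scalar
    color mapping.
    """

    parcellation: Parcellation
    network: AdjacencyNetwork
    edges: EdgeSet
    size_scalar: NodeScalar | None = None
    color_scalar: NodeScalar | None = None
    partition: ModulePartition | None = None
    module_colors: np.ndarray | None = None
    isolated_module: int | None = None
    node_colors: np.ndarray | None = None
    surface: object | None = None  # SurfaceGeometry or sequence of them
    style: ViewStyle = field(default_factory=ViewStyle)

    def __post_init__(self) -> None:
        n = self.network.n_nodes
        if len(self.parcellation) != n:
            raise ValidationError(
                f"parcellation has {len(self.parcellation)} nodes, network has {n}"
            )
        if self.edges.source_n != n:
            raise ValidationError(
                f"edge set built for {self.edges.source_n} nodes, network has {n}"
            )
        for scalar in (self.size_scalar, self.color_scalar):
            if scalar is not None and len(scalar) != n:
                raise ValidationError(
                    f"scalar {scalar.name!r} has {len(scalar)} values, network has {n}"
                )
        if self.partition is not None and len(self.partition.assignment) != n:
            raise ValidationError("partition is not aligned to the network")

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    # -- per-node visual attributes ------------------------------------

    def node_radii(self) -> np.ndarray:
        lo, hi = self.style.scalar_size_range
        if self.size_scalar is None:
            return np.full(self.n_nodes, (lo + hi) / 2.0)
        v = self.size_scalar.values
        span = v.max() - v.min()
        if span == 0:
            return np.full(self.n_nodes, (lo + hi) / 2.0)
        return lo + (v - v.min()) / span * (hi - lo)

    def node_rgb(self) -> np.ndarray:
        if self.node_colors is not None:
            return np.asarray(self.node_colors, dtype=float)
        if self.partition is not None and self.module_colors is not None:
            return self.module_colors[self.partition.assignment]
        if self.color_scalar is not None:
            v = self.color_scalar.values
            span = v.max() - v.min()
            norm = np.full_like(v, 0.5) if span == 0 else (v - v.min()) / span
            return self.style.scalar_cmap()(norm)[:, :3]
        return np.tile(np.asarray(self.style.node_default_color), (self.n_nodes, 1))

    def edge_rgb(self) -> np.ndarray:
        e = len(self.edges)
        if e == 0:
            return np.zeros((0, 3))
        w = np.array([edge[2] for edge in self.edges])
        if self.style.edge_norm == "rank":
            order = np.argsort(w, kind="stable")
            rank = np.empty(e)
            rank[order] = np.arange(e)
            norm = (rank + 1.0) / e
        else:
            span = w.max() - w.min()
            norm = np.ones(e) if span == 0 else (w - w.min()) / span
        return self.style.edge_cmap()(norm)[:, :3]

    def group_rgb(self) -> np.ndarray:
        return np.array([node.group_color for node in self.parcellation.nodes])


# ---------------------------------------------------------------------------
# Scene transformations (the programmatic form of viewer interactions)
# ---------------------------------------------------------------------------


def apply_scalar_mapping(
    scene: Scene, size_scalar: NodeScalar | None, color_scalar: NodeScalar | None
) -> Scene:
    """Map one scalar to node size and another (possibly the same) to color.

    Sizes interpolate linearly from the scalar's min to its max over
    ``style.scalar_size_range``; a constant scalar maps every node to the
    midpoint.  Colors pass min-max normalized values through the scalar
    colormap.
    """
    return replace(scene, size_scalar=size_scalar, color_scalar=color_scalar,
                   node_colors=None)


def module_palette(n_modules: int, seed: int) -> np.ndarray:
    """``n_modules`` visually distinct RGB colors, shuffled by ``seed``."""
    rng = np.random.default_rng(seed)
    hues = rng.permutation(n_modules) / max(n_modules, 1)
    hsv = np.stack([hues, np.full(n_modules, 0.65), np.full(n_modules, 0.9)], axis=1)
    return hsv_to_rgb(hsv)


#: Fig-style isolation colors: nodes inside the isolated module vs outside.
_IN_MODULE_COLOR = (0.5, 0.2, 0.7)    # purple
_OUT_MODULE_COLOR = (0.25, 0.35, 0.8)  # blue


def apply_module_display(
    scene: Scene,
    partition: ModulePartition,
    seed: int = 0,
    isolate: int | None = None,
) -> Scene:
    """Color nodes by module, optionally isolating a single module.

    Module colors come from a seeded random palette (same seed, same
    colors; distinct modules get distinct colors).  With ``isolate``, the
    active edge set is reduced to the connections with *both* endpoints in
    that module, in-module nodes turn purple and all others blue.
    """
    if len(partition.assignment) != scene.n_nodes:
        raise ValidationError("partition is not aligned to the scene's network")
    colors = module_palette(partition.n_modules, seed)
    if isolate is None:
        return replace(scene, partition=partition, module_colors=colors,
                       isolated_module=None, node_colors=None)
    if not 0 <= isolate < partition.n_modules:
        raise ValidationError(
            f"unknown module id {isolate}; valid ids: 0..{partition.n_modules - 1}"
        )
    members = set(partition.members(isolate).tolist())
    kept = tuple(e for e in scene.edges if e[0] in members and e[1] in members)
    node_colors = np.array([
        _IN_MODULE_COLOR if i in members else _OUT_MODULE_COLOR
        for i in range(scene.n_nodes)
    ])
    return replace(
        scene,
        partition=partition,
        module_colors=colors,
        isolated_module=isolate,
        edges=EdgeSet(kept, scene.edges.source_n),
        node_colors=node_colors,
    )


# ---------------------------------------------------------------------------
# Shared figure plumbing
# ---------------------------------------------------------------------------


def _new_figure(style: ViewStyle) -> tuple[Figure, FigureCanvasAgg]:
    w, h = style.image_size
    fig = Figure(figsize=(w / 100.0, h / 100.0), dpi=100.0)
    fig.set_facecolor(style.background)
    return fig, FigureCanvasAgg(fig)


def _save(fig: Figure, path: str | Path | None, dpi: float | None) -> None:
    if path is None:
        return
    fig.savefig(str(path), dpi=dpi if dpi is not None else 100.0,
                facecolor=fig.get_facecolor())


# ---------------------------------------------------------------------------
# 3-D brain view
# ---------------------------------------------------------------------------


def _camera_basis(camera) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    if isinstance(camera, str):
        if camera not in CAMERA_PRESETS:
            raise ValidationError(
                f"unknown camera preset {camera!r}; presets: "
                f"{', '.join(sorted(CAMERA_PRESETS))}"
            )
        azimuth, elevation = CAMERA_PRESETS[camera]
    else:
        azimuth, elevation = camera
    a = np.deg2rad(azimuth)
    e = np.deg2rad(elevation)
    toward = np.array([np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), np.sin(e)])
    screen_x = np.array([-np.sin(a), np.cos(a), 0.0])
    screen_y = np.array([-np.sin(e) * np.cos(a), -np.sin(e) * np.sin(a), np.cos(e)])
    return screen_x, screen_y, toward, [float(azimuth), float(elevation)]


def render_3d(
    scene: Scene,
    path: str | Path | None = None,
    camera: str | tuple[float, float] = "left-lateral",
    dpi: float | None = None,
) -> dict:
    """Orthographic node-link rendering of the network inside the brain.

    Node discs sit at their anatomical mm centers, edges are straight
    segments, and the cortical surface (when the scene has one) is drawn as
    depth-sorted translucent triangles.  Returns the draw log.
    """
    centers = scene.parcellation.centers
    if centers.size == 0:
        raise ValidationError(
            "no node centers available; supply a parcellation (surface+annot, "
            "segmentation, or coordinate table)"
        )
    sx, sy, toward, cam = _camera_basis(camera)
    xy = centers @ np.stack([sx, sy], axis=1)
    depth = centers @ toward

    # primitives: (depth, z-tier, insertion rank, draw function)
    prims: list[tuple[float, int, int, object]] = []
    rank = 0

    n_triangles = 0
    surfaces = scene.surface if isinstance(scene.surface, (list, tuple)) else (
        [scene.surface] if scene.surface is not None else []
    )
    for surf in surfaces:
        v2d = surf.vertices @ np.stack([sx, sy], axis=1)
        vdepth = surf.vertices @ toward
        for face in surf.faces:
            tri = v2d[face]
            d = float(vdepth[face].mean())
            prims.append((d, 0, rank, ("tri", tri)))
            rank += 1
            n_triangles += 1

    edge_colors = scene.edge_rgb()
    for (i, j, _w), color in zip(scene.edges, edge_colors):
        d = float((depth[i] + depth[j]) / 2.0)
        prims.append((d, 1, rank, ("seg", (xy[i], xy[j]), tuple(color))))
        rank += 1

    radii = scene.node_radii()
    node_rgb = scene.node_rgb()
    for i in range(scene.n_nodes):
        prims.append((float(depth[i]), 1, rank,
                      ("disc", tuple(xy[i]), float(radii[i]), tuple(node_rgb[i]))))
        rank += 1

    # painter's algorithm: farthest first; nodes/edges (tier 1) over
    # coincident surface triangles (tier 0); insertion rank settles the rest
    prims.sort(key=lambda p: (p[0], p[1], p[2]))

    fig, _canvas = _new_figure(scene.style)
    ax = fig.add_axes([0.0, 0.0, 1.0, 1.0])
    ax.set_axis_off()
    ax.set_aspect("equal")

    pts = [xy]
    for surf in surfaces:
        pts.append(surf.vertices @ np.stack([sx, sy], axis=1))
    allpts = np.vstack(pts)
    pad = 0.08 * max(np.ptp(allpts[:, 0]), np.ptp(allpts[:, 1]), 1.0)
    ax.set_xlim(allpts[:, 0].min() - pad, allpts[:, 0].max() + pad)
    ax.set_ylim(allpts[:, 1].min() - pad, allpts[:, 1].max() + pad)

    alpha = scene.style.surface_opacity
    for _d, _tier, _r, prim in prims:
        kind = prim[0]
        if kind == "tri":
            ax.add_patch(Polygon(prim[1], closed=True,
                                 facecolor=(0.75, 0.75, 0.78, alpha),
                                 edgecolor=(0.6, 0.6, 0.65, alpha * 0.5),
                                 linewidth=0.2))
        elif kind == "seg":
            (p0, p1), color = prim[1], prim[2]
            ax.plot([p0[0], p1[0]], [p0[1], p1[1]], color=color,
                    linewidth=1.2, solid_capstyle="round", zorder=None)
        else:
            _kind, center, radius, color = prim
            ax.add_patch(Circle(center, radius=radius, facecolor=color,
                                edgecolor=(0.1, 0.1, 0.1), linewidth=0.4))

    _save(fig, path, dpi)
    return {
        "view": "3d",
        "camera": cam,
        "n_nodes": scene.n_nodes,
        "n_edges": len(scene.edges),
        "n_surface_triangles": n_triangles,
        "node_xy": [[round(float(p[0]), 6), round(float(p[1]), 6)] for p in xy],
    }


# ---------------------------------------------------------------------------
# Matrix view
# ---------------------------------------------------------------------------


def matrix_cell_colors(scene: Scene) -> np.ndarray:
    """The n x n x 3 RGB cell array the matrix view draws.

    Cells outside the active edge set (including the whole diagonal) carry
    the background color; each active edge colors both (i, j) and (j, i).
    Exposed separately from the renderer so ordering-equivariance can be
    checked directly on the drawn values.
    """
    n = scene.n_nodes
    cells = np.tile(np.asarray(scene.style.background, dtype=float), (n, n, 1))
    colors = scene.edge_rgb()
    for (i, j, _w), color in zip(scene.edges, colors):
        cells[i, j] = color
        cells[j, i] = color
    return cells


def render_matrix(scene: Scene, path: str | Path | None = None,
                  dpi: float | None = None) -> dict:
    """Connectivity-matrix heatmap with anatomical-group color bands.

    Rows and columns follow the network ordering; the bands along the left
    and top axes repeat each node's group color, so contiguous anatomical
    blocks are visible at a glance.
    """
    n = scene.n_nodes
    cells = matrix_cell_colors(scene)
    groups = scene.group_rgb()

    fig, _canvas = _new_figure(scene.style)
    ax = fig.add_axes([0.12, 0.04, 0.84, 0.84])
    ax.imshow(cells, interpolation="nearest", origin="upper")
    ax.set_xticks([])
    ax.set_yticks([])

    ax_left = fig.add_axes([0.07, 0.04, 0.035, 0.84])
    ax_left.imshow(groups.reshape(n, 1, 3), interpolation="nearest",
                   origin="upper", aspect="auto")
    ax_left.set_axis_off()
    ax_top = fig.add_axes([0.12, 0.90, 0.84, 0.035])
    ax_top.imshow(groups.reshape(1, n, 3), interpolation="nearest",
                  origin="upper", aspect="auto")
    ax_top.set_axis_off()

    _save(fig, path, dpi)
    distinct_bands = len({tuple(np.round(g, 6)) for g in groups})
    return {
        "view": "matrix",
        "n_nodes": n,
        "n_edges": len(scene.edges),
        "n_band_colors": distinct_bands,
    }


# ---------------------------------------------------------------------------
# Circle view
# ---------------------------------------------------------------------------


def circle_layout(n: int, start_deg: float = 90.0) -> np.ndarray:
    """Angular node positions (degrees): node k at ``start - 360 k / n``.

    Node 0 sits at the start angle (top by default) and successive ordering
    entries proceed clockwise, so an ordering listing the left hemisphere
    first fills the right half of the circle with left-hemisphere nodes.
    """
    k = np.arange(n)
    return np.mod(start_deg - 360.0 * k / n, 360.0)


def _bezier_arc(theta_i: float, theta_j: float, radius: float = 1.0) -> MplPath:
    """Cubic Bezier between two circle points, pulled toward the center.

    The interior control points sit at the endpoint angles but at radius
    ``r_c = r * (1 - g/180)`` (clamped to [0.05 r, 0.95 r]) where g is the
    angular separation in degrees: adjacent nodes get a shallow arc,
    antipodal nodes an arc through the center.
    """
    g = abs(theta_i - theta_j) % 360.0
    if g > 180.0:
        g = 360.0 - g
    rc = radius * np.clip(1.0 - g / 180.0, 0.05, 0.95)
    ti, tj = np.deg2rad(theta_i), np.deg2rad(theta_j)
    p0 = radius * np.array([np.cos(ti), np.sin(ti)])
    p3 = radius * np.array([np.cos(tj), np.sin(tj)])
    c1 = rc * np.array([np.cos(ti), np.sin(ti)])
    c2 = rc * np.array([np.cos(tj), np.sin(tj)])
    return MplPath([p0, c1, c2, p3],
                   [MplPath.MOVETO, MplPath.CURVE4, MplPath.CURVE4, MplPath.CURVE4])


def render_circle(scene: Scene, path: str | Path | None = None,
                  dpi: float | None = None) -> dict:
    """Circular connectogram: nodes on a circle, connections as arcs.

    Nodes are equally spaced in ordering order (gap exactly 360/n degrees);
    the circumference segment behind each node carries its anatomical group
    color, and arc colors follow the edge colormap.
    """
    n = scene.n_nodes
    angles = circle_layout(n, scene.style.circle_start_deg)
    fig, _canvas = _new_figure(scene.style)
    ax = fig.add_axes([0.0, 0.0, 1.0, 1.0])
    ax.set_axis_off()
    ax.set_aspect("equal")
    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.35, 1.35)

    # group-colored circumference segments (one per node, clockwise order)
    half = 180.0 / n
    groups = scene.group_rgb()
    for k in range(n):
        ax.add_patch(Wedge((0.0, 0.0), 1.18, angles[k] - half, angles[k] + half,
                           width=0.09, facecolor=tuple(groups[k]),
                           edgecolor="none"))

    edge_colors = scene.edge_rgb()
    for (i, j, _w), color in zip(scene.edges, edge_colors):
        arc = _bezier_arc(angles[i], angles[j])
        ax.add_patch(PathPatch(arc, facecolor="none", edgecolor=tuple(color),
                               linewidth=1.1, capstyle="round"))

    radii = scene.node_radii()
    node_rgb = scene.node_rgb()
    lo, hi = scene.style.scalar_size_range
    # scale mm radii into circle units so scalar size mapping stays visible
    scale = 0.035 / max(hi, 1e-9)
    for k in range(n):
        t = np.deg2rad(angles[k])
        ax.add_patch(Circle((np.cos(t), np.sin(t)), radius=radii[k] * scale,
                            facecolor=tuple(node_rgb[k]),
                            edgecolor=(0.1, 0.1, 0.1), linewidth=0.3))

    _save(fig, path, dpi)
    return {
        "view": "circle",
        "n_nodes": n,
        "n_edges": len(scene.edges),
        "start_deg": scene.style.circle_start_deg,
        "angles_deg": [float(a) for a in angles],
    }


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_views(
    scene: Scene,
    out_dir: str | Path,
    camera: str | tuple[float, float] = "left-lateral",
    dpi: float = 100.0,
    draw_log: bool = True,
    prefix: str = "",
) -> dict:
    """Render all three views of one scene to PNG files.

    Returns ``{"images": {view: path}, "draw_logs": {view: log}}``.  With
    ``draw_log`` a ``draw_log.json`` is written alongside the images; the
    connection count is identical across the three logs by construction
    (all renderers draw the same active edge set).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images: dict[str, str] = {}
    logs: dict[str, dict] = {}
    for view, renderer, kwargs in [
        ("3d", render_3d, {"camera": camera}),
        ("matrix", render_matrix, {}),
        ("circle", render_circle, {}),
    ]:
        target = out_dir / f"{prefix}{view}.png"
        logs[view] = renderer(scene, target, dpi=dpi, **kwargs)
        images[view] = str(target)
    if draw_log:
        log_path = out_dir / f"{prefix}draw_log.json"
        log_path.write_text(json.dumps(logs, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
    return {"images": images, "draw_logs": logs}
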