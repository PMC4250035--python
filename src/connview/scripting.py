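"""Standalone-script execution against the library API.

A script is an ordinary Python program run with a namespace pre-populated
with the package modules and a few helpers for the most common operations,
so short analysis scripts need no imports:

``load_network(matrix_path, ordering_path)``
    Load and bind a connectivity matrix.
``load_dataset(directory)``
    Load a fixture-style dataset directory into (network, parcellation).
``make_scene(network, parcellation, threshold=...)``
    Threshold and wrap into a renderable scene.
``render_views(scene, out_dir, camera=...)``
    Export the three linked views.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import core, fixtures, io, stats, views
from .core import (
    AdjacencyNetwork,
    Ordering,
    ThresholdSpec,
    bind_matrix,
    load_matrix,
    read_ordering,
    threshold_edges,
)
from .io import (
    Parcellation,
    assemble_parcellation,
    parcel_centers,
    read_annotation,
    read_segmentation,
    read_surface,
)
from .views import Scene, ViewStyle, export_views

__all__ = ["run_script", "load_network", "load_dataset", "make_scene", "render_views"]


def load_network(matrix_path, ordering_path, symmetrize: bool = False) -> AdjacencyNetwork:
    ordering = read_ordering(ordering_path)
    return bind_matrix(load_matrix(matrix_path), ordering, symmetrize=symmetrize)


def load_dataset(directory) -> tuple[AdjacencyNetwork, Parcellation]:
    """Load a dataset directory laid out like the generated fixtures."""
    directory = Path(directory)
    network = load_network(directory / "matrix.txt", directory / "ordering.txt")
    centers: dict = {}
    for surf_name, annot_name in [
        ("lh.white", "lh.parcels.annot"),
        ("rh.white.gii", "rh.parcels.annot"),
    ]:
        surface = read_surface(directory / surf_name)
        annot = read_annotation(directory / annot_name)
        centers.update(parcel_centers(surface, annot))
    lookup_path = directory / "aseg_lookup.json"
    lookup = {int(k): v for k, v in json.loads(lookup_path.read_text()).items()}
    seg = read_segmentation(directory / "aseg.nii.gz", lookup)
    groups = json.loads((directory / "groups.json").read_text())
    parcellation = assemble_parcellation(
        network.ordering, centers, segmentation=seg, groups=groups
    )
    return network, parcellation


def make_scene(
    network: AdjacencyNetwork,
    parcellation: Parcellation,
    threshold: ThresholdSpec | None = None,
    style: ViewStyle | None = None,
) -> Scene:
    edges = threshold_edges(network, threshold or ThresholdSpec())
    return Scene(parcellation, network, edges, style=style or ViewStyle())


def render_views(scene: Scene, out_dir, camera="left-lateral", dpi: float = 100.0):
    return export_views(scene, out_dir, camera=camera, dpi=dpi)


def run_script(path) -> None:
    """Execute a standalone script with the helper namespace.

    Exceptions propagate to the caller (the command-line front end converts
    them into a nonzero exit status).
    """
    path = Path(path)
    source = path.read_text(encoding="utf-8")
    namespace = {
        "__name__": "__main__",
        "__file__": str(path),
        "core": core,
        "io": io,
        "stats": stats,
        "views": views,
        "fixtures": fixtures,
        "load_network": load_network,
        "load_dataset": load_dataset,
        "make_scene": make_scene,
        "render_views": render_views,
        "ThresholdSpec": ThresholdSpec,
        "ViewStyle": ViewStyle,
        "Scene": Scene,
    }
    code = compile(source, str(path), "exec")
    exec(code, namespace)  # noqa: S102 - scripts are the user's own programs
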