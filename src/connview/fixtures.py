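"""Synthetic brain datasets with known ground truth.

Real parcellations and connectivity matrices require neuroimaging
pipelines; this module builds small stand-ins with the same structure so
every reader, statistic, and renderer can be exercised end-to-end:

* :func:`make_toy_brain` — two mirrored ellipsoid cortical meshes (one per
  hemisphere) parcellated into angular sectors grouped into four "lobes"
  (frontal, parietal, occipital, temporal, in the principled
  front-to-temporal sweep order used for matrix/circle displays), plus a
  small labeled volume holding two subcortical structures per hemisphere;
* :func:`make_modular_network` — a planted-partition weighted graph whose
  true module labels are returned alongside, for community-recovery tests;
* :func:`make_lateral_network` — homologous left/right region pairs boosted
  above a distance-decay background, emulating the strong interhemispheric
  connectivity characteristic of resting-state fMRI networks.

All generators are fully determined by their seed.  The default scale
(33 cortical nodes per hemisphere, about 66 cortical nodes total) mirrors
the coarsest whole-brain parcellations in common use while keeping tests
fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    AdjacencyNetwork,
    Ordering,
    ValidationError,
    bind_matrix,
    canonical_name,
    write_ordering,
)
from .io import (
    GROUP_COLORS,
    Parcellation,
    ParcellationNode,
    SegmentationVolume,
    SurfaceAnnotation,
    SurfaceGeometry,
    parcel_centers,
    write_annotation,
    write_segmentation,
    write_surface,
)

__all__ = [
    "FixtureSpec",
    "ToyBrain",
    "icosphere",
    "make_toy_brain",
    "make_modular_network",
    "make_lateral_network",
    "write_fixture_dataset",
]

LOBES = ("frontal", "parietal", "occipital", "temporal")

# hemisphere ellipsoid semi-axes (mm) and center offset from the midline
_SEMI_AXES = np.array([28.0, 65.0, 45.0])
_HEMI_OFFSET = 32.0

# subcortical blobs: (name, aseg label, voxel index block lo..hi inclusive)
_SUBCORTICAL_BLOBS = [
    ("Left-Hippocampus", 17, (3, 5), (8, 10), (8, 10)),
    ("Left-Thalamus-Proper", 10, (3, 5), (13, 15), (11, 13)),
    ("Right-Hippocampus", 53, (18, 20), (8, 10), (8, 10)),
    ("Right-Thalamus-Proper", 49, (18, 20), (13, 15), (11, 13)),
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic dataset.

    ``p_in``/``p_out`` are the within/between-module edge probabilities of
    the planted-partition generator (defaults give clearly recoverable
    modules); weights are i.i.d. uniform on (0, 1] or lognormal(mu, sigma).
    """

    n_nodes_per_hemisphere: int = 33
    n_modules: int = 4
    p_in: float = 0.9
    p_out: float = 0.05
    weight_distribution: str = "uniform"
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 0.5
    seed: int = 0
    surface_subdivisions: int = 2

    def __post_init__(self) -> None:
        if self.n_nodes_per_hemisphere < 1 or 2 * self.n_nodes_per_hemisphere < 2:
            raise ValidationError("need at least one node per hemisphere")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValidationError(
                f"need 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        if self.n_modules < 1:
            raise ValidationError("n_modules must be >= 1")
        if self.weight_distribution not in ("uniform", "lognormal"):
            raise ValidationError(
                f"unknown weight distribution {self.weight_distribution!r}"
            )


@dataclass(frozen=True)
class ToyBrain:
    """A complete synthetic anatomy: meshes, labels, volume, and the
    assembled parcellation with its principled ordering."""

    parcellation: Parcellation
    ordering: Ordering
    surface_lh: SurfaceGeometry
    surface_rh: SurfaceGeometry
    annot_lh: SurfaceAnnotation
    annot_rh: SurfaceAnnotation
    segmentation: SegmentationVolume


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def icosphere(subdivisions: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere mesh: 12 vertices at subdivision 0, 42 at 1, 162 at 2."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = np.add(verts[a], verts[b]) / 2.0
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts), np.array(faces, dtype=np.int64)


def _fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit directions (deterministic)."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    theta = golden * k
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _sweep_order(directions: np.ndarray) -> np.ndarray:
    """Sort by the anterior->dorsal->posterior->ventral sweep angle.

    The sweep starts at the anterior pole (frontal cortex), rises over the
    vertex (parietal), descends the posterior pole (occipital), and returns
    underneath (temporal), which is the principled anatomical ordering used
    for the matrix and circle views.
    """
    alpha = np.mod(np.arctan2(directions[:, 2], directions[:, 1]), 2.0 * np.pi)
    return np.argsort(alpha, kind="stable")


# ---------------------------------------------------------------------------
# Toy brain
# ---------------------------------------------------------------------------


def make_toy_brain(spec: FixtureSpec) -> ToyBrain:
    """Build the synthetic anatomy for ``spec``.

    Produces ``2 * n_nodes_per_hemisphere`` cortical nodes (left hemisphere
    listed first, each hemisphere in sweep order and split into four equal
    lobe groups) plus four subcortical nodes.  The right hemisphere is the
    exact mirror image of the left (x negated), surfaces and annotations
    are mutually consistent, and node centers equal the arithmetic mean of
    each parcel's vertices.
    """
    n = spec.n_nodes_per_hemisphere
    sphere_verts, faces = icosphere(spec.surface_subdivisions)
    if n > len(sphere_verts):
        raise ValidationError(
            f"{n} parcels per hemisphere exceeds the {len(sphere_verts)} surface "
            "vertices; raise surface_subdivisions"
        )

    seeds = _fibonacci_directions(n)
    # nearest-seed parcel assignment on the unit sphere
    assignment = np.argmax(sphere_verts @ seeds.T, axis=1)
    # no parcel may be empty: give each empty parcel its closest vertex,
    # stealing only from parcels that keep at least two vertices
    for parcel in range(n):
        if (assignment == parcel).any():
            continue
        order = np.argsort(-(sphere_verts @ seeds[parcel]))
        for v in order:
            donor = assignment[v]
            if (assignment == donor).sum() >= 2:
                assignment[v] = parcel
                break

    # principled ordering of parcels within the hemisphere
    parcel_order = _sweep_order(seeds)
    lobe_of: dict[int, str] = {}
    for rank, parcel in enumerate(parcel_order):
        lobe_of[int(parcel)] = LOBES[min(rank * len(LOBES) // n, len(LOBES) - 1)]

    lh_verts = sphere_verts * _SEMI_AXES + np.array([-_HEMI_OFFSET, 0.0, 0.0])
    rh_verts = lh_verts * np.array([-1.0, 1.0, 1.0])
    surface_lh = SurfaceGeometry(lh_verts, faces)
    surface_rh = SurfaceGeometry(rh_verts, faces)

    def hemisphere_annot(hemi: str) -> SurfaceAnnotation:
        labels = np.zeros(len(sphere_verts), dtype=np.int64)
        table = {}
        for rank, parcel in enumerate(parcel_order):
            name = f"{hemi}_{lobe_of[int(parcel)]}_{rank + 1}"
            labels[assignment == parcel] = rank + 1
            hue = rank / n
            table[rank + 1] = (name, (0.3 + 0.7 * hue, 0.9 - 0.6 * hue, 0.45))
        return SurfaceAnnotation(labels, table)

    annot_lh = hemisphere_annot("lh")
    annot_rh = hemisphere_annot("rh")

    # segmentation volume: 24^3 voxels, 2 mm isotropic, centered on x=0 so
    # the left/right blobs mirror exactly
    voxels = np.zeros((24, 24, 24), dtype=np.int32)
    lookup: dict[int, str] = {}
    for name, label, (x0, x1), (y0, y1), (z0, z1) in _SUBCORTICAL_BLOBS:
        voxels[x0:x1 + 1, y0:y1 + 1, z0:z1 + 1] = label
        lookup[label] = name
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-23.0, -23.0, -23.0]
    segmentation = SegmentationVolume(voxels, affine, lookup)

    nodes: list[ParcellationNode] = []
    names: list[str] = []
    for hemi, surface, annot in [("lh", surface_lh, annot_lh), ("rh", surface_rh, annot_rh)]:
        centers = parcel_centers(surface, annot)
        for rank, parcel in enumerate(parcel_order):
            name = f"{hemi}_{lobe_of[int(parcel)]}_{rank + 1}"
            group = lobe_of[int(parcel)]
            nodes.append(ParcellationNode(
                name, tuple(centers[name]), hemisphere=hemi,
                group=group, group_color=GROUP_COLORS[group],
            ))
            names.append(name)
    from .io import segmentation_centers

    sub_centers = segmentation_centers(segmentation, [b[0] for b in _SUBCORTICAL_BLOBS])
    for name, *_ in _SUBCORTICAL_BLOBS:
        nodes.append(ParcellationNode(
            name, tuple(sub_centers[name]), hemisphere="subcortical",
            group="subcortical", group_color=GROUP_COLORS["subcortical"],
        ))
        names.append(name)

    return ToyBrain(
        parcellation=Parcellation(tuple(nodes)),
        ordering=Ordering(tuple(names)),
        surface_lh=surface_lh,
        surface_rh=surface_rh,
        annot_lh=annot_lh,
        annot_rh=annot_rh,
        segmentation=segmentation,
    )


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def _draw_weights(rng: np.random.Generator, size: int, spec: FixtureSpec) -> np.ndarray:
    if spec.weight_distribution == "lognormal":
        return rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, size)
    return 1.0 - rng.random(size)  # uniform on (0, 1]


def make_modular_network(
    spec: FixtureSpec, parcellation: Parcellation | None = None
) -> tuple[AdjacencyNetwork, np.ndarray]:
    """Planted-partition network; returns (network, true module labels).

    Nodes are split into ``n_modules`` contiguous blocks; each within-block
    pair is connected with probability ``p_in`` and each between-block pair
    with ``p_out``, with i.i.d. weights from the configured distribution.
    """
    if parcellation is not None:
        names = parcellation.names()
    else:
        names = [f"node_{i + 1}" for i in range(2 * spec.n_nodes_per_hemisphere)]
    n = len(names)
    labels = (np.arange(n) * spec.n_modules) // n
    rng = np.random.default_rng(spec.seed)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(labels[iu] == labels[ju], spec.p_in, spec.p_out)
    present = rng.random(len(iu)) < prob
    weights = _draw_weights(rng, len(iu), spec) * present
    w[iu, ju] = weights
    w[ju, iu] = weights
    return bind_matrix(w, Ordering(tuple(names))), labels


def make_lateral_network(
    parcellation: Parcellation, lateral_boost: float = 2.0, seed: int = 0
) -> AdjacencyNetwork:
    """Distance-decay background plus boosted homologous left/right pairs.

    Emulates the characteristic signature of resting-state fMRI networks:
    the strongest connections sit between mirror-image regions of the two
    hemispheres.  ``lateral_boost`` is added to the weight of each
    homologous pair; at 0 the network is pure distance-decay background.
    """
    names = parcellation.names()
    n = len(names)
    canon = {canonical_name(name): i for i, name in enumerate(names)}
    pairs = []
    for (hemi, base), i in canon.items():
        if hemi == "lh" and ("rh", base) in canon:
            pairs.append((i, canon[("rh", base)]))
    if not pairs:
        raise ValidationError(
            "parcellation has no homologous lh/rh name pairs; a lateral "
            "network requires mirrored hemispheres"
        )
    rng = np.random.default_rng(seed)
    centers = parcellation.centers
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    noise = rng.uniform(0.5, 1.0, size=(n, n))
    noise = (noise + noise.T) / 2.0
    w = np.exp(-d / 40.0) * noise
    np.fill_diagonal(w, 0.0)
    for i, j in pairs:
        w[i, j] += lateral_boost
        w[j, i] += lateral_boost
    return bind_matrix(w, Ordering(tuple(names)))


# ---------------------------------------------------------------------------
# On-disk dataset
# ---------------------------------------------------------------------------


def write_fixture_dataset(out_dir: str | Path, spec: FixtureSpec) -> dict[str, str]:
    """Write a complete toy dataset in the real external file formats.

    Emits FreeSurfer binary + GIFTI surfaces, FreeSurfer annotations, a
    NIFTI segmentation with its JSON label lookup, the ordering file, a
    planted-modular connectivity matrix (text), a coordinate table, and a
    name->group mapping, so the file readers are exercised end-to-end.
    Returns a mapping of dataset component names to paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    brain = make_toy_brain(spec)
    network, labels = make_modular_network(spec, brain.parcellation)

    paths = {
        "ordering": out_dir / "ordering.txt",
        "matrix": out_dir / "matrix.txt",
        "surface_lh": out_dir / "lh.white",
        "surface_rh": out_dir / "rh.white.gii",
        "annot_lh": out_dir / "lh.parcels.annot",
        "annot_rh": out_dir / "rh.parcels.annot",
        "segmentation": out_dir / "aseg.nii.gz",
        "lookup": out_dir / "aseg_lookup.json",
        "groups": out_dir / "groups.json",
        "coords": out_dir / "coords.txt",
        "planted_labels": out_dir / "planted_labels.txt",
    }
    write_ordering(brain.ordering, paths["ordering"])
    np.savetxt(paths["matrix"], network.weights, fmt="%.17g")
    write_surface(brain.surface_lh, paths["surface_lh"])
    write_surface(brain.surface_rh, paths["surface_rh"])
    write_annotation(brain.annot_lh, paths["annot_lh"])
    write_annotation(brain.annot_rh, paths["annot_rh"])
    write_segmentation(brain.segmentation, paths["segmentation"])
    paths["lookup"].write_text(json.dumps(
        {str(k): v for k, v in brain.segmentation.lookup.items()},
        indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["groups"].write_text(json.dumps(
        {node.name: node.group for node in brain.parcellation.nodes},
        indent=2, sort_keys=True) + "\n", encoding="utf-8")
    with paths["coords"].open("w", encoding="utf-8") as fh:
        fh.write("# name x y z hemisphere group\n")
        for node in brain.parcellation.nodes:
            x, y, z = node.center
            fh.write(f"{node.name} {x:.17g} {y:.17g} {z:.17g} "
                     f"{node.hemisphere} {node.group}\n")
    np.savetxt(paths["planted_labels"], labels, fmt="%d")
    return {key: str(path) for key, path in paths.items()}
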