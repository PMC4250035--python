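"""Parcellation and matrix I/O.

A parcellation supplies the spatial embedding of the network: named nodes
with millimetre centers, hemisphere, and an anatomical grouping used for the
color bands of the matrix and circle views.  Three input routes are
supported, mirroring how brain parcellations are distributed in practice:

* **surface parcels** — a cortical surface mesh (FreeSurfer binary or GIFTI)
  plus a per-vertex annotation (FreeSurfer ``.annot`` or GIFTI label file);
  a node's center is the mean of its parcel's vertex coordinates;
* **labeled volumes** — a segmentation image (NIFTI or MGZ) whose integer
  voxel values encode structures, with a label lookup table; used for
  subcortical structures that surface annotations do not cover;
* **coordinate tables** — plain text listing a name and three stereotaxic
  coordinates per row (e.g. EEG electrode positions).

Per-node scalar statistics are written/read as plain n x 1 matrix files so
externally computed metrics can round-trip through the same path.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np

from .core import (
    FormatError,
    NodeScalar,
    Ordering,
    ValidationError,
    canonical_name,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceGeometry",
    "SurfaceAnnotation",
    "SegmentationVolume",
    "ParcellationNode",
    "Parcellation",
    "SUBCORTICAL_LUT",
    "read_surface",
    "write_surface",
    "read_annotation",
    "write_annotation",
    "parcel_centers",
    "segmentation_centers",
    "read_segmentation",
    "write_segmentation",
    "read_coordinate_table",
    "read_scalars",
    "write_scalars",
]

#: Fixed colors for the common anatomical groups; unrecognized group names
#: get a deterministic color hashed from the name.
GROUP_COLORS: dict[str, tuple[float, float, float]] = {
    "frontal": (0.85, 0.30, 0.25),
    "parietal": (0.30, 0.55, 0.85),
    "occipital": (0.50, 0.80, 0.35),
    "temporal": (0.90, 0.70, 0.25),
    "subcortical": (0.60, 0.40, 0.70),
    "lh": (0.35, 0.45, 0.80),
    "rh": (0.80, 0.45, 0.35),
    "unknown": (0.55, 0.55, 0.55),
}


def group_color(group: str) -> tuple[float, float, float]:
    """Stable RGB color for an anatomical group name."""
    if group in GROUP_COLORS:
        return GROUP_COLORS[group]
    import hashlib

    digest = hashlib.md5(group.encode("utf-8")).digest()
    hue = digest[0] / 255.0
    from matplotlib.colors import hsv_to_rgb

    return tuple(float(c) for c in hsv_to_rgb((hue, 0.6, 0.85)))


#: Default lookup of subcortical structure names to segmentation label codes
#: (the standard FreeSurfer ``aseg`` convention).  Config-extendable: any
#: mapping with the same shape may be passed to :func:`read_segmentation`.
SUBCORTICAL_LUT: dict[int, str] = {
    10: "Left-Thalamus-Proper",
    11: "Left-Caudate",
    12: "Left-Putamen",
    13: "Left-Pallidum",
    17: "Left-Hippocampus",
    18: "Left-Amygdala",
    26: "Left-Accumbens-area",
    49: "Right-Thalamus-Proper",
    50: "Right-Caudate",
    51: "Right-Putamen",
    52: "Right-Pallidum",
    53: "Right-Hippocampus",
    54: "Right-Amygdala",
    58: "Right-Accumbens-area",
    16: "Brain-Stem",
}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceGeometry:
    """Triangulated cortical surface: V x 3 mm vertices, F x 3 faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError(f"vertices must be V x 3, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValidationError("surface vertices contain non-finite values")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValidationError("face indices out of vertex range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f.reshape(-1, 3))

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass(frozen=True)
class SurfaceAnnotation:
    """Per-vertex parcel labels plus a label table id -> (name, RGB color).

    Label id 0 is reserved for background/unknown vertices and is excluded
    from parcel statistics.
    """

    vertex_labels: np.ndarray
    label_table: dict[int, tuple[str, tuple[float, float, float]]]

    def __post_init__(self) -> None:
        labels = np.asarray(self.vertex_labels, dtype=np.int64)
        object.__setattr__(self, "vertex_labels", labels)
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValidationError(
                f"vertex labels {sorted(missing)} missing from the label table"
            )

    @property
    def n_vertices(self) -> int:
        return self.vertex_labels.shape[0]

    def parcel_names(self) -> list[str]:
        return [self.label_table[k][0] for k in sorted(self.label_table) if k != 0]


@dataclass(frozen=True)
class SegmentationVolume:
    """3-D integer label volume with an index->mm affine and a name lookup."""

    voxels: np.ndarray
    affine: np.ndarray
    lookup: Mapping[int, str]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        aff = np.asarray(self.affine, dtype=float)
        if vox.ndim != 3:
            raise ValidationError(f"segmentation volume must be 3-D, got {vox.ndim}-D")
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValidationError("segmentation affine must be an invertible 4x4 matrix")
        for key in self.lookup:
            if not (isinstance(key, (int, np.integer)) and key > 0):
                raise ValidationError(f"lookup keys must be positive integers, got {key!r}")
        object.__setattr__(self, "voxels", vox.astype(np.int32))
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "lookup", dict(self.lookup))


@dataclass(frozen=True)
class ParcellationNode:
    name: str
    center: tuple[float, float, float]
    hemisphere: str = "unknown"  # lh | rh | subcortical | unknown
    group: str = "unknown"
    group_color: tuple[float, float, float] = (0.5, 0.5, 0.5)


@dataclass(frozen=True)
class Parcellation:
    """Named nodes with 3-D mm centers: the network's spatial embedding."""

    nodes: tuple[ParcellationNode, ...]

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        object.__setattr__(self, "nodes", nodes)
        seen: dict[tuple[str, str], str] = {}
        for node in nodes:
            if not np.isfinite(node.center).all():
                raise ValidationError(f"node {node.name!r} has a non-finite center")
            key = canonical_name(node.name)
            if key in seen:
                raise ValidationError(
                    f"nodes {seen[key]!r} and {node.name!r} share canonical name {key}"
                )
            seen[key] = node.name

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def centers(self) -> np.ndarray:
        return np.array([n.center for n in self.nodes], dtype=float)

    def names(self) -> list[str]:
        return [n.name for n in self.nodes]


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------


def read_surface(path: str | Path) -> SurfaceGeometry:
    """Read a surface mesh from FreeSurfer binary or GIFTI format."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"surface file {path} does not exist")
    if path.suffix.lower() == ".gii":
        try:
            img = nib.load(str(path))
            vertices = faces = None
            for darray in img.darrays:
                if darray.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                    vertices = np.asarray(darray.data, dtype=float)
                elif darray.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                    faces = np.asarray(darray.data, dtype=np.int64)
            if vertices is None or faces is None:
                raise FormatError(
                    f"{path}: GIFTI file lacks pointset/triangle arrays"
                )
            return SurfaceGeometry(vertices, faces)
        except FormatError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise FormatError(
                f"{path}: unreadable surface; accepted formats are FreeSurfer "
                f"binary surface and GIFTI (.gii): {exc}"
            ) from exc
    try:
        vertices, faces = nib.freesurfer.read_geometry(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(
            f"{path}: unreadable surface; accepted formats are FreeSurfer "
            f"binary surface and GIFTI (.gii): {exc}"
        ) from exc
    return SurfaceGeometry(np.asarray(vertices, dtype=float), np.asarray(faces))


def write_surface(surface: SurfaceGeometry, path: str | Path) -> None:
    """Write a surface as FreeSurfer binary or GIFTI, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() == ".gii":
        coords = nib.gifti.GiftiDataArray(
            surface.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
        tris = nib.gifti.GiftiDataArray(
            surface.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))
    else:
        nib.freesurfer.write_geometry(str(path), surface.vertices, surface.faces)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> SurfaceAnnotation:
    """Read a surface parcellation from FreeSurfer ``.annot`` or GIFTI label."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file {path} does not exist")
    if path.suffix.lower() == ".gii":
        try:
            img = nib.load(str(path))
            darray = img.darrays[0]
            labels = np.asarray(darray.data, dtype=np.int64)
            table: dict[int, tuple[str, tuple[float, float, float]]] = {}
            for lab in img.labeltable.labels:
                if lab.key == 0:
                    continue
                table[int(lab.key)] = (lab.label, (lab.red, lab.green, lab.blue))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(
                f"{path}: unreadable annotation; accepted formats are FreeSurfer "
                f".annot and GIFTI label (.gii): {exc}"
            ) from exc
    else:
        try:
            indices, ctab, names = nib.freesurfer.read_annot(str(path))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(
                f"{path}: unreadable annotation; accepted formats are FreeSurfer "
                f".annot and GIFTI label (.gii): {exc}"
            ) from exc
        labels = np.zeros(len(indices), dtype=np.int64)
        table = {}
        next_id = 1
        for row, raw_name in enumerate(names):
            name = raw_name.decode() if isinstance(raw_name, bytes) else str(raw_name)
            rgb = tuple(float(c) / 255.0 for c in ctab[row, :3])
            if name.lower() in ("unknown", "???", "background", "none"):
                # background parcel: keep label 0
                continue
            labels[indices == row] = next_id
            table[next_id] = (name, rgb)
            next_id += 1
    annot = SurfaceAnnotation(labels, table)
    if not table or not (labels != 0).any():
        logger.warning("%s: annotation assigns every vertex to the background", path)
    return annot


def write_annotation(annot: SurfaceAnnotation, path: str | Path) -> None:
    """Write an annotation as FreeSurfer ``.annot`` (background id becomes
    the 'unknown' entry)."""
    keys = sorted(annot.label_table)
    names = ["unknown"] + [annot.label_table[k][0] for k in keys]
    rgb = np.zeros((len(names), 3), dtype=np.int64)
    for row, key in enumerate(keys, start=1):
        rgb[row] = [int(round(c * 255)) for c in annot.label_table[key][1]]
    # ensure distinct colors: FreeSurfer identifies parcels by packed RGB
    packed = set()
    for row in range(len(names)):
        while tuple(rgb[row]) in packed:
            rgb[row, 2] = (rgb[row, 2] + 1) % 256
        packed.add(tuple(rgb[row]))
    ctab = np.hstack([rgb, np.zeros((len(names), 1), dtype=np.int64)])
    indices = np.zeros(annot.n_vertices, dtype=np.int64)
    for row, key in enumerate(keys, start=1):
        indices[annot.vertex_labels == key] = row
    nib.freesurfer.write_annot(str(path), indices.astype(np.int32), ctab, names)


def pair_surface_annotation(
    surface: SurfaceGeometry, annot: SurfaceAnnotation
) -> None:
    if surface.n_vertices != annot.n_vertices:
        raise ValidationError(
            f"surface has {surface.n_vertices} vertices but annotation covers "
            f"{annot.n_vertices}"
        )


def parcel_centers(
    surface: SurfaceGeometry,
    annot: SurfaceAnnotation,
    nearest_vertex: bool = False,
) -> dict[str, np.ndarray]:
    """Center of each surface parcel.

    The center is the arithmetic mean of the parcel's vertex coordinates;
    with ``nearest_vertex`` the member vertex closest to that mean is used
    instead (keeps centers on the mesh for deeply folded parcels).
    Background vertices (label 0) and empty parcels are excluded.
    """
    pair_surface_annotation(surface, annot)
    centers: dict[str, np.ndarray] = {}
    for key in sorted(annot.label_table):
        if key == 0:
            continue
        name = annot.label_table[key][0]
        member = annot.vertex_labels == key
        if not member.any():
            logger.warning("parcel %r has no vertices; excluded", name)
            continue
        pts = surface.vertices[member]
        mean = pts.mean(axis=0)
        if nearest_vertex:
            mean = pts[np.argmin(((pts - mean) ** 2).sum(axis=1))]
        centers[name] = mean
    return centers


# ---------------------------------------------------------------------------
# Segmentation volumes
# ---------------------------------------------------------------------------


def read_segmentation(
    path: str | Path, lookup: Mapping[int, str] | None = None
) -> SegmentationVolume:
    """Read a labeled segmentation volume (NIFTI ``.nii``/``.nii.gz`` or MGZ).

    ``lookup`` maps label codes to structure names; by default the standard
    FreeSurfer aseg subcortical codes are used.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"segmentation file {path} does not exist")
    try:
        img = nib.load(str(path))
        voxels = np.asarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(
            f"{path}: unreadable volume; accepted formats are NIFTI "
            f"(.nii/.nii.gz) and MGZ: {exc}"
        ) from exc
    if voxels.ndim != 3:
        raise FormatError(f"{path}: segmentation must be 3-D, got {voxels.ndim}-D")
    return SegmentationVolume(
        np.rint(voxels).astype(np.int32),
        np.asarray(img.affine, dtype=float),
        dict(lookup) if lookup is not None else dict(SUBCORTICAL_LUT),
    )


def write_segmentation(seg: SegmentationVolume, path: str | Path) -> None:
    """Write the label volume as NIFTI or MGZ, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() == ".mgz":
        img = nib.MGHImage(seg.voxels.astype(np.int32), seg.affine)
    else:
        img = nib.Nifti1Image(seg.voxels.astype(np.int32), seg.affine)
    nib.save(img, str(path))


def segmentation_centers(
    seg: SegmentationVolume, wanted: Iterable[str]
) -> dict[str, np.ndarray]:
    """Centroid (mm) of each wanted structure in a segmentation volume.

    The centroid of the voxel *indices* carrying the structure's label is
    mapped through the affine.  Voxel-center convention: index ``i`` maps
    through the affine as coordinate ``i`` with no half-voxel shift.
    Structures absent from the volume are omitted with a warning.
    """
    by_name = {name: code for code, name in seg.lookup.items()}
    centers: dict[str, np.ndarray] = {}
    for name in wanted:
        if name not in by_name:
            raise ValidationError(
                f"structure {name!r} is not in the segmentation lookup table"
            )
        idx = np.argwhere(seg.voxels == by_name[name])
        if len(idx) == 0:
            logger.warning("structure %r absent from the segmentation volume", name)
            continue
        centroid = idx.mean(axis=0)
        homo = np.append(centroid, 1.0)
        centers[name] = (seg.affine @ homo)[:3]
    return centers


# ---------------------------------------------------------------------------
# Coordinate tables
# ---------------------------------------------------------------------------


def read_coordinate_table(path: str | Path) -> Parcellation:
    """Read a parcellation from a delimited text table.

    Each row: ``name x y z`` with optional trailing ``hemisphere`` and
    ``group`` columns.  Whitespace- or comma-delimited; ``#`` comments and
    blank lines are skipped.
    """
    path = Path(path)
    nodes = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f for f in re.split(r"[,\s]+", line) if f]
        if len(fields) < 4:
            raise FormatError(
                f"{path}:{lineno}: expected 'name x y z', got {len(fields)} field(s)"
            )
        name = fields[0]
        try:
            x, y, z = (float(v) for v in fields[1:4])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric coordinate in {fields[1:4]}"
            ) from None
        hemi = fields[4] if len(fields) > 4 else canonical_name(name)[0] or "unknown"
        group = fields[5] if len(fields) > 5 else (hemi if hemi != "unknown" else "unknown")
        nodes.append(ParcellationNode(name, (x, y, z), hemisphere=hemi, group=group))
    if not nodes:
        raise FormatError(f"{path}: coordinate table contains no rows")
    return Parcellation(tuple(nodes))


def parcellation_from_coords(ordering: Ordering, coords: np.ndarray) -> Parcellation:
    """Pair an n x 3 coordinate matrix with an n-name ordering by rank."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(ordering), 3):
        raise ValidationError(
            f"coordinate matrix is {coords.shape} but ordering has "
            f"{len(ordering)} names (need ({len(ordering)}, 3))"
        )
    nodes = []
    for name, xyz in zip(ordering.names, coords):
        hemi = canonical_name(name)[0] or "unknown"
        nodes.append(
            ParcellationNode(name, tuple(xyz), hemisphere=hemi,
                             group=hemi if hemi != "unknown" else "unknown")
        )
    return Parcellation(tuple(nodes))


# ---------------------------------------------------------------------------
# Scalar round-trip
# ---------------------------------------------------------------------------

_SCALAR_FORMATS = ("txt", "npy", "mat")


def write_scalars(scalars: NodeScalar, path: str | Path, format: str | None = None) -> None:
    """Write a per-node scalar vector as an n x 1 matrix file.

    Formats: plain text (one value per line, full double precision),
    ``.npy``, or MATLAB ``.mat``.  Chosen by extension when not given.
    """
    path = Path(path)
    fmt = format or {".npy": "npy", ".mat": "mat"}.get(path.suffix.lower(), "txt")
    if fmt not in _SCALAR_FORMATS:
        raise ValidationError(
            f"unsupported scalar format {fmt!r}; supported: {', '.join(_SCALAR_FORMATS)}"
        )
    column = scalars.values.reshape(-1, 1)
    if fmt == "npy":
        np.save(path, column)
    elif fmt == "mat":
        import scipy.io

        var = re.sub(r"\W", "_", scalars.name) or "scalar"
        scipy.io.savemat(path, {var: column})
    else:
        path.write_text(
            "".join(f"{v:.17g}\n" for v in scalars.values), encoding="utf-8"
        )


def read_scalars(
    path: str | Path, name: str | None = None, expected_length: int | None = None
) -> NodeScalar:
    """Read a per-node scalar vector written by :func:`write_scalars` (or an
    externally produced n x 1 matrix file)."""
    from .core import load_matrix

    path = Path(path)
    arr = load_matrix(path)
    if 1 not in arr.shape and arr.ndim == 2 and min(arr.shape) != 1:
        raise FormatError(f"{path}: scalar file must be n x 1, got {arr.shape}")
    values = arr.ravel()
    if expected_length is not None and len(values) != expected_length:
        raise ValidationError(
            f"{path}: scalar has {len(values)} values but the network has "
            f"{expected_length} nodes"
        )
    return NodeScalar(values, name or path.stem)


# ---------------------------------------------------------------------------
# Parcellation assembly
# ---------------------------------------------------------------------------


def assemble_parcellation(
    ordering: Ordering,
    surface_centers: Mapping[str, np.ndarray] | None = None,
    segmentation: SegmentationVolume | None = None,
    registration=None,
    groups: Mapping[str, str] | None = None,
) -> Parcellation:
    """Build the parcellation for an ordering from loaded inputs.

    Each ordering name is resolved, exact match first and canonical
    (hemisphere-prefix/suffix, case-insensitive) match second, against the
    surface parcel centers; names recognized by the segmentation lookup
    table resolve to the corresponding structure centroid instead, mapped
    through ``registration`` (volume -> anatomical space) when given.
    ``groups`` maps node names to anatomical groups; nodes without an entry
    default to their hemisphere.
    """
    from .core import apply_registration

    surface_centers = dict(surface_centers or {})
    canon_surface: dict[tuple[str, str], list[str]] = {}
    for name in surface_centers:
        canon_surface.setdefault(canonical_name(name), []).append(name)

    seg_centers: dict[tuple[str, str], np.ndarray] = {}
    if segmentation is not None:
        wanted = [n for n in segmentation.lookup.values()]
        for name, center in segmentation_centers(segmentation, wanted).items():
            if registration is not None:
                center = apply_registration(center[None, :], registration)[0]
            seg_centers[canonical_name(name)] = center

    groups = dict(groups or {})
    canon_groups = {canonical_name(k): v for k, v in groups.items()}

    nodes: list[ParcellationNode] = []
    unmatched: list[str] = []
    for name in ordering.names:
        key = canonical_name(name)
        hemi = key[0] or "unknown"
        if name in surface_centers:
            center, kind = surface_centers[name], "cortical"
        elif key in seg_centers:
            center, kind, hemi = seg_centers[key], "subcortical", "subcortical"
        elif key in canon_surface:
            candidates = canon_surface[key]
            if len(candidates) > 1:
                raise ValidationError(
                    f"ordering name {name!r} matches multiple parcels: {candidates}"
                )
            center, kind = surface_centers[candidates[0]], "cortical"
        else:
            unmatched.append(name)
            continue
        group = groups.get(name) or canon_groups.get(key) or (
            "subcortical" if kind == "subcortical" else hemi
        )
        nodes.append(ParcellationNode(
            name, tuple(np.asarray(center, dtype=float)), hemisphere=hemi,
            group=group, group_color=group_color(group),
        ))
    if unmatched:
        raise ValidationError(
            f"{len(unmatched)} ordering name(s) matched neither the surface "
            f"parcellation nor the segmentation lookup: {unmatched}"
        )
    return Parcellation(tuple(nodes))


def align_parcellation(ordering: Ordering, parcellation: Parcellation) -> Parcellation:
    """Reorder (and rename to the ordering's spelling) an arbitrary
    parcellation so node *k* corresponds to ordering name *k*."""
    from .core import match_nodes

    mapping = match_nodes(ordering, parcellation)
    nodes = []
    for oi, name in enumerate(ordering.names):
        src = parcellation.nodes[mapping[oi]]
        nodes.append(ParcellationNode(
            name, src.center, hemisphere=src.hemisphere,
            group=src.group, group_color=src.group_color,
        ))
    return Parcellation(tuple(nodes))
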