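"""Atlas bundles: structure hierarchy, annotation volume, region meshes.

An atlas bundle is a directory::

    structures.json    # records with id / acronym / name / parent_id / rgb
    annotation.tiff    # 3D unsigned-integer stack, voxel value = structure id
    metadata.json      # {"name": ..., "resolution": [um, um, um]}
    meshes/            # optional <acronym>.obj region surfaces

Axis order is fixed to (AP, DV, LR) matching voxel indices (i, j, k); all
physical coordinates are micrometers; a point maps to the voxel
``floor(coordinate / resolution)`` per axis, so a point exactly on a voxel
boundary belongs to the higher-index voxel.

The annotation labels leaf structures only (as in real atlases, where a
parent region is the union of its children); membership in a parent is
always resolved through the hierarchy.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import trimesh

from .errors import AtlasLoadError, AtlasValidationError, EmptyRegionError, StructureLookupError
from .geometry import label_isosurface
from .io import read_mesh

__all__ = [
    "StructureNode",
    "AnnotationVolume",
    "Atlas",
    "load_atlas",
    "OUTSIDE",
]

#: Sentinel returned by spatial queries for points outside the brain.
OUTSIDE = None


@dataclass(frozen=True)
class StructureNode:
    """One node of the structure hierarchy."""

    id: int
    acronym: str
    name: str
    parent_id: int | None
    rgb: tuple[int, int, int]
    mesh_available: bool = False

    def __post_init__(self):
        if self.id <= 0:
            raise AtlasValidationError(f"structure id must be positive, got {self.id}")
        rgb = tuple(int(v) for v in self.rgb)
        if len(rgb) != 3 or not all(0 <= v <= 255 for v in rgb):
            raise AtlasValidationError(f"{self.acronym}: rgb must be three 0-255 ints")
        object.__setattr__(self, "rgb", rgb)


@dataclass
class AnnotationVolume:
    """The 3D label grid: voxel value = structure id, 0 = outside the brain."""

    labels: np.ndarray
    resolution: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise AtlasValidationError("annotation volume must be 3D")
        self.resolution = np.broadcast_to(
            np.asarray(self.resolution, dtype=float), (3,)
        ).copy()
        if not (self.resolution > 0).all():
            raise AtlasValidationError("resolution must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent_um(self) -> np.ndarray:
        """Physical size of the grid per axis, micrometers."""
        return np.asarray(self.labels.shape) * self.resolution

    def voxel_index(self, point) -> tuple[int, int, int] | None:
        """Map a micrometer point to its voxel index (floor convention), or
        None when off-grid."""
        idx = np.floor(np.asarray(point, dtype=float) / self.resolution).astype(int)
        if (idx < 0).any() or (idx >= self.labels.shape).any():
            return None
        return tuple(int(v) for v in idx)

    def label_at(self, point) -> int:
        """Label at a micrometer point; 0 for off-grid points."""
        idx = self.voxel_index(point)
        if idx is None:
            return 0
        return int(self.labels[idx])


class Atlas:
    """A loaded atlas: hierarchy plus annotation plus region mesh store.

    Use :func:`load_atlas` to construct one from a bundle directory; the
    constructor itself validates every structural invariant (unique
    ids/acronyms, single root, acyclic parent links, annotation labels known
    to the tree).
    """

    def __init__(
        self,
        name: str,
        nodes: list[StructureNode],
        annotation: AnnotationVolume,
        mesh_store: dict[str, Path] | None = None,
    ):
        self.name = name
        self.nodes = list(nodes)
        self.annotation = annotation
        self.mesh_store = dict(mesh_store or {})
        self._mesh_cache: dict[str, trimesh.Trimesh] = {}
        self._by_id = {n.id: n for n in self.nodes}
        self._by_acronym = {n.acronym: n for n in self.nodes}
        self._validate()
        self._children: dict[int, list[StructureNode]] = {}
        for n in self.nodes:
            if n.parent_id is not None:
                self._children.setdefault(n.parent_id, []).append(n)

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if len(self._by_id) != len(self.nodes):
            raise AtlasValidationError("duplicate structure ids")
        if len(self._by_acronym) != len(self.nodes):
            raise AtlasValidationError("duplicate structure acronyms")
        roots = [n for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise AtlasValidationError(
                f"atlas must have exactly one root, found {len(roots)}"
            )
        self._root = roots[0]
        # parent links resolve and terminate at the root (no cycles)
        for n in self.nodes:
            seen = {n.id}
            cur = n
            while cur.parent_id is not None:
                if cur.parent_id not in self._by_id:
                    raise AtlasValidationError(
                        f"{cur.acronym}: parent id {cur.parent_id} unknown"
                    )
                cur = self._by_id[cur.parent_id]
                if cur.id in seen:
                    raise AtlasValidationError(
                        f"hierarchy cycle through structure {cur.acronym}"
                    )
                seen.add(cur.id)
        labels = np.unique(self.annotation.labels)
        unknown = [int(v) for v in labels if v != 0 and int(v) not in self._by_id]
        if unknown:
            raise AtlasValidationError(
                f"annotation labels {unknown} missing from the structure tree"
            )

    def check_mesh_bounds(self) -> None:
        """Stored region meshes must fit the annotation's physical bounding
        box within one voxel."""
        tol = self.annotation.resolution
        hi = self.annotation.extent_um
        for acronym in self.mesh_store:
            mesh = self.region_mesh(acronym)
            if (mesh.bounds[0] < -tol).any() or (mesh.bounds[1] > hi + tol).any():
                raise AtlasValidationError(
                    f"mesh for {acronym} exceeds the annotation bounding box"
                )

    # -- hierarchy ----------------------------------------------------------

    @property
    def root(self) -> StructureNode:
        return self._root

    @property
    def root_acronym(self) -> str:
        return self._root.acronym

    def __len__(self) -> int:
        return len(self.nodes)

    def get_structure(self, key) -> StructureNode:
        """Look a structure up by acronym (str) or id (int)."""
        if isinstance(key, (int, np.integer)):
            node = self._by_id.get(int(key))
            if node is None:
                raise StructureLookupError(f"no structure with id {int(key)}")
            return node
        node = self._by_acronym.get(key)
        if node is None:
            suggestions = difflib.get_close_matches(
                str(key), self._by_acronym.keys(), n=3, cutoff=0.3
            )
            hint = f" (did you mean: {', '.join(suggestions)}?)" if suggestions else ""
            raise StructureLookupError(
                f"no structure with acronym {key!r}{hint}", suggestions
            )
        return node

    def ancestors(self, acronym: str) -> list[StructureNode]:
        """Chain from the immediate parent up to the root; empty for the
        root itself."""
        node = self.get_structure(acronym)
        out = []
        while node.parent_id is not None:
            node = self._by_id[node.parent_id]
            out.append(node)
        return out

    def descendants(self, acronym: str) -> list[StructureNode]:
        """Every structure below the query node (the node itself excluded),
        in depth-first order."""
        node = self.get_structure(acronym)
        out: list[StructureNode] = []
        stack = list(self._children.get(node.id, []))
        while stack:
            n = stack.pop(0)
            out.append(n)
            stack = list(self._children.get(n.id, [])) + stack
        return out

    # -- spatial queries ----------------------------------------------------

    def structure_from_point(self, point) -> StructureNode | None:
        """The structure whose voxel contains the point, or :data:`OUTSIDE`
        (None) for label 0 or off-grid points."""
        label = self.annotation.label_at(point)
        if label == 0:
            return OUTSIDE
        return self._by_id[label]

    def point_in_region(
        self, point, acronym: str, include_substructures: bool = True
    ) -> bool:
        """True if the point's structure is the region (or, with
        ``include_substructures``, any of its descendants)."""
        target = self.get_structure(acronym)
        node = self.structure_from_point(point)
        if node is OUTSIDE:
            return False
        if node.id == target.id:
            return True
        if not include_substructures:
            return False
        return any(a.id == target.id for a in self.ancestors(node.acronym))

    # -- meshes -------------------------------------------------------------

    def region_ids(self, acronym: str) -> list[int]:
        """The region's own id plus all descendant ids (annotation labels
        belonging to the region)."""
        node = self.get_structure(acronym)
        return [node.id] + [d.id for d in self.descendants(acronym)]

    def region_mesh(self, acronym: str) -> trimesh.Trimesh:
        """The region's surface mesh, from the mesh store when available,
        otherwise isosurfaced from the annotation (own id union descendant
        ids). Results are cached until the atlas is reloaded."""
        node = self.get_structure(acronym)
        if node.acronym in self._mesh_cache:
            return self._mesh_cache[node.acronym]
        if node.acronym in self.mesh_store:
            mesh = read_mesh(self.mesh_store[node.acronym])
        else:
            ids = self.region_ids(acronym)
            mask = np.isin(self.annotation.labels, ids)
            if not mask.any():
                raise EmptyRegionError(
                    f"{acronym}: no stored mesh and no labeled voxels"
                )
            mesh = label_isosurface(
                mask, resolution=self.annotation.resolution
            )
        self._mesh_cache[node.acronym] = mesh
        return mesh


# ---------------------------------------------------------------------------


def load_atlas(path, check_meshes: bool = True) -> Atlas:
    """Load and validate an atlas bundle directory.

    Raises :class:`AtlasLoadError` naming any missing file, and
    :class:`AtlasValidationError` for structural problems (duplicate
    ids/acronyms, hierarchy cycles, unknown annotation labels).
    """
    path = Path(path)
    if not path.is_dir():
        raise AtlasLoadError(f"atlas directory not found: {path}")
    required = ["structures.json", "annotation.tiff", "metadata.json"]
    for fname in required:
        if not (path / fname).exists():
            raise AtlasLoadError(f"atlas bundle is missing required file: {fname}")

    with open(path / "metadata.json") as fh:
        meta = json.load(fh)
    if "resolution" not in meta:
        raise AtlasLoadError("metadata.json has no 'resolution' entry")

    with open(path / "structures.json") as fh:
        records = json.load(fh)
    nodes = [
        StructureNode(
            id=int(r["id"]),
            acronym=r["acronym"],
            name=r.get("name", r["acronym"]),
            parent_id=None if r.get("parent_id") is None else int(r["parent_id"]),
            rgb=tuple(r.get("rgb", (128, 128, 128))),
        )
        for r in records
    ]

    labels = tifffile.imread(path / "annotation.tiff")
    annotation = AnnotationVolume(labels, meta["resolution"])

    mesh_dir = path / "meshes"
    mesh_store: dict[str, Path] = {}
    if mesh_dir.is_dir():
        acronyms = {n.acronym for n in nodes}
        for f in sorted(mesh_dir.glob("*.obj")):
            if f.stem in acronyms:
                mesh_store[f.stem] = f
    nodes = [
        StructureNode(
            n.id, n.acronym, n.name, n.parent_id, n.rgb,
            mesh_available=n.acronym in mesh_store,
        )
        for n in nodes
    ]

    atlas = Atlas(meta.get("name", path.name), nodes, annotation, mesh_store)
    if check_meshes:
        atlas.check_mesh_bounds()
    return atlas
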