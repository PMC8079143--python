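"""Synthetic datasets with known ground truth.

Everything the loaders read can be generated here: a miniature atlas bundle,
labeled-cell coordinate sets, SWC neuron morphologies, streamline JSON
files, and volumetric expression images. The generators exist so the whole
library is exercisable end to end without downloading real atlases; they
write the exact on-disk formats the loaders consume.

The mini atlas is deliberately simple: a big root ellipsoid containing
bilaterally symmetric pairs of ellipsoidal leaf regions (each structure is
its own left-right mirror partner), with the hierarchy
root -> {CTX -> {VISp, MOs}, TH}. Ellipsoids are used so analytic volumes
and centroids exist for geometry tests. The annotation labels leaves only;
parent membership resolves through the tree, as in real atlases.

All randomness flows from one seeded generator per call; same seed, same
bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .atlas import Atlas, load_atlas
from .errors import EmptyRegionError, FixtureGenerationError
from .geometry import label_isosurface
from .io import NeuronMorphology, PointsData, Streamlines, write_mesh, write_streamlines, write_swc

__all__ = [
    "FixtureSpec",
    "make_mini_atlas",
    "make_synthetic_cells",
    "make_synthetic_neuron",
    "make_synthetic_streamlines",
    "make_expression_volume",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults: a 40 x 30 x 48 voxel grid at 25 um (a 1 x 0.75 x 1.2 mm
    "brain"), 3 leaf regions, 1000 cells, 8 streamline paths.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (40, 30, 48)
    resolution: float = 25.0
    n_regions: int = 3
    n_cells: int = 1000
    n_paths: int = 8

    def __post_init__(self):
        if min(self.grid_shape) < 8:
            raise FixtureGenerationError("grid_shape components must be >= 8")
        if self.n_regions < 1 or self.n_cells < 0 or self.n_paths < 0:
            raise FixtureGenerationError("counts must be positive")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside an ellipsoid given in
    voxel units (voxel i has center i + 0.5)."""
    idx = np.indices(shape).astype(float) + 0.5
    c = np.asarray(center, dtype=float).reshape(3, 1, 1, 1)
    r = np.asarray(radii, dtype=float).reshape(3, 1, 1, 1)
    return (((idx - c) / r) ** 2).sum(axis=0) <= 1.0


def _mirrored(mask: np.ndarray) -> np.ndarray:
    """Union of a mask with its left-right mirror (exact symmetry about the
    mid-sagittal plane)."""
    return mask | mask[:, :, ::-1]


# leaf placement slots, in fractions of the grid; ids are fixed per slot
# (root=1, CTX=2) so e.g. VISp is always structure 4 regardless of n_regions
_LEAF_SLOTS = [
    # id, acronym, name, parent, AP frac, DV frac, LR offset frac, radii frac
    (4, "VISp", "Primary visual area", "CTX", 0.30, 0.35, 0.18, (0.10, 0.13, 0.085)),
    (5, "MOs", "Secondary motor area", "CTX", 0.68, 0.35, 0.18, (0.10, 0.13, 0.085)),
    (3, "TH", "Thalamus", "root", 0.49, 0.62, 0.11, (0.08, 0.10, 0.065)),
    (6, "SSp", "Primary somatosensory area", "CTX", 0.49, 0.30, 0.27, (0.06, 0.08, 0.05)),
    (7, "RSP", "Retrosplenial area", "CTX", 0.18, 0.58, 0.09, (0.055, 0.08, 0.045)),
    (8, "ACA", "Anterior cingulate area", "CTX", 0.82, 0.58, 0.09, (0.055, 0.08, 0.045)),
]


def make_mini_atlas(spec: FixtureSpec = FixtureSpec(), out_dir=None) -> Path:
    """Write a complete synthetic atlas bundle and return its directory.

    The bundle contains structures.json, annotation.tiff (leaf labels only),
    metadata.json, and meshes/<acronym>.obj for every structure (parent
    meshes are isosurfaces of their leaf-union masks; the root mesh is the
    isosurface of the root ellipsoid). The annotation is exactly
    left-right mirror symmetric. Deterministic: same spec, same bytes.
    """
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)
    if spec.n_regions > len(_LEAF_SLOTS):
        raise FixtureGenerationError(
            f"cannot place {spec.n_regions} non-overlapping regions; "
            f"use n_regions <= {len(_LEAF_SLOTS)}"
        )
    shape = tuple(spec.grid_shape)
    g = np.asarray(shape, dtype=float)

    root_mask = _mirrored(
        _ellipsoid_mask(shape, g / 2, (0.43 * g[0], 0.41 * g[1], 0.44 * g[2]))
    )

    leaf_masks: dict[str, np.ndarray] = {}
    records = [
        {"id": 1, "acronym": "root", "name": "root", "parent_id": None, "rgb": [220, 220, 220]},
        {"id": 2, "acronym": "CTX", "name": "Cerebral cortex", "parent_id": 1, "rgb": [31, 157, 90]},
    ]
    rgb_cycle = [
        [0, 128, 255], [255, 64, 64], [255, 180, 0], [160, 64, 200],
        [0, 180, 160], [200, 120, 60],
    ]
    parents = {}
    for k in range(spec.n_regions):
        sid, acronym, name, parent, ap, dv, lr_off, rad = _LEAF_SLOTS[k]
        center = (ap * g[0], dv * g[1], g[2] / 2 + lr_off * g[2])
        radii = (rad[0] * g[0], rad[1] * g[1], rad[2] * g[2])
        mask = _mirrored(_ellipsoid_mask(shape, center, radii))
        if not mask.any():
            raise FixtureGenerationError(f"region {acronym} has no voxels at this grid size")
        if (mask & ~root_mask).any():
            raise FixtureGenerationError(
                f"region {acronym} does not fit inside the root; use a larger grid"
            )
        for other, omask in leaf_masks.items():
            if (mask & omask).any():
                raise FixtureGenerationError(
                    f"regions {acronym} and {other} overlap; use smaller n_regions"
                )
        leaf_masks[acronym] = mask
        parent_id = 1 if parent == "root" else 2
        parents[acronym] = parent
        records.append(
            {"id": sid, "acronym": acronym, "name": name,
             "parent_id": parent_id, "rgb": rgb_cycle[k % len(rgb_cycle)]}
        )

    annotation = np.zeros(shape, dtype=np.uint16)
    for rec in records[2:]:
        annotation[leaf_masks[rec["acronym"]]] = rec["id"]

    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "structures.json", "w") as fh:
        json.dump(records, fh, indent=1)
    tifffile.imwrite(out_dir / "annotation.tiff", annotation)
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(
            {"name": "synthetic-mini-atlas", "resolution": [spec.resolution] * 3},
            fh,
        )
    mesh_dir = out_dir / "meshes"
    mesh_dir.mkdir(exist_ok=True)
    res = spec.resolution
    write_mesh(label_isosurface(root_mask, resolution=res), mesh_dir / "root.obj")
    ctx_leaves = [a for a in leaf_masks if parents[a] == "CTX"]
    if ctx_leaves:
        ctx_mask = np.any([leaf_masks[a] for a in ctx_leaves], axis=0)
        write_mesh(label_isosurface(ctx_mask, resolution=res), mesh_dir / "CTX.obj")
    for acronym, mask in leaf_masks.items():
        write_mesh(label_isosurface(mask, resolution=res), mesh_dir / f"{acronym}.obj")
    return out_dir


def make_synthetic_cells(atlas: Atlas, acronym: str, n: int, seed: int = 0) -> PointsData:
    """Sample ``n`` cell coordinates uniformly inside a region's voxel mask.

    Every returned point satisfies
    ``atlas.point_in_region(p, acronym, include_substructures=True)`` by
    construction: a labeled voxel is drawn uniformly, then a uniform
    position within that voxel.
    """
    ids = atlas.region_ids(acronym)
    voxels = np.argwhere(np.isin(atlas.annotation.labels, ids))
    if len(voxels) == 0:
        raise EmptyRegionError(f"{acronym}: region has no labeled voxels")
    rng = np.random.default_rng(seed)
    if n == 0:
        return PointsData(np.zeros((0, 3)))
    picks = voxels[rng.integers(0, len(voxels), size=n)]
    offsets = rng.random((n, 3))
    coords = (picks + offsets) * atlas.annotation.resolution
    return PointsData(coords)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_synthetic_neuron(
    out_path,
    seed: int = 0,
    n_branch_points: int = 3,
    soma_position=(0.0, 0.0, 0.0),
    segment_length: float = 12.0,
) -> Path:
    """Write a random binary-branching neuron as an SWC file.

    The tree has one soma sample (type 1) with a single primary neurite;
    each branch event converts one growing tip into a bifurcation, so the
    parsed tree has exactly ``n_branch_points`` branch points (non-soma
    samples with two children). ``n_branch_points=0`` yields an unbranched
    neurite.
    """
    rng = np.random.default_rng(seed)
    soma_position = np.asarray(soma_position, dtype=float)
    ids = [1]
    types = [1]
    positions = [soma_position]
    radii = [6.0]
    parents = [-1]
    next_id = 2
    pos_of = {1: soma_position}

    def extend(tip: int, direction: np.ndarray, steps: int, tcode: int) -> tuple[int, np.ndarray]:
        nonlocal next_id
        for _ in range(steps):
            direction = _unit(direction + rng.normal(0.0, 0.25, 3))
            p = pos_of[tip] + direction * segment_length
            ids.append(next_id)
            types.append(tcode)
            positions.append(p)
            radii.append(1.0)
            parents.append(tip)
            pos_of[next_id] = p
            tip = next_id
            next_id += 1
        return tip, direction

    tip, d = extend(1, _unit(rng.normal(size=3)), steps=int(rng.integers(2, 5)), tcode=3)
    tips = [(tip, d)]
    for _ in range(n_branch_points):
        k = int(rng.integers(0, len(tips)))
        tip, d = tips.pop(k)
        perp = _unit(np.cross(d, _unit(rng.normal(size=3))))
        for sign in (1.0, -1.0):
            child_dir = _unit(d + 0.7 * sign * perp)
            t, dd = extend(tip, child_dir, steps=int(rng.integers(2, 5)), tcode=3)
            tips.append((t, dd))
    morph = NeuronMorphology(ids, types, positions, radii, parents)
    return write_swc(morph, out_path)


def make_synthetic_streamlines(
    atlas: Atlas,
    source_acronym: str,
    n_paths: int,
    seed: int = 0,
    out_path=None,
    n_points: int = 20,
) -> Path:
    """Write smooth random-walk streamline paths starting inside a source
    region, in the JSON dialect read by :func:`brainscene.io.read_streamlines`.

    Every path's first point passes
    ``point_in_region(source_acronym, include_substructures=True)``.
    """
    if out_path is None:
        raise ValueError("out_path is required")
    rng = np.random.default_rng(seed)
    starts = make_synthetic_cells(atlas, source_acronym, n_paths, seed=seed)
    step = 1.5 * float(np.max(atlas.annotation.resolution))
    paths = []
    for start in starts.coordinates:
        v = _unit(rng.normal(size=3))
        pts = [start]
        for _ in range(n_points - 1):
            v = _unit(0.8 * v + 0.2 * rng.normal(size=3))
            pts.append(pts[-1] + v * step)
        paths.append(np.array(pts))
    s = Streamlines(paths, intensities=rng.random(n_paths).tolist())
    return write_streamlines(s, out_path)


def make_expression_volume(
    atlas: Atlas,
    hot_acronym: str,
    seed: int = 0,
    out_path=None,
    background_rate: float = 10.0,
    hot_rate: float = 200.0,
) -> Path:
    """Write a TIFF expression volume: Poisson background everywhere inside
    the grid, elevated Poisson counts inside the hot region.

    Thresholding at the midpoint of the two rates recovers essentially all
    hot-region voxels (Poisson(200) mass below 105 is negligible).
    """
    if out_path is None:
        raise ValueError("out_path is required")
    rng = np.random.default_rng(seed)
    shape = atlas.annotation.shape
    values = rng.poisson(background_rate, size=shape).astype(np.uint16)
    ids = atlas.region_ids(hot_acronym)
    hot = np.isin(atlas.annotation.labels, ids)
    if not hot.any():
        raise EmptyRegionError(f"{hot_acronym}: region has no labeled voxels")
    values[hot] = rng.poisson(hot_rate, size=int(hot.sum())).astype(np.uint16)
    out_path = Path(out_path)
    tifffile.imwrite(out_path, values)
    with open(out_path.with_suffix(".json"), "w") as fh:
        json.dump({"resolution": atlas.annotation.resolution.tolist()}, fh)
    return out_path
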