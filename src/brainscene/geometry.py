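"""Mesh construction and interrogation.

All physical coordinates are micrometers, axis order (AP, DV, LR) matching
voxel indices (i, j, k): voxel ``i`` spans physical ``[i*res, (i+1)*res)``.

Meshes are plain :class:`trimesh.Trimesh` objects throughout. Isosurfaces are
extracted with marching cubes at the 0.5 level of a binary mask; the mask is
2x nearest-neighbour supersampled first so the extracted surface sits on the
voxel boundary rather than halfway between voxel centers, which keeps mesh
volumes metrically faithful to voxel counts (a single voxel yields ~0.7 of
its volume instead of the octahedral 1/6).

Plane slicing, tube sweeping and point-in-mesh tests are implemented here
with standard computational-geometry primitives (ear clipping, parallel
transport frames, Moller-Trumbore ray casting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from skimage import measure

from .errors import EmptyMeshError, EmptyRegionError

__all__ = [
    "Plane",
    "validate_mesh",
    "label_isosurface",
    "slice_mesh",
    "points_to_spheres",
    "tube_along_path",
    "neuron_to_meshes",
    "streamlines_to_mesh",
    "center_of_mass",
    "distance_between",
    "contains_points",
    "point_in_mesh",
    "meshes_intersect",
]

# default number of sides for tube cross-sections; quality/size tradeoff
TUBE_SECTIONS = 12


@dataclass(frozen=True)
class Plane:
    """An oriented plane given by a point and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(normal)
        if norm == 0:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "normal", normal / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points to the plane (positive along the normal)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.normal


def validate_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Enforce mesh invariants: in-range face indices, no degenerate faces.

    Degenerate faces (repeated vertex index within a face) are dropped;
    out-of-range indices raise ``ValueError``.
    """
    faces = np.asarray(mesh.faces)
    if len(faces) and (faces.min() < 0 or faces.max() >= len(mesh.vertices)):
        raise ValueError("face index out of range")
    if len(faces):
        ok = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        if not ok.all():
            mesh = trimesh.Trimesh(mesh.vertices.copy(), faces[ok], process=False)
    return mesh


def _empty_mesh() -> trimesh.Trimesh:
    return trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int), process=False)


# ---------------------------------------------------------------------------
# isosurfacing


def _as_mask(volume, select) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve (mask, resolution, origin) from an annotation volume, a scalar
    volume grid, or a raw boolean array."""
    origin = np.zeros(3)
    if hasattr(volume, "labels"):  # AnnotationVolume
        labels = np.asarray(volume.labels)
        ids = np.atleast_1d(np.asarray(select))
        mask = np.isin(labels, ids)
        resolution = np.asarray(volume.resolution, dtype=float)
    elif hasattr(volume, "values"):  # VolumeGrid
        mask = np.asarray(volume.values) >= float(select)
        resolution = np.asarray(volume.resolution, dtype=float)
        origin = np.asarray(getattr(volume, "origin", origin), dtype=float)
    else:
        arr = np.asarray(volume)
        if arr.dtype == bool:
            mask = arr
        elif select is None:
            mask = arr != 0
        elif np.isscalar(select):
            mask = arr >= float(select)
        else:
            mask = np.isin(arr, np.atleast_1d(select))
        resolution = np.ones(3)
    return mask, np.broadcast_to(resolution, (3,)).astype(float), origin


def label_isosurface(
    volume,
    select=None,
    smoothing_iterations: int = 0,
    resolution=None,
) -> trimesh.Trimesh:
    """Extract the surface of a voxel selection as a triangle mesh.

    Parameters
    ----------
    volume
        An annotation volume (``select`` = structure id or ids), a scalar
        volume grid (``select`` = threshold; voxels >= threshold are kept),
        or a raw 3D array (boolean mask, or thresholded if ``select`` given).
    smoothing_iterations
        Taubin smoothing passes applied to the extracted surface (volume
        preserving, unlike plain Laplacian shrinkage).
    resolution
        Micrometers per voxel, overriding the volume's own metadata
        (required only for raw arrays with non-unit spacing).

    Returns a closed mesh for selections that do not touch the grid border
    (one voxel of zero padding ensures border-touching selections close too).
    """
    mask, res, origin = _as_mask(volume, select)
    if resolution is not None:
        res = np.broadcast_to(np.asarray(resolution, dtype=float), (3,)).astype(float)
    if mask.ndim != 3:
        raise ValueError("isosurfacing needs a 3D volume")
    if not mask.any():
        raise EmptyRegionError("selection contains no voxels")

    # crop to the selection's bounding box (plus margin) to keep marching
    # cubes cheap on large mostly-empty grids
    nz = np.nonzero(mask)
    lo = np.array([max(int(a.min()), 0) for a in nz])
    hi = np.array([int(a.max()) + 1 for a in nz])
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]

    sup = sub
    for ax in range(3):
        sup = np.repeat(sup, 2, axis=ax)
    padded = np.pad(sup, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    # padded supersampled index -> physical: each sub-voxel is res/2 wide,
    # centered at ((idx - 1) * 0.5 + 0.25) * res relative to the crop corner
    phys = ((verts - 1.0) * 0.5 + 0.25) * res + (lo * res) + origin
    mesh = trimesh.Trimesh(phys, faces, process=False)
    mesh = validate_mesh(mesh)
    if smoothing_iterations > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=int(smoothing_iterations))
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# plane slicing with caps


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex loops of the mesh's open boundary, oriented as the
    boundary edges appear in the faces."""
    faces = mesh.faces
    directed = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    und = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = directed[counts[inverse] == 1]
    nxt = {int(a): int(b) for a, b in boundary}
    loops = []
    while nxt:
        start, cur = next(iter(nxt.items()))
        loop = [start]
        del nxt[start]
        while cur != start:
            loop.append(cur)
            nxt_v = nxt.pop(cur, None)
            if nxt_v is None:  # open chain: numerically broken boundary, drop
                loop = None
                break
            cur = nxt_v
        if loop is not None and len(loop) >= 3:
            loops.append(np.array(loop, dtype=int))
    return loops


def _ear_clip(poly2d: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple polygon (indices into poly2d) by ear clipping.

    Returns triangles oriented like the input polygon. Coordinates are
    normalized to unit scale so tolerances are scale free; collinear ears
    (zero area) are clipped freely since they have no interior. Falls back
    to a centroid fan only if clipping stalls on degenerate input.
    """

    def cross2(p, q):
        return p[..., 0] * q[..., 1] - p[..., 1] * q[..., 0]

    n = len(poly2d)
    scale = float(np.abs(poly2d - poly2d.mean(axis=0)).max())
    pts2 = (poly2d - poly2d.mean(axis=0)) / max(scale, 1e-30)
    eps = 1e-12
    idx = list(range(n))
    # ensure CCW working order; remember if we flipped
    area2 = cross2(pts2[1:] - pts2[0], np.roll(pts2, -1, 0)[1:] - pts2[0]).sum()
    flipped = area2 < 0
    if flipped:
        idx = idx[::-1]
    tris: list[tuple[int, int, int]] = []

    def try_pass(allow_flat: bool) -> bool:
        m = len(idx)
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = pts2[i0], pts2[i1], pts2[i2]
            area = cross2(b - a, c - b)
            if area < -eps:  # reflex corner, not an ear
                continue
            if area <= eps:  # collinear sliver: clip without emitting a face
                if not allow_flat:
                    continue
                del idx[k]
                return True
            others = [j for j in idx if j not in (i0, i1, i2)]
            if others:
                q = pts2[others]
                v0, v1 = c - a, b - a
                den = cross2(v1, v0)
                u = cross2(q - a, v0) / den
                v = cross2(v1, q - a) / den
                if ((u > eps) & (v > eps) & (u + v < 1 - eps)).any():
                    continue
            tris.append((i0, i1, i2))
            del idx[k]
            return True
        return False

    while len(idx) > 3:
        if try_pass(allow_flat=False):
            continue
        if try_pass(allow_flat=True):
            continue
        break
    if len(idx) == 3:
        tris.append((idx[0], idx[1], idx[2]))
    elif len(idx) > 3:  # stalled: centroid fan as a best-effort fallback
        tris += [(idx[k], idx[k + 1], idx[0]) for k in range(1, len(idx) - 1)]
    if flipped:
        tris = [(c, b, a) for a, b, c in tris]
    return tris


def _cap_boundary(mesh: trimesh.Trimesh, plane: Plane, outward: np.ndarray) -> trimesh.Trimesh:
    """Close the open boundary loops of a plane-sliced mesh with flat caps
    whose normals point along ``outward``."""
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh
    # 2D basis in the plane
    n = outward / np.linalg.norm(outward)
    u = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    new_faces = []
    for loop in loops:
        pts = mesh.vertices[loop]
        poly2d = np.c_[pts @ u, pts @ v]
        tris = _ear_clip(poly2d)
        if not tris:
            continue
        cand = np.array([[loop[a], loop[b], loop[c]] for a, b, c in tris], dtype=int)
        # orient cap normals along `outward`; sum over all triangles so a
        # single degenerate sliver cannot flip the whole cap
        tri_pts = mesh.vertices[cand]
        total = np.cross(
            tri_pts[:, 1] - tri_pts[:, 0], tri_pts[:, 2] - tri_pts[:, 0]
        ).sum(axis=0)
        if total @ n < 0:
            cand = cand[:, ::-1]
        new_faces.append(cand)
    if not new_faces:
        return mesh
    faces = np.concatenate([mesh.faces] + new_faces, axis=0)
    return trimesh.Trimesh(mesh.vertices.copy(), faces, process=False)


def slice_mesh(mesh: trimesh.Trimesh, plane: Plane, keep: str = "below") -> trimesh.Trimesh:
    """Cut a mesh with a plane and keep one side, closing the cut with a cap.

    ``keep="below"`` retains points with ``(p - origin) . normal <= 0``;
    ``keep="above"`` the complement. A plane that misses the mesh returns the
    mesh unchanged (or an empty mesh if everything lies on the discarded
    side) -- neither case is an error.
    """
    if keep not in ("below", "above"):
        raise ValueError("keep must be 'below' or 'above'")
    if len(mesh.faces) == 0:
        return _empty_mesh()
    sd = plane.signed_distance(mesh.vertices)
    kept_normal = -plane.normal if keep == "below" else plane.normal
    kept = sd <= 0 if keep == "below" else sd >= 0
    if kept.all():
        return mesh.copy()
    if not kept.any():
        return _empty_mesh()
    cut = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=kept_normal, plane_origin=plane.origin, cap=False
    )
    if len(cut.faces) == 0:
        return _empty_mesh()
    cut = trimesh.Trimesh(cut.vertices, cut.faces, process=False)
    # weld duplicated cut vertices so boundary edges chain into loops
    cut.merge_vertices()
    outward = plane.normal if keep == "below" else -plane.normal
    capped = _cap_boundary(cut, plane, outward)
    capped = validate_mesh(capped)
    return capped


# ---------------------------------------------------------------------------
# glyphs and tubes


def points_to_spheres(
    points, radius: float, subdivisions: int = 1
) -> trimesh.Trimesh:
    """Instance one template icosphere at every coordinate and merge.

    The merged mesh has exactly ``N * template_vertex_count`` vertices
    (instances are concatenated, never welded), so glyph identity survives
    in the vertex layout.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(getattr(points, "coordinates", points), dtype=float)
    if coords.size == 0:
        return _empty_mesh()
    coords = coords.reshape(-1, 3)
    template = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    tv, tf = template.vertices, template.faces
    nv = len(tv)
    verts = (coords[:, None, :] + tv[None, :, :]).reshape(-1, 3)
    offsets = (np.arange(len(coords)) * nv)[:, None, None]
    faces = (tf[None, :, :] + offsets).reshape(-1, 3)
    return trimesh.Trimesh(verts, faces, process=False)


def _transport_frames(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transported (u, v) frame vectors along a polyline."""
    tangents = np.diff(path, axis=0)
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    # per-vertex tangent: average of adjacent segment tangents
    vt = np.empty_like(path)
    vt[0], vt[-1] = tangents[0], tangents[-1]
    if len(path) > 2:
        mid = tangents[:-1] + tangents[1:]
        norms = np.linalg.norm(mid, axis=1, keepdims=True)
        norms[norms < 1e-12] = 1.0
        vt[1:-1] = mid / norms
    t0 = vt[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(t0 @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(t0, ref)
    u /= np.linalg.norm(u)
    us = [u]
    for k in range(1, len(path)):
        u = us[-1] - vt[k] * (us[-1] @ vt[k])
        n = np.linalg.norm(u)
        if n < 1e-12:  # hairpin; restart frame
            ref = np.array([1.0, 0.0, 0.0]) if abs(vt[k][0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            u = np.cross(vt[k], ref)
            n = np.linalg.norm(u)
        us.append(u / n)
    us = np.array(us)
    vs = np.cross(vt, us)
    return us, vs


def tube_along_path(
    path, radius: float, sections: int = TUBE_SECTIONS
) -> trimesh.Trimesh:
    """Sweep a circle of ``radius`` along a polyline, capping both ends.

    The result is a single connected, watertight tube.
    """
    pts = np.asarray(path, dtype=float).reshape(-1, 3)
    # drop zero-length steps, which break frame transport
    if len(pts) >= 2:
        step = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        keepers = np.concatenate([[True], step > 1e-12])
        pts = pts[keepers]
    if len(pts) < 2:
        raise ValueError("a tube path needs at least 2 distinct points")
    if radius <= 0:
        raise ValueError("radius must be positive")
    us, vs = _transport_frames(pts)
    ang = np.linspace(0.0, 2 * np.pi, sections, endpoint=False)
    circ = np.c_[np.cos(ang), np.sin(ang)]  # (S, 2)
    rings = (
        pts[:, None, :]
        + radius * (circ[None, :, 0:1] * us[:, None, :] + circ[None, :, 1:2] * vs[:, None, :])
    )  # (P, S, 3)
    n_pts, S = len(pts), sections
    verts = rings.reshape(-1, 3)
    faces = []
    for p in range(n_pts - 1):
        a = p * S + np.arange(S)
        b = p * S + (np.arange(S) + 1) % S
        c = (p + 1) * S + np.arange(S)
        d = (p + 1) * S + (np.arange(S) + 1) % S
        faces.append(np.c_[a, b, d])
        faces.append(np.c_[a, d, c])
    faces = np.concatenate(faces, axis=0)
    # end caps: fan to center vertices
    c0 = len(verts)
    c1 = c0 + 1
    verts = np.vstack([verts, pts[0], pts[-1]])
    ring0 = np.arange(S)
    cap0 = np.c_[np.full(S, c0), (ring0 + 1) % S, ring0]
    ringN = (n_pts - 1) * S + np.arange(S)
    capN = np.c_[np.full(S, c1), ringN, (n_pts - 1) * S + (ring0 + 1) % S]
    faces = np.vstack([faces, cap0, capN])
    tube = trimesh.Trimesh(verts, faces, process=False)
    if tube.volume < 0:
        tube.invert()
    return tube


def neuron_to_meshes(
    morph,
    soma_radius_scale: float = 1.0,
    neurite_radius: float | None = None,
    sections: int = TUBE_SECTIONS,
) -> dict[str, trimesh.Trimesh]:
    """Build per-part meshes from a neuron morphology.

    Soma nodes become spheres (radius scaled by ``soma_radius_scale``); each
    parent-child segment becomes a capped tube whose radius is the child
    node's recorded radius, or ``neurite_radius`` if given. Parts are grouped
    by SWC type code: soma (1), axon (2), dendrites (3, 4), other.
    """
    part_of = {1: "soma", 2: "axon", 3: "dendrites", 4: "dendrites"}
    pieces: dict[str, list[trimesh.Trimesh]] = {}
    index = {int(s): k for k, s in enumerate(morph.ids)}
    for k in range(len(morph.ids)):
        tcode = int(morph.types[k])
        if tcode == 1:
            r = float(morph.radii[k]) * soma_radius_scale
            sph = trimesh.creation.icosphere(subdivisions=2, radius=r)
            sph.apply_translation(morph.positions[k])
            pieces.setdefault("soma", []).append(sph)
        parent = int(morph.parents[k])
        if parent == -1:
            continue
        pk = index[parent]
        if tcode == 1 and int(morph.types[pk]) == 1:
            continue  # soma-soma links are part of the soma blob, not neurites
        r = float(neurite_radius) if neurite_radius is not None else float(morph.radii[k])
        seg = np.vstack([morph.positions[pk], morph.positions[k]])
        if np.linalg.norm(seg[1] - seg[0]) < 1e-12:
            continue
        tube = tube_along_path(seg, radius=r, sections=sections)
        pieces.setdefault(part_of.get(tcode, "other"), []).append(tube)
    return {
        name: trimesh.util.concatenate(meshes) if len(meshes) > 1 else meshes[0]
        for name, meshes in pieces.items()
    }


def streamlines_to_mesh(
    streamlines, radius: float, sections: int = TUBE_SECTIONS
) -> trimesh.Trimesh:
    """Sweep every streamline path into a tube and merge into one mesh.

    Each input path contributes one connected component to the merged mesh.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    paths = getattr(streamlines, "paths", streamlines)
    tubes = [tube_along_path(p, radius=radius, sections=sections) for p in paths]
    if not tubes:
        return _empty_mesh()
    return trimesh.util.concatenate(tubes) if len(tubes) > 1 else tubes[0]


# ---------------------------------------------------------------------------
# measurements


def center_of_mass(mesh: trimesh.Trimesh) -> np.ndarray:
    """Volume centroid for closed meshes, area-weighted surface centroid
    otherwise."""
    if len(mesh.faces) == 0:
        raise EmptyMeshError("cannot take the center of an empty mesh")
    if mesh.is_watertight and abs(mesh.volume) > 1e-12:
        return np.asarray(mesh.center_mass, dtype=float)
    return np.average(mesh.triangles_center, axis=0, weights=mesh.area_faces)


def distance_between(a: trimesh.Trimesh, b: trimesh.Trimesh) -> float:
    """Euclidean distance between two meshes' centers of mass."""
    return float(np.linalg.norm(center_of_mass(a) - center_of_mass(b)))


# fixed, slightly irrational ray direction: avoids axis-aligned edge grazing
_RAY_DIR = np.array([0.2971528391, 0.5655325351, 0.7693221634])
_RAY_DIR = _RAY_DIR / np.linalg.norm(_RAY_DIR)


def _ray_crossings(points: np.ndarray, triangles: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Count ray-triangle crossings per point (Moller-Trumbore, vectorized,
    chunked over points)."""
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    h = np.cross(direction, e2)  # (F, 3)
    a = (e1 * h).sum(axis=1)  # (F,)
    live = np.abs(a) > 1e-12
    v0, e1, e2, h, a = v0[live], e1[live], e2[live], h[live], a[live]
    counts = np.zeros(len(points), dtype=int)
    if len(a) == 0:
        return counts
    inv_a = 1.0 / a
    chunk = max(1, int(4e6 // max(len(a), 1)))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]  # (C, 3)
        svec = p[:, None, :] - v0[None, :, :]  # (C, F, 3)
        u = (svec * h[None, :, :]).sum(axis=2) * inv_a[None, :]
        q = np.cross(svec, e1[None, :, :])
        v = (q * direction).sum(axis=2) * inv_a[None, :]
        t = (q * e2[None, :, :]).sum(axis=2) * inv_a[None, :]
        hit = (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        counts[s : s + chunk] = hit.sum(axis=1)
    return counts


def contains_points(mesh: trimesh.Trimesh, points, warn_open: bool = True) -> np.ndarray:
    """Ray-parity containment test: odd crossings => inside.

    For non-watertight meshes the result is best effort (a warning is
    emitted); real region meshes are occasionally imperfect and a flagged
    answer beats an exception.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(mesh.faces) == 0:
        raise EmptyMeshError("containment test against an empty mesh")
    if warn_open and not mesh.is_watertight:
        import warnings

        warnings.warn(
            "containment tested against a non-watertight mesh; result is best effort",
            RuntimeWarning,
            stacklevel=2,
        )
    inside = np.zeros(len(pts), dtype=bool)
    lo, hi = mesh.bounds
    in_box = np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)
    if in_box.any():
        counts = _ray_crossings(pts[in_box], mesh.triangles, _RAY_DIR)
        inside[in_box] = counts % 2 == 1
    return inside


def point_in_mesh(point, mesh: trimesh.Trimesh) -> bool:
    """True if a single point lies inside a closed mesh (ray parity)."""
    return bool(contains_points(mesh, np.asarray(point, dtype=float).reshape(1, 3))[0])


def _segments_cross_triangles(segments: np.ndarray, triangles: np.ndarray) -> bool:
    """True if any segment (S, 2, 3) crosses any triangle (Moller-Trumbore
    restricted to t in [0, 1])."""
    starts = segments[:, 0]
    vecs = segments[:, 1] - segments[:, 0]
    lengths = np.linalg.norm(vecs, axis=1)
    ok = lengths > 1e-12
    starts, vecs, lengths = starts[ok], vecs[ok], lengths[ok]
    if len(starts) == 0 or len(triangles) == 0:
        return False
    dirs = vecs / lengths[:, None]
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    chunk = max(1, int(2e6 // max(len(triangles), 1)))
    for s in range(0, len(starts), chunk):
        p, d, L = starts[s : s + chunk], dirs[s : s + chunk], lengths[s : s + chunk]
        h = np.cross(d[:, None, :], e2[None, :, :])  # (C, F, 3)
        a = (h * e1[None, :, :]).sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_a = np.where(np.abs(a) > 1e-12, 1.0 / a, 0.0)
            svec = p[:, None, :] - v0[None, :, :]
            u = (svec * h).sum(axis=2) * inv_a
            q = np.cross(svec, e1[None, :, :])
            v = (q * d[:, None, :]).sum(axis=2) * inv_a
            t = (q * e2[None, :, :]).sum(axis=2) * inv_a
        hit = (
            (np.abs(a) > 1e-12)
            & (u >= -1e-9)
            & (v >= -1e-9)
            & (u + v <= 1 + 1e-9)
            & (t >= -1e-9)
            & (t <= L[:, None] + 1e-9)
        )
        if hit.any():
            return True
    return False


def meshes_intersect(a: trimesh.Trimesh, b: trimesh.Trimesh) -> bool:
    """True if two meshes' surfaces cross or one lies inside the other."""
    if len(a.faces) == 0 or len(b.faces) == 0:
        return False
    lo = np.maximum(a.bounds[0], b.bounds[0])
    hi = np.minimum(a.bounds[1], b.bounds[1])
    if np.any(lo > hi):
        return False

    def _sample(verts, n=300):
        if len(verts) <= n:
            return verts
        stride = len(verts) // n
        return verts[::stride][:n]

    if contains_points(b, _sample(a.vertices), warn_open=False).any():
        return True
    if contains_points(a, _sample(b.vertices), warn_open=False).any():
        return True
    # surfaces may cross without either mesh's sampled vertices inside the
    # other: test a's edges against b's triangles inside the bbox overlap
    pad = 1e-9 + 0.01 * np.linalg.norm(hi - lo)
    seg = a.vertices[a.edges_unique]
    seg_in = np.all((seg.min(axis=1) <= hi + pad) & (seg.max(axis=1) >= lo - pad), axis=1)
    tri = b.triangles
    tri_in = np.all(
        (tri.min(axis=1) <= hi + pad) & (tri.max(axis=1) >= lo - pad), axis=1
    )
    segments = seg[seg_in]
    if len(segments) > 2000:
        segments = segments[:: len(segments) // 2000][:2000]
    return _segments_cross_triangles(segments, tri[tri_in])
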