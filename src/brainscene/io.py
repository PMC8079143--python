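"""Readers and writers for the standard neuroanatomy data formats.

Supported: SWC neuron morphologies (7-column text), OBJ/STL surface meshes,
NPY/CSV coordinate tables, JSON streamlines, and TIFF volume stacks.

The streamlines JSON dialect is a top-level object with key ``"lines"``,
each line an array of ``{"x", "y", "z"}`` micrometer points, mirroring the
mesoscale-connectivity exports commonly visualized in this field; an
optional top-level ``"intensities"`` array carries one scalar per path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .errors import FormatError
from .geometry import validate_mesh

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronMorphology",
    "Streamlines",
    "PointsData",
    "VolumeGrid",
    "read_swc",
    "write_swc",
    "read_mesh",
    "write_mesh",
    "read_points",
    "read_streamlines",
    "write_streamlines",
    "read_volume",
    "write_volume",
]


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class NeuronMorphology:
    """A neuron reconstruction as an ordered table of SWC samples.

    ``types`` follow the SWC convention (1 soma, 2 axon, 3 basal dendrite,
    4 apical dendrite; higher codes are accepted and styled with a default).
    ``parents`` reference ``ids`` defined earlier in the table, or -1 for a
    root. Positions and radii are micrometers.
    """

    ids: np.ndarray
    types: np.ndarray
    positions: np.ndarray
    radii: np.ndarray
    parents: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        if n == 0:
            raise FormatError("morphology has no samples")
        if len(np.unique(self.ids)) != n:
            raise FormatError("duplicate sample ids")
        if not (self.radii > 0).all():
            raise FormatError("radii must be strictly positive")
        if not (self.parents == -1).any():
            raise FormatError("morphology has no root (parent -1) sample")
        seen: set[int] = set()
        for k in range(n):
            p = int(self.parents[k])
            if p != -1 and p not in seen:
                raise FormatError(
                    f"sample {int(self.ids[k])} references parent {p} "
                    "not defined earlier"
                )
            seen.add(int(self.ids[k]))

    def __len__(self) -> int:
        return len(self.ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, NeuronMorphology):
            return NotImplemented
        return (
            np.array_equal(self.ids, other.ids)
            and np.array_equal(self.types, other.types)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.radii, other.radii)
            and np.array_equal(self.parents, other.parents)
        )

    @property
    def n_roots(self) -> int:
        return int((self.parents == -1).sum())

    def branch_point_ids(self) -> np.ndarray:
        """Sample ids with two or more children, soma excluded."""
        counts: dict[int, int] = {}
        for p in self.parents:
            if p != -1:
                counts[int(p)] = counts.get(int(p), 0) + 1
        soma = set(self.ids[self.types == 1].tolist())
        return np.array(
            sorted(i for i, c in counts.items() if c >= 2 and i not in soma), dtype=int
        )

    def segment_lengths(self) -> np.ndarray:
        """Euclidean length of every parent-child segment, in table order."""
        index = {int(s): k for k, s in enumerate(self.ids)}
        out = []
        for k in range(len(self)):
            p = int(self.parents[k])
            if p == -1:
                continue
            out.append(np.linalg.norm(self.positions[k] - self.positions[index[p]]))
        return np.array(out)


@dataclass
class Streamlines:
    """A bundle of 3D polyline paths (micrometers), e.g. mesoscale
    projection trajectories; ``intensities`` optionally carries one scalar
    per path."""

    paths: list
    intensities: list | None = None

    def __post_init__(self):
        self.paths = [np.asarray(p, dtype=float).reshape(-1, 3) for p in self.paths]
        for p in self.paths:
            if len(p) < 2:
                raise FormatError("every streamline path needs at least 2 points")

    def __len__(self) -> int:
        return len(self.paths)

    @property
    def total_points(self) -> int:
        return int(sum(len(p) for p in self.paths))


@dataclass
class PointsData:
    """An N x 3 table of micrometer coordinates with optional per-point
    labels (e.g. cell types or colors)."""

    coordinates: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.coordinates).all():
            raise FormatError("coordinates must be finite; filter before constructing")

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class VolumeGrid:
    """A scalar 3D grid (e.g. voxel-wise gene expression) with voxel size
    and physical origin in micrometers."""

    values: np.ndarray
    resolution: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError("volume grid must be 3D")
        self.resolution = np.broadcast_to(
            np.asarray(self.resolution, dtype=float), (3,)
        ).copy()
        if not (self.resolution > 0).all():
            raise FormatError("resolution must be strictly positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)


# ---------------------------------------------------------------------------
# SWC


def read_swc(path) -> NeuronMorphology:
    """Parse a 7-column SWC file (``id type x y z radius parent``).

    Lines starting with ``#`` are comments; blank lines are ignored. Raises
    :class:`FormatError` with a line number for malformed rows, forward
    parent references, or an empty file.
    """
    path = Path(path)
    ids, types, pos, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                sid, tcode = int(fields[0]), int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-numeric field ({exc})") from exc
            ids.append(sid)
            types.append(tcode)
            pos.append((x, y, z))
            radii.append(r)
            parents.append(parent)
    if not ids:
        raise FormatError(f"{path.name}: no samples (comments/blank lines only)")
    try:
        return NeuronMorphology(ids, types, pos, radii, parents)
    except FormatError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc


def write_swc(morph: NeuronMorphology, path) -> Path:
    """Write a morphology as standard 7-column SWC; exact round-trip with
    :func:`read_swc` (floats serialized with shortest round-trip repr)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(len(morph)):
            x, y, z = (float(v) for v in morph.positions[k])
            fh.write(
                f"{int(morph.ids[k])} {int(morph.types[k])} "
                f"{x!r} {y!r} {z!r} {float(morph.radii[k])!r} {int(morph.parents[k])}\n"
            )
    return path


# ---------------------------------------------------------------------------
# meshes


_MESH_EXTENSIONS = {".obj", ".stl"}


def read_mesh(path) -> trimesh.Trimesh:
    """Load an OBJ or STL surface mesh.

    OBJ preserves the vertex/face layout exactly. STL stores a triangle
    soup, so duplicate vertices are welded on load; for meshes written by
    :func:`write_mesh` this restores the original vertex count.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _MESH_EXTENSIONS:
        raise FormatError(f"unsupported mesh extension {ext!r} (use .obj or .stl)")
    try:
        mesh = trimesh.load_mesh(path, file_type=ext[1:], process=False)
    except Exception as exc:
        raise FormatError(f"{path.name}: cannot parse mesh ({exc})") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        mesh = trimesh.util.concatenate(geoms) if geoms else trimesh.Trimesh()
    if ext == ".stl":
        mesh.merge_vertices()
    try:
        mesh = validate_mesh(mesh)
    except ValueError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> Path:
    """Write a mesh as OBJ or STL (chosen by extension)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _MESH_EXTENSIONS:
        raise FormatError(f"unsupported mesh extension {ext!r} (use .obj or .stl)")
    mesh.export(path)
    return path


# ---------------------------------------------------------------------------
# points


def _looks_numeric(tokens) -> bool:
    for t in tokens:
        try:
            float(t)
        except ValueError:
            return False
    return True


def read_points(path) -> PointsData:
    """Load an N x 3 coordinate table from NPY or CSV/TSV.

    CSV delimiter is auto-detected (comma or tab) and a header row is
    detected by a non-numeric first line. Rows containing non-finite values
    are dropped; the count is logged.
    """
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path, allow_pickle=False)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise FormatError(
                f"{path.name}: expected an N x 3 array, got shape {arr.shape}"
            )
        arr = arr.astype(float)
    else:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
        header = 0 if not _looks_numeric(first.strip().split(sep)) else None
        df = pd.read_csv(path, sep=sep, header=header)
        numeric = df.apply(pd.to_numeric, errors="coerce")
        if numeric.shape[1] != 3:
            raise FormatError(
                f"{path.name}: expected 3 coordinate columns, got {numeric.shape[1]}"
            )
        arr = numeric.to_numpy(dtype=float)
    finite = np.isfinite(arr).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("read_points(%s): dropped %d non-finite rows", path.name, dropped)
    pts = PointsData(arr[finite])
    pts.n_dropped = dropped
    return pts


def write_points(points: PointsData, path) -> Path:
    """Write coordinates as NPY or CSV (chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, points.coordinates)
    else:
        pd.DataFrame(points.coordinates, columns=["x", "y", "z"]).to_csv(
            path, index=False
        )
    return path


# ---------------------------------------------------------------------------
# streamlines


def read_streamlines(path) -> Streamlines:
    """Load streamlines from the JSON dialect described in the module
    docstring. Paths with fewer than 2 points are dropped; the count is
    logged."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "lines" not in doc:
        raise FormatError(f"{path.name}: missing top-level 'lines' key")
    raw_paths = doc["lines"]
    intensities = doc.get("intensities")
    paths, kept_idx = [], []
    for k, line in enumerate(raw_paths):
        pts = np.array([[p["x"], p["y"], p["z"]] for p in line], dtype=float)
        if len(pts) >= 2:
            paths.append(pts)
            kept_idx.append(k)
    dropped = len(raw_paths) - len(paths)
    if dropped:
        logger.info(
            "read_streamlines(%s): dropped %d paths with < 2 points", path.name, dropped
        )
    kept_int = None
    if intensities is not None:
        kept_int = [intensities[k] for k in kept_idx]
    s = Streamlines(paths, kept_int)
    s.n_dropped = dropped
    return s


def write_streamlines(streamlines: Streamlines, path) -> Path:
    """Write streamlines in the JSON dialect read by
    :func:`read_streamlines`."""
    path = Path(path)
    doc = {
        "lines": [
            [{"x": float(x), "y": float(y), "z": float(z)} for x, y, z in p]
            for p in streamlines.paths
        ]
    }
    if streamlines.intensities is not None:
        doc["intensities"] = [float(v) for v in streamlines.intensities]
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


# ---------------------------------------------------------------------------
# volumes


def read_volume(path, resolution=None) -> VolumeGrid:
    """Load a 3D TIFF stack as a :class:`VolumeGrid`.

    ``resolution`` (micrometers per voxel) may be passed by the caller or
    supplied by a JSON sidecar ``<name>.json`` with a ``"resolution"`` key;
    it defaults to 1 um otherwise.
    """
    path = Path(path)
    values = tifffile.imread(path)
    if values.ndim != 3:
        raise FormatError(f"{path.name}: expected a 3D stack, got {values.ndim}D")
    origin = np.zeros(3)
    if resolution is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
            resolution = meta.get("resolution", 1.0)
            origin = np.asarray(meta.get("origin", origin), dtype=float)
        else:
            resolution = 1.0
    return VolumeGrid(values, resolution, origin)


def write_volume(grid: VolumeGrid, path) -> Path:
    """Write a volume grid as TIFF plus a JSON sidecar with resolution and
    origin."""
    path = Path(path)
    tifffile.imwrite(path, grid.values)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(
            {"resolution": grid.resolution.tolist(), "origin": grid.origin.tolist()},
            fh,
        )
    return path
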