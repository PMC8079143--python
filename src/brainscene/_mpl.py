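"""Off-screen rendering backend (matplotlib Agg).

Renders a list of actors from a camera pose into a PNG of exactly the
requested pixel dimensions; no display, no GPU, deterministic output on a
given platform. Atlas coordinates (AP, DV, LR) map to plot axes as
x = AP, y = LR, z = -DV so that dorsal points up.

Points actors are drawn as screen-space markers at their glyph centers
(the sphere meshes exist for geometry and export; rasterizing tens of
thousands of tiny spheres as polygons buys nothing visually).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.colors import to_rgb
from matplotlib.figure import Figure
from mpl_toolkits.mplot3d.art3d import Poly3DCollection

_DPI = 100

#: Per-actor cap on rasterized triangles: above this, faces are stride
#: subsampled for display only (geometry, export and measurements always use
#: the full mesh). Keeps frame rendering O(seconds) on one CPU.
MAX_RENDER_FACES = 12000

def _to_plot(points: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(points)
    return np.c_[p[:, 0], p[:, 2], -p[:, 1]]


def render_png(
    actors,
    camera,
    path,
    width: int = 800,
    height: int = 600,
    background: str = "white",
) -> Path:
    """Render visible actors to a ``width x height`` PNG file."""
    path = Path(path)
    fig = Figure(figsize=(width / _DPI, height / _DPI), dpi=_DPI)
    FigureCanvasAgg(fig)
    fig.set_facecolor(background)
    ax = fig.add_axes((0.0, 0.0, 1.0, 1.0), projection="3d")
    ax.set_facecolor(background)
    ax.set_axis_off()

    drew_any = False
    for actor in actors:
        if not actor.visible:
            continue
        style = actor.style
        centers = actor.metadata.get("centers")
        if actor.kind == "points" and centers is not None and len(centers):
            c = _to_plot(centers)
            ax.scatter(
                c[:, 0], c[:, 1], c[:, 2],
                c=style.color, alpha=style.alpha, s=9, depthshade=False,
            )
            drew_any = True
            continue
        mesh = actor.mesh
        if len(mesh.faces) == 0:
            continue
        faces = mesh.faces
        if len(faces) > MAX_RENDER_FACES:
            stride = int(np.ceil(len(faces) / MAX_RENDER_FACES))
            faces = faces[::stride]
        tris = _to_plot(mesh.vertices.reshape(-1, 3)).reshape(-1, 3)[faces]
        # simple Lambert shading with a fixed light; per-face colors
        e1 = tris[:, 1] - tris[:, 0]
        e2 = tris[:, 2] - tris[:, 0]
        n = np.cross(e1, e2)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm < 1e-12] = 1.0
        n /= norm
        light = np.array([0.45, -0.5, 0.74])
        light /= np.linalg.norm(light)
        shade = 0.45 + 0.55 * np.abs(n @ light)
        base = np.array(to_rgb(style.color))
        face_rgba = np.empty((len(tris), 4))
        face_rgba[:, :3] = shade[:, None] * base[None, :]
        face_rgba[:, 3] = style.alpha
        coll = Poly3DCollection(
            tris,
            facecolors=face_rgba,
            edgecolors="none",
            linewidth=style.line_width,
        )
        ax.add_collection3d(coll)
        drew_any = True

    focal = _to_plot(camera.focal_point)[0]
    view_vec = _to_plot(camera.position)[0] - focal
    r = np.linalg.norm(view_vec)
    if r < 1e-12:
        view_vec, r = np.array([1.0, 0.0, 0.0]), 1.0
    elev = float(np.degrees(np.arcsin(np.clip(view_vec[2] / r, -1, 1))))
    azim = float(np.degrees(np.arctan2(view_vec[1], view_vec[0])))
    ax.view_init(elev=elev, azim=azim, roll=0)

    half = max(r / 2.0, 1e-6) / max(camera.zoom, 1e-6)
    if not drew_any:
        half = max(half, 1.0)
    ax.set_xlim(focal[0] - half, focal[0] + half)
    ax.set_ylim(focal[1] - half, focal[1] + half)
    ax.set_zlim(focal[2] - half, focal[2] + half)
    ax.set_box_aspect((1, 1, 1))

    # rasterize and enforce the exact requested pixel dimensions: matplotlib
    # rounds figsize*dpi inconsistently for odd sizes, so crop/pad as needed
    canvas = fig.canvas
    canvas.draw()
    arr = np.asarray(canvas.buffer_rgba()).copy()
    h, w = arr.shape[:2]
    if (h, w) != (height, width):
        bg = (np.array(to_rgb(background) + (1.0,)) * 255).astype(np.uint8)
        out = np.empty((height, width, 4), dtype=np.uint8)
        out[:] = bg
        out[: min(h, height), : min(w, width)] = arr[: min(h, height), : min(w, width)]
        arr = out
    from PIL import Image

    Image.fromarray(arr, mode="RGBA").save(path, format="PNG")
    return path
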