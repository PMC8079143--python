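"""The Scene: compose actors, slice, set the camera, export.

A Scene owns an atlas, an ordered actor list (render order is list order),
a camera pose and a background color. Exports: PNG screenshots (off-screen,
exact requested pixel dimensions) and single-file HTML documents embedding
every visible actor's geometry as JSON plus a small self-contained canvas
viewer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from . import _mpl
from .actors import Actor, Style, make_actor
from .atlas import Atlas
from .errors import StructureLookupError
from .geometry import Plane, slice_mesh

__all__ = ["CameraPose", "camera_preset", "Scene", "CAMERA_PRESETS"]

CAMERA_PRESETS = ("frontal", "sagittal", "top")


@dataclass
class CameraPose:
    """Camera position/orientation: where it sits, what it looks at, which
    way is up, and a zoom factor (>1 magnifies)."""

    position: np.ndarray
    focal_point: np.ndarray
    viewup: np.ndarray = (0.0, -1.0, 0.0)
    zoom: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.focal_point = np.asarray(self.focal_point, dtype=float).reshape(3)
        up = np.asarray(self.viewup, dtype=float).reshape(3)
        n = np.linalg.norm(up)
        if n == 0:
            raise ValueError("viewup must be non-zero")
        self.viewup = up / n
        if np.allclose(self.position, self.focal_point):
            raise ValueError("camera position must differ from the focal point")
        if self.zoom <= 0:
            raise ValueError("zoom must be positive")

    def copy(self) -> "CameraPose":
        return CameraPose(
            self.position.copy(), self.focal_point.copy(), self.viewup.copy(), self.zoom
        )


def camera_preset(name: str, bounds: np.ndarray, zoom: float = 1.0) -> CameraPose:
    """A named view computed from a bounding box (2 x 3, micrometers).

    ``frontal`` looks along +AP from anterior, ``sagittal`` along +LR from
    the left, ``top`` along +DV from dorsal.
    """
    bounds = np.asarray(bounds, dtype=float)
    center = bounds.mean(axis=0)
    extent = float(np.max(bounds[1] - bounds[0]))
    d = 2.0 * max(extent, 1.0)
    if name == "frontal":
        offset, up = np.array([-d, 0.0, 0.0]), (0.0, -1.0, 0.0)
    elif name == "sagittal":
        offset, up = np.array([0.0, 0.0, -d]), (0.0, -1.0, 0.0)
    elif name == "top":
        offset, up = np.array([0.0, -d, 0.0]), (-1.0, 0.0, 0.0)
    else:
        raise ValueError(f"unknown camera preset {name!r}; one of {CAMERA_PRESETS}")
    return CameraPose(center + offset, center, up, zoom)


class Scene:
    """A renderable composition of actors over one atlas.

    Construction adds the root-region actor (light gray, nearly
    transparent) unless ``add_root=False``, and frames it with a frontal
    camera.
    """

    def __init__(self, atlas: Atlas, add_root: bool = True, background: str = "white"):
        self.atlas = atlas
        self.actors: list[Actor] = []
        self.background = background
        if add_root:
            mesh = atlas.region_mesh(atlas.root_acronym)
            root = Actor(
                name=atlas.root_acronym,
                kind="region",
                mesh=mesh,
                style=Style(color="#d3d3d3", alpha=0.1),
                source=atlas.root_acronym,
            )
            self.actors.append(root)
            self.camera = camera_preset("frontal", mesh.bounds)
        else:
            ext = atlas.annotation.extent_um
            self.camera = camera_preset("frontal", np.array([[0.0, 0.0, 0.0], ext]))

    # -- composition --------------------------------------------------------

    def _unique_name(self, name: str) -> str:
        taken = {a.name for a in self.actors}
        if name not in taken:
            return name
        k = 1
        while f"{name}_{k}" in taken:
            k += 1
        return f"{name}_{k}"

    def add(self, actor_or_list):
        """Add an actor (or list of actors), suffixing names to keep them
        unique within the scene. Returns what was added."""
        actors = actor_or_list if isinstance(actor_or_list, list) else [actor_or_list]
        for a in actors:
            a.name = self._unique_name(a.name)
            self.actors.append(a)
        return actor_or_list

    def add_actor(self, payload, **kwargs):
        """Build an actor from any supported payload and add it."""
        return self.add(make_actor(payload, **kwargs))

    def add_brain_region(self, acronyms, alpha: float = 0.3, color=None) -> list[Actor]:
        """Add one region actor per acronym (meshes via the atlas).

        Atomic: an unknown acronym raises before anything is added. Color
        defaults to each structure's own rgb.
        """
        if isinstance(acronyms, str):
            acronyms = [acronyms]
        nodes = [self.atlas.get_structure(a) for a in acronyms]  # may raise
        meshes = [self.atlas.region_mesh(n.acronym) for n in nodes]
        added = []
        for node, mesh in zip(nodes, meshes):
            c = color if color is not None else "#{:02x}{:02x}{:02x}".format(*node.rgb)
            actor = Actor(
                name=node.acronym,
                kind="region",
                mesh=mesh,
                style=Style(color=c, alpha=alpha),
                source=node.acronym,
            )
            added.append(actor)
        self.add(added)
        return added

    def get_actor(self, name: str) -> Actor:
        for a in self.actors:
            if a.name == name:
                return a
        raise StructureLookupError(f"no actor named {name!r} in the scene")

    def __len__(self) -> int:
        return len(self.actors)

    # -- slicing ------------------------------------------------------------

    def slice(self, plane: Plane, actors=None, keep: str = "below") -> "Scene":
        """Cut targeted actors with a plane, keeping one side.

        ``actors`` may be a list of actors or names; None targets all.
        Mesh actors are sliced and capped; points actors keep whole glyphs
        by which side their centers fall on. Fully discarded actors become
        empty and invisible. Returns the scene for chaining.
        """
        if actors is None:
            targets = list(self.actors)
        else:
            targets = [a if isinstance(a, Actor) else self.get_actor(a) for a in actors]
        for actor in targets:
            centers = actor.metadata.get("centers")
            if actor.kind == "points" and centers is not None:
                sd = plane.signed_distance(centers)
                keep_mask = sd <= 0 if keep == "below" else sd >= 0
                kept = centers[keep_mask]
                from .geometry import points_to_spheres

                radius = actor.metadata.get("radius", 15.0)
                actor.mesh = points_to_spheres(kept, radius=radius) if len(kept) else \
                    trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int), process=False)
                actor.metadata["centers"] = kept
            else:
                actor.mesh = slice_mesh(actor.mesh, plane, keep=keep)
        return self

    # -- export -------------------------------------------------------------

    def render_screenshot(
        self, path, width: int = 800, height: int = 600, camera: CameraPose | None = None
    ) -> Path:
        """Write an off-screen PNG of exactly ``width x height`` pixels."""
        return _mpl.render_png(
            self.actors,
            camera or self.camera,
            path,
            width=width,
            height=height,
            background=self.background,
        )

    def export_html(self, path) -> Path:
        """Write a single self-contained HTML document.

        Every *visible* actor's geometry (vertices, faces, style) is
        embedded as JSON in a ``<script type="application/json"
        id="brainscene-data">`` block, followed by a small inline canvas
        viewer; no external assets are referenced.
        """
        path = Path(path)
        geometries = []
        for a in self.actors:
            if not a.visible:
                continue
            geometries.append(
                {
                    "name": a.name,
                    "kind": a.kind,
                    "color": a.style.color,
                    "alpha": a.style.alpha,
                    "vertices": np.round(a.mesh.vertices, 3).tolist(),
                    "faces": a.mesh.faces.tolist(),
                }
            )
        doc = {
            "generator": "brainscene",
            "background": self.background,
            "camera": {
                "position": self.camera.position.tolist(),
                "focal_point": self.camera.focal_point.tolist(),
                "viewup": self.camera.viewup.tolist(),
                "zoom": self.camera.zoom,
            },
            "geometries": geometries,
        }
        payload = json.dumps(doc)
        html = _HTML_TEMPLATE.replace("__DATA__", payload)
        path.write_text(html)
        return path


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>brainscene export</title>
<style>body{margin:0;overflow:hidden}canvas{display:block}</style></head>
<body>
<script type="application/json" id="brainscene-data">__DATA__</script>
<canvas id="view"></canvas>
<script>
(function(){
  var doc = JSON.parse(document.getElementById('brainscene-data').textContent);
  var cv = document.getElementById('view');
  cv.width = window.innerWidth || 800; cv.height = window.innerHeight || 600;
  var ctx = cv.getContext('2d');
  var rotY = 0.6, rotX = -0.4, drag = null;
  function bounds(){
    var lo=[1e30,1e30,1e30], hi=[-1e30,-1e30,-1e30];
    doc.geometries.forEach(function(g){ g.vertices.forEach(function(v){
      for(var i=0;i<3;i++){ if(v[i]<lo[i])lo[i]=v[i]; if(v[i]>hi[i])hi[i]=v[i]; }});});
    return [lo,hi];
  }
  var bb = bounds();
  var c = [(bb[0][0]+bb[1][0])/2,(bb[0][1]+bb[1][1])/2,(bb[0][2]+bb[1][2])/2];
  var ext = Math.max(bb[1][0]-bb[0][0], bb[1][1]-bb[0][1], bb[1][2]-bb[0][2], 1);
  function project(v){
    var x=v[0]-c[0], y=v[1]-c[1], z=v[2]-c[2];
    var x1=x*Math.cos(rotY)+z*Math.sin(rotY), z1=-x*Math.sin(rotY)+z*Math.cos(rotY);
    var y1=y*Math.cos(rotX)-z1*Math.sin(rotX);
    var s=Math.min(cv.width,cv.height)/(1.4*ext);
    return [cv.width/2+x1*s, cv.height/2+y1*s];
  }
  function draw(){
    ctx.fillStyle = doc.background || 'white';
    ctx.fillRect(0,0,cv.width,cv.height);
    doc.geometries.forEach(function(g){
      ctx.strokeStyle = g.color; ctx.globalAlpha = Math.max(0.15, g.alpha*0.6);
      ctx.beginPath();
      var step = Math.max(1, Math.floor(g.faces.length/4000));
      for(var k=0;k<g.faces.length;k+=step){
        var f=g.faces[k];
        var a=project(g.vertices[f[0]]), b=project(g.vertices[f[1]]);
        ctx.moveTo(a[0],a[1]); ctx.lineTo(b[0],b[1]);
      }
      ctx.stroke(); ctx.globalAlpha = 1;
    });
  }
  cv.addEventListener('mousedown', function(e){ drag=[e.clientX,e.clientY]; });
  window.addEventListener('mouseup', function(){ drag=null; });
  window.addEventListener('mousemove', function(e){
    if(!drag) return;
    rotY += (e.clientX-drag[0])*0.01; rotX += (e.clientY-drag[1])*0.01;
    drag=[e.clientX,e.clientY]; draw();
  });
  draw();
})();
</script>
</body>
</html>
"""
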