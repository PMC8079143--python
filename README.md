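# brainscene

Scene-based 3D visualization of anatomically registered neuroscience data,
entirely off-screen and scriptable: brain-atlas region meshes, labeled cell
coordinates, SWC neuron morphologies, mesoscale projection streamlines,
implanted probe geometry and volumetric images, composed into a `Scene` of
styled `Actor`s and exported as PNG screenshots, single-file interactive
HTML documents, or keyframe-animated frame sequences.

It is aimed at systems and developmental neuroscientists who have data
registered to a common anatomical reference (e.g. cell detections from
whole-brain microscopy, reconstructed neurons, tractography) and want
publication-quality 3D figures and videos without a GPU, a display server,
or hand-written rendering code.

## What it does

**Atlas model.** An atlas is a structure hierarchy (unique positive integer
ids and acronyms, one root, acyclic parent links), a 3D annotation volume
(voxel value = structure id, 0 = outside the brain), and a store of region
surface meshes. Axis order is fixed to (AP, DV, LR); all physical
coordinates are micrometers; a point `p` maps to voxel `floor(p / res)` per
axis. Parent regions are unions of their children, so membership queries
resolve through the hierarchy:

- `atlas.structure_from_point(p)` — which structure contains a point
- `atlas.point_in_region(p, "CTX", include_substructures=True)`
- `atlas.ancestors("VISp")` / `atlas.descendants("CTX")`
- `atlas.region_mesh("CTX")` — stored mesh, or a marching-cubes isosurface
  of the region's labeled voxels (own id ∪ descendant ids) at the 0.5 level
  of the binary mask

**Geometry.** Label/scalar volumes become watertight triangle meshes;
meshes can be sliced by arbitrary planes with the cut capped (volume is
conserved to machine precision: kept + complement = original); point sets
become instanced sphere glyphs; SWC neurons become soma spheres plus
per-segment neurite tubes grouped by type (soma/axon/dendrites);
streamlines become swept tubes. Measurement utilities: centers of mass,
pairwise distances, mesh–mesh intersection tests and ray-parity
point-in-mesh containment.

**Scene & export.** A `Scene` owns the atlas, an ordered actor list, a
camera pose and background. Rendering is off-screen (matplotlib Agg):
screenshots have exactly the requested pixel dimensions and repeated
renders are byte-identical on one platform. `export_html` writes a single
self-contained document embedding every visible actor's geometry as JSON
plus an inline canvas viewer. The `Animation` class interpolates camera
pose and actor style linearly between keyframes and writes numbered PNG
frames on the half-open grid `[t0, t_end)` at `1/fps` (3 s at 10 fps = 30
frames).

**Synthetic data.** `brainscene.synthetic` generates everything the
loaders read — a miniature atlas bundle (bilaterally symmetric ellipsoid
regions, hierarchy root → {CTX → {VISp, MOs}, TH}), cell coordinates
guaranteed inside a chosen region, random binary-branching SWC neurons,
streamline JSON, and Poisson expression volumes — so every pipeline is
testable end to end with known ground truth and no downloads.

## Worked example

```python
from pathlib import Path
from brainscene import (FixtureSpec, Scene, load_atlas,
                        make_mini_atlas, make_synthetic_cells)

make_mini_atlas(FixtureSpec(), Path("atlas"))
atlas = load_atlas("atlas")

scene = Scene(atlas)                      # adds the root outline actor
scene.add_brain_region(["VISp", "MOs"], alpha=0.4)
cells = make_synthetic_cells(atlas, "VISp", 1000, seed=7)
scene.add_actor(cells, kind="points", name="cells")

print(len(scene), "actors")
n_in = sum(atlas.point_in_region(p, "CTX") for p in cells.coordinates)
print(n_in, "of", len(cells), "cells in CTX")
scene.render_screenshot("figure.png", width=800, height=600)
```

prints

```
4 actors
1000 of 1000 cells in CTX
```

— the scene holds the root outline, two region actors colored by their
atlas rgb, and one points actor; every generated cell lies inside CTX
because VISp is one of its substructures; `figure.png` is exactly 800x600.

The same workflow runs without code from a config file:

```bash
brainscene render scene.toml         # regions + data files + outputs
brainscene query atlas cells.npy CTX # per-point structure table (CSV)
brainscene benchmark atlas           # the five standard workload timings
```

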