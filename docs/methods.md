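# Methods

This note records the models, conventions and numerical choices behind
brainscene, what the synthetic data does and does not emulate, and the
known limitations.

## Coordinate and atlas conventions

All physical coordinates are micrometers. Axis order is fixed to
(AP, DV, LR) — anterior→posterior, dorsal→ventral, left→right — matching
voxel indices (i, j, k). Voxel `i` spans the half-open physical interval
`[i*res, (i+1)*res)`, and a point maps to its voxel by floor division, so a
point exactly on a voxel boundary belongs to the higher-index voxel. This
single stated convention makes the brute-force voxel oracle used in the
tests unambiguous.

The annotation volume labels **leaf** structures only; a parent region is
the union of its children and membership is always resolved through the
hierarchy. This mirrors common reference atlases, where e.g. cortex is
never labeled directly but only through its subdivisions. Real annotation
volumes that do label parents directly would need the leaf-only assumption
relaxed; `Atlas.region_ids` already unions the region's own id with its
descendants, so such volumes load and query correctly — the assumption
only matters to the synthetic generator.

Region meshes come from the bundle's mesh store when present; otherwise
they are isosurfaced on demand from the annotation and cached per acronym.
The cache lives on the `Atlas` object and is discarded on reload.

## Isosurfacing

Region and volume surfaces are extracted with marching cubes at the 0.5
level of a binary mask, with one voxel of zero padding so selections
touching the grid border still close. Sampling the mask at voxel centers
puts the 0.5-level halfway between centers, which systematically erodes
thin structures (a single voxel becomes an octahedron of volume 1/6). We
therefore 2x nearest-neighbour supersample the mask first: the extracted
surface then sits on the voxel boundary and mesh volumes track voxel
counts closely (single voxel ≈ 0.71 of its volume; digital balls of radius
4/8/16 voxels are within 3.5 % / 1.2 % / 0.5 % of the analytic sphere
volume, monotonically improving with radius). Optional smoothing uses
Taubin's lambda/mu filter, which unlike plain Laplacian smoothing does not
shrink the mesh; the default is 0 iterations so measured volumes stay
faithful.

## Plane slicing

`slice_mesh(mesh, plane, keep)` keeps the sub-mesh on one side and closes
the cut. Convention: `keep="below"` retains points with
`(p − origin) · normal ≤ 0`; a plane that misses the mesh is a no-op (or
yields an empty mesh), never an error. The open cut produced by the plane
clip is welded, its boundary edges are chained into loops, and each loop
is triangulated by ear clipping in the cut plane. Numerical choices that
matter:

- loop coordinates are normalized to unit scale before clipping, so
  tolerances are scale-free (atlas meshes span 10^2–10^3 µm);
- collinear "ears" (zero area) are clipped without emitting a face — the
  jagged loops that marching-cubes meshes produce contain long collinear
  runs that would otherwise stall the clipper;
- cap orientation is decided by the *summed* cap normal against the
  outward direction, so a single degenerate sliver triangle cannot flip an
  entire cap.

With these choices, kept + complement volume equals the original to
machine precision across hundreds of random planes through ellipsoid,
multi-body glyph and curved tube meshes. Nested boundary loops (an annulus
cross-section, e.g. cutting a torus along its plane) are capped
independently and would be filled incorrectly; none of the supported
actor geometries produce them.

Points actors are sliced per glyph: a sphere is kept or dropped by which
side its *center* falls on, rather than cutting individual glyphs. This
keeps the glyph count meaningful (it equals the count of a per-center
plane-side test) and the vertex layout uniform.

## Tubes, glyphs and containment

Neurite segments and streamlines are swept as 12-sided tubes (configurable)
using parallel-transported frames along the polyline, with fan caps; each
input path yields one connected watertight component. Point sets are
instanced icospheres (subdivision 1, 42 vertices) concatenated without
welding, so the merged mesh has exactly N x 42 vertices.

Point-in-mesh containment uses ray-crossing parity with a fixed,
irrationally oriented ray direction (avoiding axis-aligned edge grazing on
lattice-aligned meshes), implemented as vectorized Moller–Trumbore
intersection chunked over points. Mesh–mesh intersection tests bounding
boxes, then mutual vertex containment, then edge–triangle crossings
restricted to the overlap region — the last step catches surfaces that
cross without either mesh holding a vertex of the other. For
non-watertight meshes containment degrades to a best-effort answer with a
`RuntimeWarning` rather than an exception, since real region meshes are
occasionally imperfect. Centers of mass use the volume centroid for
watertight meshes and the area-weighted surface centroid otherwise.

## Rendering

Rendering is off-screen on the matplotlib Agg backend: no display, no GPU,
deterministic bytes on a given platform (cross-platform pixel identity is
not promised by any rasterizer and is not claimed). The camera pose
(position, focal point, view-up, zoom) maps to an azimuth/elevation view;
roll from the view-up vector is not applied — an accepted approximation of
this backend. Faces get flat Lambert shading from a fixed light. The
rasterized buffer is cropped/padded to the exact requested pixel
dimensions, since figure-size rounding would otherwise drift by one pixel
at odd sizes. Per actor, at most 12 000 triangles are rasterized (stride
subsampled above that); geometry, measurements and exports always use the
full mesh. Points actors draw as screen-space markers at their glyph
centers — rasterizing tens of thousands of tiny spheres as polygons buys
nothing visually and dominates frame time.

HTML export embeds every visible actor's geometry and style as one JSON
block inside a single self-contained document (no external assets),
followed by a small inline canvas wireframe viewer; the geometry count in
the document equals the visible actor count by construction.

## Animation

Keyframes hold an optional camera pose and optional per-actor style
parameters, at strictly increasing times. Interpolation is linear per
scalar component (colors in RGB, view-up renormalized after
interpolation); easing curves are an extension point, not built in. A
parameter absent from a keyframe simply does not key there: its value is
interpolated between the bracketing keyframes that define it and held
constant beyond the last one. Frames are sampled on the half-open grid
`[t0, t_end)` at spacing `1/fps` — `ceil(duration * fps)` frames, exactly
`duration * fps` when the product is integral, so 3 s at 10 fps gives 30
frames with no dangling endpoint frame. Video container encoding is
delegated to external encoders; the module emits numbered PNG sequences.

## Synthetic study conditions

The generators exist so every pipeline is exercisable with known ground
truth and no network access. Defaults, chosen once:

- **Mini atlas**: 40 x 30 x 48 voxels at 25 µm (a 1 x 0.75 x 1.2 mm
  "brain"); hierarchy root → {CTX → {VISp, MOs}, TH}; each leaf is a
  bilaterally symmetric pair of ellipsoids (ellipsoids admit analytic
  volumes and centroids), mirrored exactly about the mid-sagittal plane by
  construction (`mask | mask[:, :, ::-1]`), so each structure is its own
  left–right mirror partner. Leaves are verified disjoint and inside the
  root at generation time; impossible placements raise a generation error.
  Structure ids are fixed per slot (root 1, CTX 2, TH 3, VISp 4, MOs 5).
  The bundle ships meshes for every structure; parent meshes are
  isosurfaces of their leaf-union masks.
- **Cells**: a labeled voxel drawn uniformly, then a uniform offset within
  it — every sample passes `point_in_region` on its source region by
  construction; n = 1000 in the standard conditions.
- **Neurons**: one soma with a single primary neurite; each branch event
  splits a growing tip, so the parsed tree has exactly the requested
  number of bifurcations. Segment length 12 µm with small angular noise.
- **Streamlines**: momentum random walks (20 points, step 1.5 voxels)
  started inside the source region.
- **Expression volumes**: Poisson counts, λ = 10 background / λ = 200
  inside the hot region; thresholding at the midpoint recovers essentially
  every hot voxel because the two distributions are ~27 standard
  deviations apart.

All randomness flows from one seeded generator per call; identical seeds
give byte-identical files. What the fixtures do **not** emulate: realistic
neuroanatomy (region shapes, counts, adjacency), imaging noise or
registration error, non-isotropic resolutions, annotation volumes that
label parent structures, or non-watertight region meshes. Tests passing on
these fixtures therefore validate the geometry, query and export
machinery — not robustness to the messiness of any particular real atlas.

## Problem sizes

The test suite and the acceptance script run at deliberately desk-scale
sizes chosen to exercise every code path while staying fast on one CPU:
1000-point query batches, 50 slicing planes, balls up to radius 16 voxels,
100 round-trip instances, 1000-cell scenes, 30-frame animations at reduced
resolution (96 x 72 to 320 x 240), and benchmark point clouds of 10^3–10^4
by default (the `--sizes` flag scales the benchmark up where desired).

## Known limitations

- One annotation label per voxel; no probabilistic or multi-label atlases.
- NRRD/NIfTI volumes are out of scope (TIFF only); an extension point, not
  a reader.
- No mesh booleans/CSG, decimation, or remeshing beyond optional Taubin
  smoothing.
- The HTML viewer is a wireframe aid, not a full renderer; the embedded
  JSON is the interchange payload.
- Interactive windowing exists only insofar as matplotlib provides it;
  the supported workflow is off-screen export.
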