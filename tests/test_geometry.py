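"""Isosurfacing, slicing, glyphing, tube meshing, and mesh measurements."""

import numpy as np
import pytest
import trimesh

from brainscene.errors import EmptyMeshError, EmptyRegionError
from brainscene.geometry import (
    Plane,
    center_of_mass,
    contains_points,
    distance_between,
    label_isosurface,
    meshes_intersect,
    neuron_to_meshes,
    point_in_mesh,
    points_to_spheres,
    slice_mesh,
    streamlines_to_mesh,
    tube_along_path,
)
from brainscene.io import NeuronMorphology, Streamlines


def digital_ball(radius: int) -> np.ndarray:
    n = 2 * radius + 4
    idx = np.indices((n, n, n)).astype(float) - n / 2 + 0.5
    return (idx**2).sum(axis=0) <= radius**2


class TestIsosurface:
    def test_single_voxel_volume_near_voxel_volume(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        mesh = label_isosurface(mask, resolution=1.0)
        assert mesh.is_watertight
        assert 0.4 <= abs(mesh.volume) <= 1.1

    def test_ball_volume_within_15_percent(self):
        mesh = label_isosurface(digital_ball(8), resolution=1.0)
        analytic = 4 / 3 * np.pi * 8**3
        assert abs(abs(mesh.volume) - analytic) / analytic < 0.15

    def test_ball_error_shrinks_with_radius(self):
        errs = []
        for r in (4, 8, 16):
            mesh = label_isosurface(digital_ball(r), resolution=1.0)
            analytic = 4 / 3 * np.pi * r**3
            errs.append(abs(abs(mesh.volume) - analytic) / analytic)
        assert errs[0] > errs[1] > errs[2]

    def test_resolution_scales_vertices(self):
        mask = digital_ball(4)
        m1 = label_isosurface(mask, resolution=1.0)
        m25 = label_isosurface(mask, resolution=25.0)
        assert np.allclose(m25.vertices, m1.vertices * 25.0)

    def test_threshold_above_max_is_empty_region(self):
        from brainscene.io import VolumeGrid

        grid = VolumeGrid(np.ones((8, 8, 8)), 1.0)
        with pytest.raises(EmptyRegionError):
            label_isosurface(grid, 2.0)

    def test_border_touching_mask_still_closes(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        mesh = label_isosurface(mask, resolution=1.0)
        assert mesh.is_watertight


class TestSlicing:
    def test_cube_halved_by_center_plane(self):
        cube = trimesh.creation.box(extents=[100.0] * 3)
        half = slice_mesh(cube, Plane([0, 0, 0], [1, 0, 0]), keep="below")
        assert half.is_watertight
        assert abs(half.volume) == pytest.approx(0.5 * 100**3, rel=0.01)

    def test_plane_missing_mesh_is_noop(self):
        cube = trimesh.creation.box(extents=[100.0] * 3)
        out = slice_mesh(cube, Plane([1000, 0, 0], [1, 0, 0]), keep="below")
        assert abs(out.volume) == pytest.approx(abs(cube.volume))

    def test_fully_discarded_gives_empty_mesh(self):
        cube = trimesh.creation.box(extents=[100.0] * 3)
        out = slice_mesh(cube, Plane([-1000, 0, 0], [1, 0, 0]), keep="below")
        assert len(out.faces) == 0

    def test_volume_conserved_over_random_planes(self, rng):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=40.0)
        total = abs(sphere.volume)
        for _ in range(25):
            plane = Plane(rng.normal(0, 15, 3), rng.normal(size=3))
            below = slice_mesh(sphere, plane, keep="below")
            above = slice_mesh(sphere, plane, keep="above")
            assert abs(below.volume) + abs(above.volume) == pytest.approx(total, rel=0.01)


class TestGlyphs:
    def test_vertex_count_is_points_times_template(self, rng):
        pts = rng.uniform(0, 100, (10, 3))
        mesh = points_to_spheres(pts, radius=3.0, subdivisions=1)
        assert len(mesh.vertices) == 10 * 42

    def test_single_point_bbox(self):
        mesh = points_to_spheres(np.zeros((1, 3)), radius=7.0)
        extent = mesh.bounds[1] - mesh.bounds[0]
        assert np.allclose(extent, 14.0, rtol=0.05)

    def test_centroid_matches_mean(self, rng):
        pts = rng.uniform(0, 500, (2000, 3))
        mesh = points_to_spheres(pts, radius=4.0, subdivisions=0)
        assert np.linalg.norm(mesh.vertices.mean(axis=0) - pts.mean(axis=0)) < 4.0

    def test_empty_points_empty_mesh(self):
        assert len(points_to_spheres(np.zeros((0, 3)), radius=1.0).faces) == 0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            points_to_spheres(np.zeros((1, 3)), radius=0.0)


class TestNeuronMeshing:
    def test_single_soma_gives_one_sphere_part(self):
        m = NeuronMorphology([1], [1], [(0.0, 0.0, 0.0)], [5.0], [-1])
        parts = neuron_to_meshes(m)
        assert set(parts) == {"soma"}
        assert abs(parts["soma"].volume) == pytest.approx(4 / 3 * np.pi * 125, rel=0.1)

    def test_toy_neuron_parts(self, toy_swc):
        from brainscene.io import read_swc

        parts = neuron_to_meshes(read_swc(toy_swc))
        assert set(parts) == {"soma", "dendrites"}
        # two tube segments, each watertight with its own vertices
        assert parts["dendrites"].body_count == 2

    def test_total_tube_length_matches_segments(self, tmp_path):
        from brainscene.io import read_swc
        from brainscene.synthetic import make_synthetic_neuron

        m = read_swc(make_synthetic_neuron(tmp_path / "n.swc", seed=9, n_branch_points=3))
        parts = neuron_to_meshes(m, neurite_radius=0.5)
        area = sum(p.area for name, p in parts.items() if name != "soma")
        # lateral tube area ~ 2*pi*r*L (12-gon: 1.1% low); caps add ~2*pi*r^2 per segment
        n_segments = len(m.segment_lengths())
        expected = 2 * np.pi * 0.5 * m.segment_lengths().sum() + n_segments * 2 * np.pi * 0.25
        assert area == pytest.approx(expected, rel=0.05)


class TestStreamlineMeshing:
    def test_straight_tube_area(self):
        s = Streamlines([np.array([[0, 0, 0], [0, 0, 200.0]])])
        mesh = streamlines_to_mesh(s, radius=2.0)
        assert mesh.area == pytest.approx(2 * np.pi * 2 * 200, rel=0.10)

    def test_component_per_path(self, rng):
        paths = [rng.normal(k * 100, 5, (10, 3)) for k in range(4)]
        mesh = streamlines_to_mesh(Streamlines(paths), radius=1.0)
        assert mesh.body_count == 4

    def test_empty_streamlines_empty_mesh(self):
        assert len(streamlines_to_mesh(Streamlines([]), radius=1.0).faces) == 0


class TestMeasurements:
    def test_distance_between_spheres(self):
        a = trimesh.creation.icosphere(2, 1.0)
        b = a.copy()
        b.apply_translation([10.0, 0, 0])
        assert distance_between(a, b) == pytest.approx(10.0, abs=1e-6)
        assert distance_between(a, a) == 0.0

    def test_cube_center_of_mass(self):
        cube = trimesh.creation.box(extents=[2.0, 2.0, 2.0])
        cube.apply_translation([5.0, -3.0, 7.0])
        assert np.allclose(center_of_mass(cube), [5.0, -3.0, 7.0], atol=1e-6)

    def test_empty_mesh_errors(self):
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int), process=False)
        with pytest.raises(EmptyMeshError):
            center_of_mass(empty)


class TestContainmentAndIntersection:
    def test_sphere_pair_intersection(self):
        a = trimesh.creation.icosphere(2, 1.0)
        far = a.copy()
        far.apply_translation([10.0, 0, 0])
        near = a.copy()
        near.apply_translation([1.0, 0, 0])
        assert not meshes_intersect(a, far)
        assert meshes_intersect(a, near)

    def test_crossing_surfaces_without_contained_vertices(self):
        slab_x = trimesh.creation.box(extents=[100.0, 1.0, 1.0])
        slab_y = trimesh.creation.box(extents=[1.0, 100.0, 1.0])
        assert meshes_intersect(slab_x, slab_y)

    def test_point_in_cube(self):
        cube = trimesh.creation.box(extents=[2.0] * 3)
        assert point_in_mesh([0, 0, 0], cube)
        assert not point_in_mesh([5, 0, 0], cube)

    def test_containment_agrees_with_voxel_oracle(self, rng):
        r = 8
        ball = digital_ball(r)
        mesh = label_isosurface(ball, resolution=1.0)
        n = ball.shape[0]
        pts = rng.uniform(0, n, (500, 3))
        inside_mesh = contains_points(mesh, pts)
        idx = np.floor(pts).astype(int)
        inside_vox = ball[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert (inside_mesh == inside_vox).mean() >= 0.98

    def test_open_mesh_warns_but_answers(self):
        cube = trimesh.creation.box(extents=[2.0] * 3)
        open_mesh = trimesh.Trimesh(cube.vertices, cube.faces[:-2], process=False)
        with pytest.warns(RuntimeWarning, match="non-watertight"):
            contains_points(open_mesh, [[0.0, 0.0, 0.0]])


class TestPlane:
    def test_normal_normalized(self):
        p = Plane([0, 0, 0], [0, 0, 10.0])
        assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-9)

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            Plane([0, 0, 0], [0, 0, 0])
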