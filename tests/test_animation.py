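"""Keyframe ordering, interpolation, and frame-sequence generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainscene.animation import Animation
from brainscene.errors import StructureLookupError
from brainscene.scene import CameraPose, Scene, camera_preset


@pytest.fixture()
def scene(atlas):
    return Scene(atlas)


@pytest.fixture()
def cams(atlas):
    b = atlas.region_mesh("root").bounds
    return camera_preset("frontal", b), camera_preset("sagittal", b)


class TestKeyframes:
    def test_insertion_keeps_time_order(self, scene, cams):
        anim = Animation(scene, fps=10)
        anim.add_keyframe(0.0, camera=cams[0])
        anim.add_keyframe(2.0, camera=cams[1])
        anim.add_keyframe(1.0)
        assert [k.time for k in anim.keyframes] == [0.0, 1.0, 2.0]

    def test_duplicate_time_rejected(self, scene, cams):
        anim = Animation(scene, fps=10).add_keyframe(0.0, camera=cams[0])
        with pytest.raises(ValueError, match="already exists"):
            anim.add_keyframe(0.0, camera=cams[1])

    def test_unknown_actor_name_rejected(self, scene):
        anim = Animation(scene, fps=10)
        with pytest.raises(StructureLookupError):
            anim.add_keyframe(0.0, actor_params={"ghost": {"alpha": 0.5}})


class TestInterpolation:
    def test_linear_midpoint_of_position(self, scene):
        c0 = CameraPose([0, 0, 0], [100, 0, 0])
        c1 = CameraPose([10, 0, 0], [100, 0, 0])
        anim = Animation(scene, fps=10)
        anim.add_keyframe(0.0, camera=c0).add_keyframe(2.0, camera=c1)
        cam, _ = anim.state_at(1.0)
        assert np.allclose(cam.position, [5, 0, 0])

    def test_keyframe_times_reproduce_exact_values(self, scene, cams):
        anim = Animation(scene, fps=10)
        anim.add_keyframe(0.0, camera=cams[0], actor_params={"root": {"alpha": 0.9}})
        anim.add_keyframe(3.0, camera=cams[1], actor_params={"root": {"alpha": 0.1}})
        for t, cam_exp, alpha_exp in ((0.0, cams[0], 0.9), (3.0, cams[1], 0.1)):
            cam, params = anim.state_at(t)
            assert np.allclose(cam.position, cam_exp.position)
            assert np.allclose(cam.focal_point, cam_exp.focal_point)
            assert params["root"]["alpha"] == pytest.approx(alpha_exp)

    def test_alpha_linear(self, scene, cams):
        anim = Animation(scene, fps=10)
        anim.add_keyframe(0.0, camera=cams[0], actor_params={"root": {"alpha": 1.0}})
        anim.add_keyframe(3.0, actor_params={"root": {"alpha": 0.0}})
        _, params = anim.state_at(1.5)
        assert params["root"]["alpha"] == pytest.approx(0.5)

    def test_param_held_after_last_keyframe_defining_it(self, scene, cams):
        anim = Animation(scene, fps=10)
        anim.add_keyframe(0.0, camera=cams[0], actor_params={"root": {"alpha": 0.7}})
        anim.add_keyframe(2.0, camera=cams[1])
        anim.add_keyframe(4.0, camera=cams[0])
        _, params = anim.state_at(3.0)
        assert params["root"]["alpha"] == pytest.approx(0.7)

    def test_time_outside_range_rejected(self, scene, cams):
        anim = Animation(scene, fps=10)
        anim.add_keyframe(1.0, camera=cams[0]).add_keyframe(2.0, camera=cams[1])
        for t in (0.5, 2.5):
            with pytest.raises(ValueError, match="outside"):
                anim.state_at(t)

    def test_continuity_near_interior_keyframe(self, scene, cams):
        anim = Animation(scene, fps=10)
        anim.add_keyframe(0.0, camera=cams[0], actor_params={"root": {"alpha": 1.0}})
        anim.add_keyframe(1.0, actor_params={"root": {"alpha": 0.4}})
        anim.add_keyframe(2.0, camera=cams[1], actor_params={"root": {"alpha": 0.0}})
        eps = 1e-6
        for t in (1.0, 0.5):
            a_minus = anim.state_at(t - eps)[1]["root"]["alpha"]
            a_plus = anim.state_at(t + eps)[1]["root"]["alpha"]
            assert abs(a_plus - a_minus) < 1e-4
            c_minus = anim.state_at(t - eps)[0].position
            c_plus = anim.state_at(t + eps)[0].position
            assert np.linalg.norm(c_plus - c_minus) < 1e-2


class TestFrameGrid:
    def test_three_seconds_ten_fps_thirty_frames(self, scene, cams):
        anim = Animation(scene, fps=10)
        anim.add_keyframe(0.0, camera=cams[0]).add_keyframe(3.0, camera=cams[1])
        assert len(anim.frame_times()) == 30

    def test_one_fps_two_seconds(self, scene, cams):
        anim = Animation(scene, fps=1)
        anim.add_keyframe(0.0, camera=cams[0]).add_keyframe(2.0, camera=cams[1])
        assert np.allclose(anim.frame_times(), [0.0, 1.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        duration=st.floats(0.2, 8.0),
        fps=st.sampled_from([1, 2, 5, 10, 24, 30]),
    )
    def test_frame_count_matches_half_open_grid(self, duration, fps):
        """Count equals the brute-force number of grid points in [0, d)."""
        anim = Animation.__new__(Animation)
        anim.fps = float(fps)
        anim.keyframes = [type("K", (), {"time": 0.0})(), type("K", (), {"time": duration})()]
        k, brute = 0, 0
        while k / fps < duration - 1e-9:
            brute += 1
            k += 1
        assert len(anim.frame_times()) == brute

    def test_frames_written_with_uniform_dimensions(self, atlas, tmp_path, cams):
        from PIL import Image

        scene = Scene(atlas)
        anim = Animation(scene, fps=5)
        anim.add_keyframe(0.0, camera=cams[0], actor_params={"root": {"alpha": 0.8}})
        anim.add_keyframe(0.6, camera=cams[1], actor_params={"root": {"alpha": 0.2}})
        files = anim.write_frames(tmp_path / "frames", width=96, height=72)
        assert len(files) == 3
        assert [f.name for f in files] == ["frame_00000.png", "frame_00001.png", "frame_00002.png"]
        assert {Image.open(f).size for f in files} == {(96, 72)}
        # scene styles restored afterwards
        assert scene.get_actor("root").style.alpha == pytest.approx(0.1)

    def test_single_keyframe_cannot_generate(self, scene, cams):
        anim = Animation(scene, fps=10).add_keyframe(0.0, camera=cams[0])
        with pytest.raises(ValueError, match="2 keyframes"):
            anim.frame_times()
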