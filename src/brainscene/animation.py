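"""Keyframe animation: interpolate camera pose and actor style parameters
between keyframes and emit a numbered frame sequence.

Frames are sampled on the half-open time grid ``[t0, t_end)`` at spacing
``1/fps``, so a 3 s animation at 10 fps yields exactly 30 frames.
Interpolation is linear per scalar component (colors interpolate in RGB,
the camera view-up vector is renormalized after interpolation); a parameter
absent from a keyframe simply does not key that parameter there -- its
value comes from the bracketing keyframes that do define it, held constant
beyond the last one. Easing curves are an extension point, not built in.

Video container encoding is delegated to external encoders; this module
emits ``frame_00000.png ...`` sequences only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colors as mcolors

from .errors import StructureLookupError
from .scene import CameraPose, Scene

__all__ = ["Keyframe", "Animation"]

_INTERP_FIELDS = ("alpha", "line_width", "color")  # 'visible' is step-held


@dataclass
class Keyframe:
    """Camera pose and/or per-actor style parameters at one time point."""

    time: float
    camera: CameraPose | None = None
    actor_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("keyframe time must be >= 0")


def _lerp(a, b, w):
    return a + (b - a) * w


class Animation:
    """An ordered list of keyframes over a scene, with a frame rate.

    At least two keyframes are required to generate frames.
    """

    def __init__(self, scene: Scene, fps: float = 10.0):
        if fps <= 0:
            raise ValueError("fps must be positive")
        self.scene = scene
        self.fps = float(fps)
        self.keyframes: list[Keyframe] = []

    # -- building -----------------------------------------------------------

    def add_keyframe(self, time: float, camera: CameraPose | None = None, actor_params: dict | None = None) -> "Animation":
        """Insert a keyframe in time order.

        Raises ``ValueError`` for a duplicate time and
        :class:`StructureLookupError` for an actor name not in the scene.
        """
        time = float(time)
        if any(abs(k.time - time) < 1e-9 for k in self.keyframes):
            raise ValueError(f"a keyframe already exists at t={time}")
        actor_params = dict(actor_params or {})
        for name in actor_params:
            self.scene.get_actor(name)  # raises on unknown names
        kf = Keyframe(time, camera, actor_params)
        self.keyframes.append(kf)
        self.keyframes.sort(key=lambda k: k.time)
        return self

    @property
    def duration(self) -> float:
        if len(self.keyframes) < 2:
            return 0.0
        return self.keyframes[-1].time - self.keyframes[0].time

    # -- interpolation ------------------------------------------------------

    def _bracket(self, records: list[tuple[float, object]], time: float):
        """(previous, next) records around ``time`` in a per-parameter
        timeline; either may be None at the ends."""
        prev = nxt = None
        for t, v in records:
            if t <= time + 1e-12:
                prev = (t, v)
            elif nxt is None:
                nxt = (t, v)
                break
        return prev, nxt

    def _interp_value(self, key: str, a, b, w):
        if key == "color":
            ca, cb = np.array(mcolors.to_rgb(a)), np.array(mcolors.to_rgb(b))
            return mcolors.to_hex(_lerp(ca, cb, w))
        return _lerp(float(a), float(b), w)

    def state_at(self, time: float) -> tuple[CameraPose, dict]:
        """The interpolated camera pose and actor-parameter map at a time
        within the keyframed range (inclusive)."""
        if len(self.keyframes) < 2:
            raise ValueError("state_at needs at least 2 keyframes")
        t0, t1 = self.keyframes[0].time, self.keyframes[-1].time
        if not (t0 - 1e-9 <= time <= t1 + 1e-9):
            raise ValueError(f"time {time} outside the keyframed range [{t0}, {t1}]")

        cam_records = [(k.time, k.camera) for k in self.keyframes if k.camera is not None]
        prev, nxt = self._bracket(cam_records, time)
        if prev is None and nxt is None:
            camera = self.scene.camera.copy()
        elif prev is None:
            camera = nxt[1].copy()
        elif nxt is None or nxt[1] is prev[1]:
            camera = prev[1].copy()
        else:
            (ta, ca), (tb, cb) = prev, nxt
            w = 0.0 if tb == ta else (time - ta) / (tb - ta)
            up = _lerp(ca.viewup, cb.viewup, w)
            n = np.linalg.norm(up)
            up = ca.viewup if n < 1e-12 else up / n
            camera = CameraPose(
                _lerp(ca.position, cb.position, w),
                _lerp(ca.focal_point, cb.focal_point, w),
                up,
                _lerp(ca.zoom, cb.zoom, w),
            )

        params: dict[str, dict] = {}
        names = {n for k in self.keyframes for n in k.actor_params}
        for name in names:
            out: dict = {}
            keys = {p for k in self.keyframes for p in k.actor_params.get(name, {})}
            for key in keys:
                records = [
                    (k.time, k.actor_params[name][key])
                    for k in self.keyframes
                    if name in k.actor_params and key in k.actor_params[name]
                ]
                prev, nxt = self._bracket(records, time)
                if prev is None:
                    out[key] = records[0][1]
                elif nxt is None:
                    out[key] = prev[1]
                elif key in _INTERP_FIELDS and key != "visible":
                    (ta, va), (tb, vb) = prev, nxt
                    w = 0.0 if tb == ta else (time - ta) / (tb - ta)
                    out[key] = self._interp_value(key, va, vb, w)
                else:  # step-hold (visible and any non-numeric parameter)
                    out[key] = prev[1]
            params[name] = out
        return camera, params

    # -- frame generation ---------------------------------------------------

    def frame_times(self) -> np.ndarray:
        """Sample times on the half-open grid [t0, t_end) at 1/fps."""
        if len(self.keyframes) < 2:
            raise ValueError("frame generation needs at least 2 keyframes")
        t0 = self.keyframes[0].time
        n = max(1, math.ceil(self.duration * self.fps - 1e-9))
        return t0 + np.arange(n) / self.fps

    def write_frames(self, out_dir, width: int = 320, height: int = 240) -> list[Path]:
        """Render every frame to ``out_dir/frame_#####.png``; returns the
        file list in time order."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        times = self.frame_times()
        saved_styles = {a.name: a.style.copy() for a in self.scene.actors}
        files = []
        from .actors import set_style

        try:
            for i, t in enumerate(times):
                camera, params = self.state_at(float(t))
                for name, fields in params.items():
                    set_style(self.scene.get_actor(name), **fields)
                f = out_dir / f"frame_{i:05d}.png"
                self.scene.render_screenshot(f, width=width, height=height, camera=camera)
                files.append(f)
        finally:
            for a in self.scene.actors:
                if a.name in saved_styles:
                    a.style = saved_styles[a.name]
        return files
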