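"""Actors: renderable objects with identity and style.

An :class:`Actor` bundles a mesh with a name, a kind, a :class:`Style`
(color, transparency, visibility) and a provenance string (file path or
atlas acronym). :func:`make_actor` dispatches any supported payload --
a raw mesh, a coordinate table, a neuron morphology, a streamline bundle,
or a scalar volume -- to the matching geometry constructor.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from matplotlib import colors as mcolors

from .errors import BrainsceneError
from .geometry import (
    label_isosurface,
    neuron_to_meshes,
    points_to_spheres,
    streamlines_to_mesh,
    validate_mesh,
)
from .io import NeuronMorphology, PointsData, Streamlines, VolumeGrid

__all__ = ["Style", "Actor", "ActorKind", "make_actor", "set_style", "DEFAULT_STYLES"]

ActorKind = ("region", "points", "neuron_part", "streamlines", "volume", "user_mesh", "probe")

#: Per-kind default styles; regions get the structure's own rgb at add time.
DEFAULT_STYLES = {
    "region": dict(color="#9f9f9f", alpha=0.3),
    "root": dict(color="#d3d3d3", alpha=0.1),
    "points": dict(color="salmon", alpha=1.0),
    "neuron_part": dict(color="#cc3311", alpha=1.0),
    "streamlines": dict(color="#66ccee", alpha=0.8),
    "volume": dict(color="#aa3377", alpha=0.6),
    "user_mesh": dict(color="#999999", alpha=1.0),
    "probe": dict(color="#222222", alpha=1.0),
}

_NEURON_PART_COLORS = {"soma": "#1c1c1c", "axon": "#4477aa", "dendrites": "#cc3311", "other": "#bbbbbb"}


def _normalize_color(color) -> str:
    """Validate a named or hex color and normalize it to lowercase hex."""
    try:
        return mcolors.to_hex(color)
    except ValueError:
        suggestions = difflib.get_close_matches(
            str(color), mcolors.CSS4_COLORS.keys(), n=3, cutoff=0.5
        )
        hint = f" (did you mean: {', '.join(suggestions)}?)" if suggestions else ""
        raise ValueError(f"unknown color {color!r}{hint}") from None


@dataclass
class Style:
    """Visual style of an actor."""

    color: str = "#999999"
    alpha: float = 1.0
    line_width: float = 1.0
    visible: bool = True

    def __post_init__(self):
        self.color = _normalize_color(self.color)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.line_width < 0:
            raise ValueError("line_width must be non-negative")

    def copy(self) -> "Style":
        return replace(self)


@dataclass
class Actor:
    """One renderable object in a scene."""

    name: str
    kind: str
    mesh: trimesh.Trimesh
    style: Style = field(default_factory=Style)
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ActorKind:
            raise ValueError(f"unknown actor kind {self.kind!r}; one of {ActorKind}")
        self.mesh = validate_mesh(self.mesh)

    @property
    def visible(self) -> bool:
        return self.style.visible and len(self.mesh.faces) > 0


def _style_for(kind: str, style) -> Style:
    if isinstance(style, Style):
        return style.copy()
    base = dict(DEFAULT_STYLES.get(kind, {}))
    if isinstance(style, dict):
        base.update(style)
    return Style(**base)


def make_actor(
    payload,
    kind: str | None = None,
    style: Style | dict | None = None,
    name: str | None = None,
    source: str = "",
    **geometry_kwargs,
):
    """Turn a payload into one Actor (or, for neurons, one per part).

    Dispatch: ``PointsData`` -> sphere glyphs; ``NeuronMorphology`` -> one
    actor per part (soma/axon/dendrites); ``Streamlines`` -> merged tubes;
    ``VolumeGrid`` -> threshold isosurface (pass ``threshold=``);
    ``trimesh.Trimesh`` -> used as is. The payload is never mutated.

    Extra keyword arguments go to the geometry constructor (``radius``,
    ``subdivisions``, ``threshold``, ``soma_radius_scale``, ...).
    """
    if isinstance(payload, trimesh.Trimesh):
        kind = kind or "user_mesh"
        if kind not in ("user_mesh", "region", "probe", "volume"):
            raise TypeError(f"a raw mesh cannot be actor kind {kind!r}")
        return Actor(name or "mesh", kind, payload.copy(), _style_for(kind, style), source)

    if isinstance(payload, PointsData):
        if kind not in (None, "points"):
            raise TypeError(f"PointsData payload cannot be kind {kind!r}")
        radius = geometry_kwargs.pop("radius", 15.0)
        mesh = points_to_spheres(payload, radius=radius, **geometry_kwargs)
        actor = Actor(name or "points", "points", mesh, _style_for("points", style), source)
        actor.metadata["centers"] = payload.coordinates.copy()
        actor.metadata["radius"] = radius
        return actor

    if isinstance(payload, NeuronMorphology):
        if kind not in (None, "neuron_part"):
            raise TypeError(f"NeuronMorphology payload cannot be kind {kind!r}")
        parts = neuron_to_meshes(payload, **geometry_kwargs)
        actors = []
        base = name or "neuron"
        for part, mesh in parts.items():
            part_style = (
                _style_for("neuron_part", style)
                if style is not None
                else Style(color=_NEURON_PART_COLORS.get(part, "#bbbbbb"))
            )
            actors.append(Actor(f"{base}.{part}", "neuron_part", mesh, part_style, source))
        return actors

    if isinstance(payload, Streamlines):
        if kind not in (None, "streamlines"):
            raise TypeError(f"Streamlines payload cannot be kind {kind!r}")
        radius = geometry_kwargs.pop("radius", 8.0)
        mesh = streamlines_to_mesh(payload, radius=radius, **geometry_kwargs)
        return Actor(
            name or "streamlines", "streamlines", mesh, _style_for("streamlines", style), source
        )

    if isinstance(payload, VolumeGrid):
        if kind not in (None, "volume"):
            raise TypeError(f"VolumeGrid payload cannot be kind {kind!r}")
        if "threshold" not in geometry_kwargs:
            raise TypeError("volume payloads need a threshold= keyword")
        threshold = geometry_kwargs.pop("threshold")
        mesh = label_isosurface(payload, threshold, **geometry_kwargs)
        return Actor(name or "volume", "volume", mesh, _style_for("volume", style), source)

    raise TypeError(f"cannot build an actor from {type(payload).__name__}")


def set_style(actor: Actor, **fields) -> Actor:
    """Update only the supplied style fields, validating each; returns the
    actor for chaining."""
    known = {"color", "alpha", "line_width", "visible"}
    unknown = set(fields) - known
    if unknown:
        raise ValueError(f"unknown style fields: {sorted(unknown)}")
    merged = {
        "color": actor.style.color,
        "alpha": actor.style.alpha,
        "line_width": actor.style.line_width,
        "visible": actor.style.visible,
    }
    merged.update(fields)
    actor.style = Style(**merged)  # Style.__post_init__ validates
    return actor
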