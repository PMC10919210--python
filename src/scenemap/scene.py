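"""The scene: styled drawing primitives in normalized figure coordinates.

Every layout operation in the package emits primitives — rects, lines,
polylines, texts and markers — positioned in the unit square (origin
bottom-left, y up), plus legend models. The scene serializes to a
canonical JSON document (sorted keys, floats at 1e-6 precision) so two
scenes are equal exactly when their documents are byte-identical; that
document is the primary test artifact, and rendering is a thin backend
over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

from .datamodel import SceneMapError

#: Coordinates may bleed slightly outside the unit square (labels).
BLEED = 0.01

_KINDS = ("rect", "line", "polyline", "text", "marker")


def _round6(x: float) -> float:
    return round(float(x), 6)


@dataclass
class Primitive:
    """One styled drawing element.

    Geometry fields used per kind:
      rect      — x, y, w, h
      line      — points (2)
      polyline  — points (>= 2)
      text      — x, y, text, anchor, rotation
      marker    — x, y, shape, radius

    ``tags`` carries semantic labels (e.g. row/col ids on heatmap cells)
    used by tests and dropped by renderers.
    """

    kind: str
    x: float | None = None
    y: float | None = None
    w: float | None = None
    h: float | None = None
    points: list[tuple[float, float]] | None = None
    text: str | None = None
    anchor: str | None = None  # start | middle | end
    rotation: float = 0.0
    shape: str | None = None
    radius: float | None = None
    fill: str | None = None
    stroke: str | None = None
    stroke_width: float | None = None
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SceneMapError(f"unknown primitive kind {self.kind!r}")

    def coordinates(self) -> list[tuple[float, float]]:
        if self.points is not None:
            return [(float(px), float(py)) for px, py in self.points]
        pts = [(float(self.x), float(self.y))]
        if self.kind == "rect":
            pts.append((float(self.x) + float(self.w), float(self.y) + float(self.h)))
        return pts

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"kind": self.kind}
        for name in ("x", "y", "w", "h", "radius", "stroke_width"):
            v = getattr(self, name)
            if v is not None:
                d[name] = _round6(v)
        if self.points is not None:
            d["points"] = [[_round6(px), _round6(py)] for px, py in self.points]
        for name in ("text", "anchor", "shape", "fill", "stroke"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        if self.rotation:
            d["rotation"] = _round6(self.rotation)
        if self.tags:
            d["tags"] = dict(sorted(self.tags.items()))
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Primitive":
        kw = dict(d)
        if "points" in kw:
            kw["points"] = [(p[0], p[1]) for p in kw["points"]]
        return cls(**kw)


def rect(x, y, w, h, fill=None, stroke=None, stroke_width=None, tags=None) -> Primitive:
    return Primitive(
        kind="rect", x=x, y=y, w=w, h=h, fill=fill, stroke=stroke,
        stroke_width=stroke_width, tags=tags or {},
    )


def line(p0, p1, stroke="#000000ff", stroke_width=0.001, tags=None) -> Primitive:
    return Primitive(
        kind="line", points=[tuple(p0), tuple(p1)], stroke=stroke,
        stroke_width=stroke_width, tags=tags or {},
    )


def polyline(points, stroke="#000000ff", stroke_width=0.001, tags=None) -> Primitive:
    return Primitive(
        kind="polyline", points=[tuple(p) for p in points], stroke=stroke,
        stroke_width=stroke_width, tags=tags or {},
    )


def text(x, y, s, anchor="middle", rotation=0.0, fill="#000000ff", tags=None) -> Primitive:
    return Primitive(
        kind="text", x=x, y=y, text=s, anchor=anchor, rotation=rotation,
        fill=fill, tags=tags or {},
    )


def marker(x, y, shape="circle", radius=0.005, fill="#000000ff", stroke=None, tags=None) -> Primitive:
    return Primitive(
        kind="marker", x=x, y=y, shape=shape, radius=radius, fill=fill,
        stroke=stroke, tags=tags or {},
    )


@dataclass
class Scene:
    """A flat, ordered list of primitives plus document metadata."""

    primitives: list[Primitive] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def add(self, prims: Iterable[Primitive]) -> None:
        self.primitives.extend(prims)

    def validate(self) -> None:
        lo, hi = -BLEED, 1.0 + BLEED
        for p in self.primitives:
            for cx, cy in p.coordinates():
                if not (lo <= cx <= hi and lo <= cy <= hi):
                    raise SceneMapError(
                        f"primitive {p.kind} coordinate ({cx}, {cy}) outside "
                        f"[{lo}, {hi}]"
                    )

    def by_kind(self, kind: str) -> list[Primitive]:
        return [p for p in self.primitives if p.kind == kind]

    def tagged(self, **tags: str) -> list[Primitive]:
        return [
            p
            for p in self.primitives
            if all(p.tags.get(k) == v for k, v in tags.items())
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Scene):
            return NotImplemented
        return serialize_scene(self) == serialize_scene(other)


def serialize_scene(scene: Scene) -> str:
    """Canonical text form: sorted keys, floats at 1e-6; equality of
    documents is equality of layouts."""
    doc = {
        "format": "scenemap-scene/1",
        "meta": scene.meta,
        "primitives": [p.to_dict() for p in scene.primitives],
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"), allow_nan=False)


def deserialize_scene(document: str) -> Scene:
    doc = json.loads(document)
    if doc.get("format") != "scenemap-scene/1":
        raise SceneMapError("not a scenemap scene document")
    return Scene(
        primitives=[Primitive.from_dict(d) for d in doc["primitives"]],
        meta=doc.get("meta", {}),
    )


@dataclass(frozen=True)
class Legend:
    """One legend block: categorical patches, a colorbar, marker shapes,
    or reference dot sizes. ``entries`` are (label, swatch) pairs where the
    swatch is a small descriptor dict (color / ramp / marker / radius)."""

    title: str
    kind: str  # categorical_patches | colorbar | marker_set | size_set
    entries: tuple[tuple[str, tuple[tuple[str, Any], ...]], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("categorical_patches", "colorbar", "marker_set", "size_set"):
            raise SceneMapError(f"unknown legend kind {self.kind!r}")
        labels = [l for l, _ in self.entries]
        if len(labels) != len(set(labels)):
            raise SceneMapError(f"duplicate entry labels in legend {self.title!r}")

    @classmethod
    def make(cls, title: str, kind: str, entries: Sequence[tuple[str, dict]]) -> "Legend":
        frozen = tuple((str(l), tuple(sorted(sw.items()))) for l, sw in entries)
        return cls(title=title, kind=kind, entries=frozen)

    def entry_swatches(self) -> list[tuple[str, dict]]:
        return [(l, dict(sw)) for l, sw in self.entries]


def build_legends(requests: Sequence[Legend]) -> list[Legend]:
    """Collapse duplicate legends, preserving first-use order.

    Callers append the main-heatmap colorbar first, so it leads the list.
    """
    out: list[Legend] = []
    seen: set[Legend] = set()
    for leg in requests:
        if leg not in seen:
            out.append(leg)
            seen.add(leg)
    return out
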