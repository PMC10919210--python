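"""Rendering backends: the scene drawn to SVG or PNG, geometry untouched.

The scene is the source of truth; rendering only maps normalized figure
coordinates to pixels (flipping y for SVG) and draws each primitive in
order. Legends are drawn from their models into the reserved right-hand
column.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence
from xml.sax.saxutils import escape

from .colors import ramp_lookup
from .datamodel import SceneMapError
from .scene import Legend, Primitive, Scene

DEFAULT_SIZE = 900  # pixels per figure side
_FONT_PX = 11


def _hex_to_svg(color: str) -> tuple[str, float]:
    """8-digit hex RGBA -> (6-digit hex, opacity)."""
    c = color.lstrip("#")
    if len(c) == 6:
        return "#" + c, 1.0
    return "#" + c[:6], int(c[6:8], 16) / 255.0


def _marker_points(shape: str, cx: float, cy: float, r: float) -> list[tuple[float, float]]:
    if shape == "square":
        return [(cx - r, cy - r), (cx + r, cy - r), (cx + r, cy + r), (cx - r, cy + r)]
    if shape == "triangle":
        return [(cx, cy - r), (cx + r * 0.866, cy + r / 2), (cx - r * 0.866, cy + r / 2)]
    if shape == "diamond":
        return [(cx, cy - r), (cx + r, cy), (cx, cy + r), (cx - r, cy)]
    if shape == "star":
        pts = []
        for k in range(10):
            rad = r if k % 2 == 0 else r * 0.45
            ang = -math.pi / 2 + k * math.pi / 5
            pts.append((cx + rad * math.cos(ang), cy + rad * math.sin(ang)))
        return pts
    raise SceneMapError(f"unknown marker shape {shape!r}")


def render(
    scene: Scene,
    path,
    fmt: str | None = None,
    legends: Sequence[Legend] = (),
    size: int = DEFAULT_SIZE,
) -> None:
    """Write the scene (plus optional legends) as SVG or PNG."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "svg":
        path.write_text(render_svg(scene, legends=legends, size=size))
    elif fmt == "png":
        _render_png(scene, path, legends=legends, size=size)
    else:
        raise SceneMapError(f"unknown output format {fmt!r} (use svg or png)")


def render_svg(scene: Scene, legends: Sequence[Legend] = (), size: int = DEFAULT_SIZE) -> str:
    W = H = float(size)

    def X(x: float) -> float:
        return round(x * W, 2)

    def Y(y: float) -> float:
        return round((1.0 - y) * H, 2)

    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">',
        f'<rect x="0" y="0" width="{size}" height="{size}" fill="#ffffff"/>',
    ]
    for p in scene.primitives + list(_legend_primitives(legends)):
        out.append(_svg_primitive(p, X, Y, W))
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _svg_primitive(p: Primitive, X, Y, W: float) -> str:
    style = []
    if p.fill is not None:
        c, o = _hex_to_svg(p.fill)
        style.append(f'fill="{c}"')
        if o < 1.0:
            style.append(f'fill-opacity="{o:.3f}"')
    elif p.kind in ("rect", "marker"):
        style.append('fill="none"')
    if p.stroke is not None:
        c, o = _hex_to_svg(p.stroke)
        style.append(f'stroke="{c}"')
        if o < 1.0:
            style.append(f'stroke-opacity="{o:.3f}"')
        style.append(f'stroke-width="{max(0.5, (p.stroke_width or 0.001) * W):.2f}"')
    s = " ".join(style)
    if p.kind == "rect":
        return (
            f'<rect x="{X(p.x)}" y="{Y(p.y + p.h)}" width="{round(p.w * W, 2)}" '
            f'height="{round(p.h * W, 2)}" {s}/>'
        )
    if p.kind in ("line", "polyline"):
        pts = " ".join(f"{X(a)},{Y(b)}" for a, b in p.points)
        return f'<polyline points="{pts}" fill="none" {s}/>'
    if p.kind == "text":
        anchor = {"start": "start", "middle": "middle", "end": "end"}[p.anchor or "middle"]
        transform = ""
        if p.rotation:
            transform = f' transform="rotate({-p.rotation} {X(p.x)} {Y(p.y)})"'
        fill = p.fill or "#000000ff"
        c, _ = _hex_to_svg(fill)
        return (
            f'<text x="{X(p.x)}" y="{Y(p.y)}" text-anchor="{anchor}" '
            f'dominant-baseline="middle" font-size="{_FONT_PX}" '
            f'font-family="sans-serif" fill="{c}"{transform}>{escape(p.text)}</text>'
        )
    if p.kind == "marker":
        r = (p.radius or 0.005) * W
        if p.shape in (None, "circle"):
            return f'<circle cx="{X(p.x)}" cy="{Y(p.y)}" r="{round(r, 2)}" {s}/>'
        if p.shape == "cross":
            c, _ = _hex_to_svg(p.fill or "#000000ff")
            x0, y0 = X(p.x), Y(p.y)
            return (
                f'<path d="M {x0 - r} {y0 - r} L {x0 + r} {y0 + r} '
                f'M {x0 - r} {y0 + r} L {x0 + r} {y0 - r}" stroke="{c}" '
                f'stroke-width="1.5" fill="none"/>'
            )
        pts = _marker_points(p.shape, X(p.x), Y(p.y), r)
        pts_s = " ".join(f"{a:.2f},{b:.2f}" for a, b in pts)
        return f'<polygon points="{pts_s}" {s}/>'
    raise SceneMapError(f"unknown primitive kind {p.kind!r}")


def _legend_primitives(legends: Sequence[Legend]):
    """Lay legends into the right-hand column as ordinary primitives."""
    from . import scene as sc

    x = 0.865
    y = 0.95
    for leg in legends:
        if y < 0.05:
            break
        yield sc.text(x, y, leg.title, anchor="start", fill="#000000ff")
        y -= 0.025
        if leg.kind == "colorbar":
            sw = dict(leg.entries[0][1])
            ramp = sw.get("ramp", "viridis-like")
            n = 12
            for k in range(n):
                yield sc.rect(x + k * 0.09 / n, y - 0.012, 0.09 / n, 0.012,
                              fill=ramp_lookup(ramp, k / (n - 1)))
            vals = {lab: dict(swd).get("value") for lab, swd in leg.entries}
            yield sc.text(x, y - 0.03, f'{vals.get("min", 0):.3g}', anchor="start")
            yield sc.text(x + 0.09, y - 0.03, f'{vals.get("max", 1):.3g}', anchor="end")
            y -= 0.055
        elif leg.kind == "categorical_patches":
            for lab, swd in leg.entries:
                sw = dict(swd)
                yield sc.rect(x, y - 0.012, 0.014, 0.012, fill=sw.get("color", "#888888ff"))
                yield sc.text(x + 0.02, y - 0.006, lab, anchor="start")
                y -= 0.02
            y -= 0.015
        elif leg.kind == "size_set":
            for lab, swd in leg.entries:
                sw = dict(swd)
                r = max(float(sw.get("radius", 0.1)), 0.05) * 0.012
                yield sc.marker(x + 0.007, y - 0.008, shape="circle", radius=r,
                                fill="#555555ff")
                yield sc.text(x + 0.02, y - 0.008, lab, anchor="start")
                y -= 0.022
            y -= 0.015
        elif leg.kind == "marker_set":
            for lab, swd in leg.entries:
                sw = dict(swd)
                yield sc.marker(x + 0.007, y - 0.008, shape=sw.get("marker", "circle"),
                                radius=0.006, fill="#555555ff")
                yield sc.text(x + 0.02, y - 0.008, lab, anchor="start")
                y -= 0.022
            y -= 0.015


def _render_png(scene: Scene, path, legends: Sequence[Legend], size: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon, Rectangle as MplRect, Circle

    dpi = 100
    fig = plt.figure(figsize=(size / dpi, size / dpi), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")

    def col(c):
        if c is None:
            return None
        h = c.lstrip("#")
        return (
            int(h[0:2], 16) / 255, int(h[2:4], 16) / 255, int(h[4:6], 16) / 255,
            int(h[6:8], 16) / 255 if len(h) == 8 else 1.0,
        )

    for p in scene.primitives + list(_legend_primitives(legends)):
        if p.kind == "rect":
            ax.add_patch(MplRect((p.x, p.y), p.w, p.h, facecolor=col(p.fill) or "none",
                                 edgecolor=col(p.stroke) or "none",
                                 linewidth=(p.stroke_width or 0.001) * size))
        elif p.kind in ("line", "polyline"):
            xs = [a for a, _ in p.points]
            ys = [b for _, b in p.points]
            ax.plot(xs, ys, color=col(p.stroke) or "black",
                    linewidth=max(0.5, (p.stroke_width or 0.001) * size / 2))
        elif p.kind == "text":
            ha = {"start": "left", "middle": "center", "end": "right"}[p.anchor or "middle"]
            ax.text(p.x, p.y, p.text, ha=ha, va="center", rotation=p.rotation,
                    fontsize=_FONT_PX * 0.8, color=col(p.fill or "#000000ff"))
        elif p.kind == "marker":
            r = p.radius or 0.005
            if p.shape in (None, "circle"):
                ax.add_patch(Circle((p.x, p.y), r, facecolor=col(p.fill) or "black",
                                    edgecolor="none"))
            elif p.shape == "cross":
                ax.plot([p.x - r, p.x + r], [p.y - r, p.y + r], color=col(p.fill) or "black")
                ax.plot([p.x - r, p.x + r], [p.y + r, p.y - r], color=col(p.fill) or "black")
            else:
                pts = _marker_points(p.shape, p.x, p.y, r)
                # marker points were built for screen-y; flip back for data-y
                pts = [(a, 2 * p.y - b) for a, b in pts]
                ax.add_patch(MplPolygon(pts, closed=True, facecolor=col(p.fill) or "black",
                                        edgecolor="none"))
    fig.savefig(path, format="png")
    plt.close(fig)
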