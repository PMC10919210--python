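"""Color ramps, categorical palettes, size scales and value-to-style maps.

Continuous ramps are defined by explicit control-point tables and linear
RGB interpolation, so mapped colors are identical across backends and
releases. All colors are 8-digit lowercase hex RGBA strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datamodel import SceneMapError

#: Named continuous ramps: (position in [0,1], color) control points.
RAMPS: dict[str, tuple[tuple[float, str], ...]] = {
    "viridis-like": (
        (0.00, "#440154ff"),
        (0.25, "#3b528bff"),
        (0.50, "#21918cff"),
        (0.75, "#5ec962ff"),
        (1.00, "#fde725ff"),
    ),
    "jet-like": (
        (0.000, "#00007fff"),
        (0.125, "#0000ffff"),
        (0.375, "#00ffffff"),
        (0.625, "#ffff00ff"),
        (0.875, "#ff0000ff"),
        (1.000, "#7f0000ff"),
    ),
    "turbo-like": (
        (0.00, "#30123bff"),
        (0.25, "#28bcebff"),
        (0.50, "#a4fc3cff"),
        (0.75, "#fb7e21ff"),
        (1.00, "#7a0403ff"),
    ),
    "coolwarm-like": (
        (0.0, "#3b4cc0ff"),
        (0.5, "#f7f7f7ff"),
        (1.0, "#b40426ff"),
    ),
}

#: Default categorical palette (10 colors, cycled beyond that).
PALETTE: tuple[str, ...] = (
    "#1f77b4ff",
    "#ff7f0eff",
    "#2ca02cff",
    "#d62728ff",
    "#9467bdff",
    "#8c564bff",
    "#e377c2ff",
    "#7f7f7fff",
    "#bcbd22ff",
    "#17becfff",
)

#: Fixed marker vocabulary; hue levels map to markers in first-appearance
#: order, cycling if there are more levels than shapes.
MARKERS: tuple[str, ...] = ("circle", "square", "triangle", "diamond", "cross", "star")

DEFAULT_MISSING_COLOR = "#bfbfbfff"


def _parse_hex(color: str) -> tuple[int, int, int, int]:
    c = color.lstrip("#")
    if len(c) == 6:
        c += "ff"
    if len(c) != 8:
        raise SceneMapError(f"not an 8-digit hex RGBA color: {color!r}")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4, 6))  # type: ignore[return-value]


def _to_hex(rgba: Iterable[float]) -> str:
    return "#" + "".join(f"{int(round(v)):02x}" for v in rgba)


def ramp_lookup(ramp_name: str, t: float) -> str:
    """Color at position ``t`` in [0, 1] on a named ramp."""
    if ramp_name not in RAMPS:
        raise SceneMapError(
            f"unknown ramp {ramp_name!r}; choose from {sorted(RAMPS)}"
        )
    t = min(1.0, max(0.0, float(t)))
    points = RAMPS[ramp_name]
    for (t0, c0), (t1, c1) in zip(points, points[1:]):
        if t <= t1:
            frac = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
            a = _parse_hex(c0)
            b = _parse_hex(c1)
            return _to_hex(a_ + frac * (b_ - a_) for a_, b_ in zip(a, b))
    return points[-1][1]


def relative_luminance(color: str) -> float:
    """WCAG relative luminance of an sRGB color (alpha ignored)."""
    r, g, b, _ = _parse_hex(color)

    def lin(u: int) -> float:
        s = u / 255.0
        return s / 12.92 if s <= 0.04045 else ((s + 0.055) / 1.055) ** 2.4

    return 0.2126 * lin(r) + 0.7152 * lin(g) + 0.0722 * lin(b)


def text_contrast_color(background: str) -> str:
    """White on dark fills (luminance < 0.5), black on light ones."""
    return "#ffffffff" if relative_luminance(background) < 0.5 else "#000000ff"


@dataclass
class ColorSpec:
    """How values become colors: a category mapping or a continuous ramp.

    Categorical mode needs ``mapping`` to cover every observed category,
    or ``fallback_palette=True`` to assign palette colors to unmapped
    categories in first-appearance order. Continuous mode maps values
    affinely from [vmin, vmax] into ramp positions; a constant vector
    (vmin == vmax) maps to the ramp midpoint.
    """

    mode: str  # "categorical" | "continuous"
    mapping: dict[str, str] | None = None
    ramp_name: str = "viridis-like"
    vmin: float | None = None
    vmax: float | None = None
    missing_color: str = DEFAULT_MISSING_COLOR
    fallback_palette: bool = True
    robust: bool = False  # clip continuous range to (q01, q99)
    title: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("categorical", "continuous"):
            raise SceneMapError(f"unknown color mode {self.mode!r}")
        if self.mode == "continuous" and self.ramp_name not in RAMPS:
            raise SceneMapError(f"unknown ramp {self.ramp_name!r}")
        if (
            self.vmin is not None
            and self.vmax is not None
            and self.vmin > self.vmax
        ):
            raise SceneMapError("vmin must not exceed vmax")

    @classmethod
    def categorical(
        cls, mapping: dict[str, str] | None = None, **kw
    ) -> "ColorSpec":
        return cls(mode="categorical", mapping=mapping, **kw)

    @classmethod
    def continuous(cls, ramp_name: str = "viridis-like", **kw) -> "ColorSpec":
        return cls(mode="continuous", ramp_name=ramp_name, **kw)

    def resolved(self, values: Sequence) -> "ColorSpec":
        """Fill vmin/vmax (or the category mapping) from observed values."""
        if self.mode == "continuous":
            vmin, vmax = self.vmin, self.vmax
            finite = np.asarray(
                [v for v in values if v is not None and np.isfinite(v)], dtype=float
            )
            if vmin is None or vmax is None:
                if finite.size == 0:
                    vmin = 0.0 if vmin is None else vmin
                    vmax = 1.0 if vmax is None else vmax
                elif self.robust:
                    lo, hi = np.quantile(finite, [0.01, 0.99])
                    vmin = float(lo) if vmin is None else vmin
                    vmax = float(hi) if vmax is None else vmax
                else:
                    vmin = float(finite.min()) if vmin is None else vmin
                    vmax = float(finite.max()) if vmax is None else vmax
            return ColorSpec(
                mode="continuous",
                ramp_name=self.ramp_name,
                vmin=vmin,
                vmax=vmax,
                missing_color=self.missing_color,
                robust=self.robust,
                title=self.title,
            )
        mapping = dict(self.mapping or {})
        next_i = 0
        for v in values:
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            cat = str(v)
            if cat not in mapping:
                if not self.fallback_palette:
                    raise SceneMapError(
                        f"no color mapped for category {cat!r} and no fallback palette"
                    )
                while PALETTE[next_i % len(PALETTE)] in mapping.values():
                    next_i += 1
                mapping[cat] = PALETTE[next_i % len(PALETTE)]
                next_i += 1
        return ColorSpec(
            mode="categorical",
            mapping=mapping,
            missing_color=self.missing_color,
            fallback_palette=self.fallback_palette,
            title=self.title,
        )


def map_colors(values: Sequence, spec: ColorSpec) -> list[str]:
    """Element-wise value-to-color mapping; missing values get
    ``spec.missing_color``."""
    spec = spec.resolved(values)
    out: list[str] = []
    if spec.mode == "categorical":
        assert spec.mapping is not None
        for v in values:
            if v is None or (isinstance(v, float) and math.isnan(v)):
                out.append(spec.missing_color)
            else:
                cat = str(v)
                if cat not in spec.mapping:
                    raise SceneMapError(f"no color mapped for category {cat!r}")
                out.append(spec.mapping[cat])
        return out
    vmin, vmax = spec.vmin, spec.vmax
    for v in values:
        if v is None or not np.isfinite(v):
            out.append(spec.missing_color)
        elif vmax == vmin:  # constant vector: ramp midpoint
            out.append(ramp_lookup(spec.ramp_name, 0.5))
        else:
            t = (min(max(float(v), vmin), vmax) - vmin) / (vmax - vmin)
            out.append(ramp_lookup(spec.ramp_name, t))
    return out


@dataclass
class SizeScale:
    """Value-to-radius scale for dot heatmaps.

    Radii are area-linear in value: r = r_max * sqrt((v - vmin)/(vmax - vmin))
    after clipping v into [vmin, vmax]. ``r_max`` is a fraction of the cell
    half-extent, in (0, 1].
    """

    vmin: float
    vmax: float
    r_max: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.r_max <= 1.0):
            raise SceneMapError("r_max must be in (0, 1]")
        if self.vmin >= self.vmax:
            raise SceneMapError("size scale needs vmin < vmax")


def map_sizes(values: Sequence[float], scale: SizeScale) -> np.ndarray:
    """Element-wise radii; v == vmin gives 0 (no dot), v == vmax gives r_max."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise SceneMapError("size values must be finite")
    t = (np.clip(v, scale.vmin, scale.vmax) - scale.vmin) / (scale.vmax - scale.vmin)
    return scale.r_max * np.sqrt(t)


def marker_assignment(hue_levels: Sequence[str]) -> dict[str, str]:
    """Hue level -> marker shape, by first-appearance order."""
    out: dict[str, str] = {}
    for i, lev in enumerate(hue_levels):
        if lev not in out:
            out[lev] = MARKERS[len(out) % len(MARKERS)]
    return out
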