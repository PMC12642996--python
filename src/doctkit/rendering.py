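"""HSB fusion of metric maps into color images.

Every metric family in the toolkit renders three scalar maps into one image
through the same machinery: normalize each map to [0, 1] (percentile or manual
bounds, optional inversion), assign the normalized maps to hue, saturation and
brightness, and convert to RGB.  Hue travels along a configurable arc of the
color wheel; the default 240°→0° arc runs blue→green→red without wrapping
through magenta, so "cold" blue reads as slow and "hot" red as fast.

Invalid pixels (NaN in any source map) render black — a failed fit must never
masquerade as fast dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .stack_io import MetricMap, ValidationError

__all__ = [
    "Percentile",
    "Manual",
    "Fixed",
    "ChannelSpec",
    "ChannelMapping",
    "ColorImage",
    "normalize_channel",
    "compose_hsb",
    "render",
]


@dataclass(frozen=True)
class Percentile:
    """Clip at the lo/hi percentiles of the map's finite values."""

    lo: float = 0.0
    hi: float = 100.0

    def __post_init__(self):
        if not (0.0 <= self.lo < self.hi <= 100.0):
            raise ValidationError(f"need 0 <= lo < hi <= 100, got {self.lo}, {self.hi}")


@dataclass(frozen=True)
class Manual:
    """Clip at fixed metric values (the 'manual thresholds' of the motility preset)."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValidationError(f"need lo < hi, got {self.lo}, {self.hi}")


@dataclass(frozen=True)
class Fixed:
    """A channel held at a constant value (e.g. saturation fixed at maximum)."""

    value: float = 1.0


NormRule = Union[Percentile, Manual]


@dataclass(frozen=True)
class ChannelSpec:
    source: str  # MetricName value, or "FIXED"
    rule: NormRule | None = None
    invert: bool = False
    log: bool = False  # apply 10*log10 before normalizing (B-scan brightness)
    fixed: float | None = None


@dataclass(frozen=True)
class ChannelMapping:
    hue: ChannelSpec
    saturation: ChannelSpec
    brightness: ChannelSpec
    hue_arc: tuple[float, float] = (240.0, 0.0)

    def __post_init__(self):
        for end in self.hue_arc:
            if not (0.0 <= end <= 360.0):
                raise ValidationError("hue_arc endpoints must lie in [0, 360] degrees")


@dataclass(frozen=True)
class ColorImage:
    """H×W×3 RGB in [0, 1] plus the mapping and resolved ranges that made it."""

    rgb: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValidationError("rgb must be H×W×3")
        if not np.all(np.isfinite(self.rgb)):
            raise ValidationError("rgb must be finite")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ValidationError("rgb values must lie in [0, 1]")


def resolve_bounds(values: np.ndarray, rule: NormRule) -> tuple[float, float]:
    """Concrete (lo, hi) clip values for a normalization rule on a map."""
    if isinstance(rule, Manual):
        return float(rule.lo), float(rule.hi)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return 0.0, 1.0
    lo, hi = np.percentile(finite, [rule.lo, rule.hi])
    return float(lo), float(hi)


def normalize_channel(
    metric: MetricMap | np.ndarray,
    rule: NormRule,
    invert: bool = False,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Clip to the rule's bounds, map affinely to [0, 1], optionally invert.

    Returns ``(unit_map, invalid_mask, (lo, hi))``.  Invalid (non-finite)
    pixels come back as 0 with the mask set; a constant map under a percentile
    rule degenerates to 0.5 everywhere with a warning.
    """
    values = metric.values if isinstance(metric, MetricMap) else np.asarray(metric, dtype=float)
    invalid = ~np.isfinite(values)
    lo, hi = resolve_bounds(values, rule)
    if hi <= lo:
        warnings.warn("degenerate normalization bounds (constant map); output set to 0.5")
        out = np.full(values.shape, 0.5)
    else:
        out = np.clip((np.where(invalid, lo, values) - lo) / (hi - lo), 0.0, 1.0)
    if invert:
        out = 1.0 - out
    out[invalid] = 0.0
    return out, invalid, (lo, hi)


def compose_hsb(
    h: np.ndarray,
    s: np.ndarray,
    b: np.ndarray,
    mapping: ChannelMapping | None = None,
    invalid: np.ndarray | None = None,
) -> ColorImage:
    """HSB→RGB fusion of three unit-interval maps along the mapping's hue arc."""
    mapping = mapping or ChannelMapping(ChannelSpec("H"), ChannelSpec("S"), ChannelSpec("B"))
    h, s, b = (np.asarray(a, dtype=float) for a in (h, s, b))
    if not (h.shape == s.shape == b.shape):
        raise ValidationError("channel shapes differ")
    start, end = mapping.hue_arc
    hue_deg = start + h * (end - start)
    hsv = np.stack([hue_deg / 360.0, np.clip(s, 0, 1), np.clip(b, 0, 1)], axis=-1)
    rgb = hsv_to_rgb(hsv)
    if invalid is not None:
        rgb[invalid] = 0.0
    return ColorImage(np.clip(rgb, 0.0, 1.0), provenance={"hue_arc": mapping.hue_arc})


def _resolve(spec: ChannelSpec, maps: dict[str, MetricMap]) -> tuple[np.ndarray, np.ndarray, dict]:
    if spec.source == "FIXED" or spec.fixed is not None:
        value = 1.0 if spec.fixed is None else spec.fixed
        shape = next(iter(maps.values())).values.shape
        return np.full(shape, value), np.zeros(shape, bool), {"source": "FIXED", "value": value}
    m = maps[spec.source]
    values = m.values
    meta: dict = {"source": spec.source, "invert": spec.invert}
    if spec.log:
        with np.errstate(divide="ignore", invalid="ignore"):
            values = 10.0 * np.log10(values)
        values = np.where(np.isfinite(values), values, np.nan)
        meta["log"] = True
    unit, invalid, bounds = normalize_channel(
        MetricMap(values, m.name, m.units), spec.rule or Percentile(), spec.invert
    )
    meta["bounds"] = bounds
    return unit, invalid, meta


def render(maps: dict[str, MetricMap], mapping: ChannelMapping) -> ColorImage:
    """Render a full ChannelMapping against a dict of metric maps keyed by name."""
    h, inv_h, meta_h = _resolve(mapping.hue, maps)
    s, inv_s, meta_s = _resolve(mapping.saturation, maps)
    b, inv_b, meta_b = _resolve(mapping.brightness, maps)
    invalid = inv_h | inv_s | inv_b
    img = compose_hsb(h, s, b, mapping, invalid)
    return ColorImage(
        img.rgb,
        provenance={
            "hue": meta_h,
            "saturation": meta_s,
            "brightness": meta_b,
            "hue_arc": mapping.hue_arc,
        },
    )
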