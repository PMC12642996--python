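"""LIV-family metrics: LIV, time-window LIV curves, aLIV and Swiftness.

LIV (logarithmic intensity variance) is the time variance of the dB-scaled
OCT intensity.  Its value grows with the analysis time window and saturates;
fitting the window-size dependence with the first-order saturation law

    LIV(T) = a * (1 - exp(-s * T))

yields two contrasts: aLIV = a, the saturation level (dB², fluctuation
magnitude, sensitive to the occupancy of moving scatterers) and
Swiftness = s, the inverse time constant (s⁻¹, fluctuation speed).

Window sizes default to a ~9-point geometric grid between 2 frames and the
full record; for each size the LIV is averaged over windows placed at stride
w/2 (disjoint placement available as an option).  A window of w frames spans
T = (w-1) frame periods, so the curve passes through the origin like the
saturation law itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .rendering import ChannelMapping, ChannelSpec, ColorImage, Manual, Percentile, render
from .stack_io import (
    INVALID,
    MetricMap,
    MetricName,
    Modality,
    TimeSeriesStack,
    ValidationError,
    intensity_to_db,
)

__all__ = [
    "SaturationFit",
    "liv",
    "default_window_sizes",
    "liv_curve",
    "fit_saturation",
    "aliv_swiftness",
    "AlivOptions",
]


@dataclass(frozen=True)
class SaturationFit:
    """Result of fitting LIV(T) = a*(1 - exp(-s*T))."""

    a: float          # saturation level, dB^2  -> aLIV
    s: float          # rate constant, 1/s      -> Swiftness
    sse: float
    converged: bool


def liv(stack_db: np.ndarray, window: tuple[int, int] | None = None) -> MetricMap:
    """Population time-variance of dB intensity over ``window = (start, length)``."""
    stack_db = np.asarray(stack_db, dtype=float)
    n = stack_db.shape[0]
    start, length = window if window is not None else (0, n)
    if length < 2:
        raise ValidationError("window length must be >= 2")
    if start < 0 or start + length > n:
        raise ValidationError(f"window {window} outside [0, {n})")
    seg = stack_db[start : start + length]
    return MetricMap(seg.var(axis=0), MetricName.LIV, units="dB^2")


def default_window_sizes(n_frames: int, n_sizes: int = 9) -> np.ndarray:
    """Geometric grid of integer window sizes from 2 to N (ceil, deduplicated).

    For N=32 this is {2, 3, 4, 6, 8, 12, 16, 23, 32}.
    """
    if n_frames < 2:
        raise ValidationError("need n_frames >= 2")
    sizes = np.unique(np.ceil(np.geomspace(2, n_frames, n_sizes)).astype(int))
    return sizes


def liv_curve(
    stack_db: np.ndarray,
    frame_period_s: float,
    window_sizes: np.ndarray | list[int] | None = None,
    *,
    disjoint: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean LIV per window size for every pixel.

    Returns ``(T_w, curves)`` with ``T_w`` in seconds (``(w-1)*frame_period``)
    and ``curves`` shaped (n_sizes, rows, cols).  For each size the LIV is
    averaged over windows at stride ``max(1, w//2)`` (or ``w`` when
    ``disjoint``).
    """
    stack_db = np.asarray(stack_db, dtype=float)
    n = stack_db.shape[0]
    sizes = (
        default_window_sizes(n)
        if window_sizes is None
        else np.unique(np.asarray(window_sizes, dtype=int))
    )
    if sizes.size < 4:
        raise ValidationError("need >= 4 window sizes for a 2-parameter fit")
    if sizes.min() < 2 or sizes.max() > n:
        raise ValidationError(f"window sizes must lie in [2, {n}]")
    curves = np.empty((sizes.size,) + stack_db.shape[1:])
    for i, w in enumerate(sizes):
        stride = w if disjoint else max(1, w // 2)
        starts = range(0, n - w + 1, stride)
        acc = np.zeros(stack_db.shape[1:])
        for s0 in starts:
            acc += stack_db[s0 : s0 + w].var(axis=0)
        curves[i] = acc / len(list(starts))
    T = (sizes - 1) * frame_period_s
    return T, curves


def _saturation(T: np.ndarray, a: float, s: float) -> np.ndarray:
    return a * (1.0 - np.exp(-s * T))


def fit_saturation(T: np.ndarray, livs: np.ndarray) -> SaturationFit:
    """Bounded least-squares fit of the first-order saturation law to one curve.

    Initial guesses: a0 = max(LIV); s0 = 1/T_half with T_half the first T
    where the curve reaches a0/2 (fallback 1/median(T)).  An all-zero curve
    returns a = 0 with the rate flagged invalid (the time constant of a flat
    zero curve is undefined).
    """
    T = np.asarray(T, dtype=float)
    y = np.asarray(livs, dtype=float)
    if T.size < 4:
        raise ValidationError("need >= 4 samples")
    if np.any(np.diff(T) <= 0):
        raise ValidationError("T must be strictly increasing")
    if not np.all(np.isfinite(y)):
        return SaturationFit(INVALID, INVALID, INVALID, False)
    a0 = float(y.max())
    if a0 <= 1e-12:  # zero curve up to float noise: rate constant undefined
        return SaturationFit(0.0, INVALID, float(np.sum(y**2)), True)
    reached = np.nonzero(y >= a0 / 2)[0]
    T_half = T[reached[0]] if reached.size and T[reached[0]] > 0 else float(np.median(T))
    s0 = 1.0 / T_half if T_half > 0 else 1.0
    try:
        popt, _ = curve_fit(
            _saturation,
            T,
            y,
            p0=[a0, s0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return SaturationFit(INVALID, INVALID, INVALID, False)
    a, s = float(popt[0]), float(popt[1])
    sse = float(np.sum((y - _saturation(T, a, s)) ** 2))
    return SaturationFit(a, s, sse, True)


def fit_saturation_maps(T: np.ndarray, curves: np.ndarray) -> tuple[MetricMap, MetricMap]:
    """Per-pixel saturation fits over a (n_sizes, rows, cols) curve array."""
    rows, cols = curves.shape[1:]
    aliv = np.full((rows, cols), INVALID)
    swift = np.full((rows, cols), INVALID)
    for i in range(rows):
        for j in range(cols):
            fit = fit_saturation(T, curves[:, i, j])
            if fit.converged:
                aliv[i, j] = fit.a
                swift[i, j] = fit.s
    return (
        MetricMap(aliv, MetricName.ALIV, units="dB^2"),
        MetricMap(swift, MetricName.SWIFTNESS, units="1/s"),
    )


@dataclass(frozen=True)
class AlivOptions:
    window_sizes: tuple[int, ...] | None = None
    disjoint_windows: bool = False
    subsample_count: int | None = None   # e.g. 64 frames ...
    subsample_stride: int | None = None  # ... at 8-frame intervals
    db_floor: float | None = None
    hue_range: tuple[float, float] | None = None        # Swiftness display, 1/s
    sat_range: tuple[float, float] | None = None        # aLIV display, dB^2
    brightness_range: tuple[float, float] | None = None # dB intensity display


def aliv_swiftness(
    stack: TimeSeriesStack,
    options: AlivOptions | None = None,
) -> tuple[dict[str, MetricMap], ColorImage, ColorImage]:
    """Full LIV pipeline: dB conversion → LIV curves → fits → fusion images.

    Returns the metric maps plus two renderings: the modality-appropriate
    fusion (en face: Swiftness→hue, aLIV→brightness, saturation fixed;
    B-scan: Swiftness→hue, aLIV→saturation, mean dB intensity→brightness)
    and the conventional single-metric view (Swiftness on a red→green hue
    arc with dB intensity as brightness).
    """
    options = options or AlivOptions()
    frames = stack.frames
    if options.subsample_count and options.subsample_stride:
        idx = np.arange(options.subsample_count) * options.subsample_stride
        if idx[-1] >= stack.n_frames:
            raise ValidationError("subsampling pattern exceeds the record length")
        frames = frames[idx]
        stack = TimeSeriesStack(frames, stack.frame_rate_hz / options.subsample_stride,
                                stack.modality, stack.pixel_spacing)
    stack_db = intensity_to_db(stack, options.db_floor)
    T, curves = liv_curve(
        stack_db,
        stack.frame_period_s,
        options.window_sizes,
        disjoint=options.disjoint_windows,
    )
    aliv_map, swift_map = fit_saturation_maps(T, curves)
    db_mean = MetricMap(stack_db.mean(axis=0), MetricName.OCT_DB_MEAN, units="dB")
    maps = {"ALIV": aliv_map, "SWIFTNESS": swift_map, "OCT_DB_MEAN": db_mean}

    def rule(bounds, default=Percentile(1.0, 99.0)):
        return Manual(*bounds) if bounds is not None else default

    if stack.modality is Modality.EN_FACE:
        fusion_mapping = ChannelMapping(
            hue=ChannelSpec("SWIFTNESS", rule(options.hue_range)),
            saturation=ChannelSpec("FIXED", fixed=1.0),
            brightness=ChannelSpec("ALIV", rule(options.sat_range)),
            hue_arc=(240.0, 0.0),
        )
    else:
        fusion_mapping = ChannelMapping(
            hue=ChannelSpec("SWIFTNESS", rule(options.hue_range)),
            saturation=ChannelSpec("ALIV", rule(options.sat_range)),
            brightness=ChannelSpec("OCT_DB_MEAN", rule(options.brightness_range)),
            hue_arc=(240.0, 0.0),
        )
    fusion = render(maps, fusion_mapping)
    # conventional individual-metric view: metric on a red->green arc,
    # dB intensity as brightness
    single_mapping = ChannelMapping(
        hue=ChannelSpec("SWIFTNESS", rule(options.hue_range)),
        saturation=ChannelSpec("FIXED", fixed=1.0),
        brightness=ChannelSpec("OCT_DB_MEAN", rule(options.brightness_range)),
        hue_arc=(0.0, 120.0),
    )
    single = render(maps, single_mapping)
    return maps, fusion, single
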