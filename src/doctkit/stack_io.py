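"""I/O and core containers for OCT time-series analysis.

A dynamic-OCT measurement is a movie of linear-intensity OCT frames acquired
at a fixed sample position.  Everything downstream (temporal spectra, LIV
curves, motility fits) consumes the :class:`TimeSeriesStack` defined here and
produces :class:`MetricMap` scalar fields, which this module can persist as
32-bit float TIFFs alongside a JSON provenance sidecar.

Axis convention: ``frames[t, row, col]`` — time leading, then the two spatial
axes.  For B-scans the row axis is depth (z); for en face planes it is y.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "Modality",
    "MetricName",
    "TimeSeriesStack",
    "MetricMap",
    "ValidationError",
    "FormatError",
    "load_stack",
    "save_stack",
    "intensity_to_db",
    "db_floor",
    "save_outputs",
]

INVALID = np.nan
"""Sentinel for invalid pixels in metric maps (failed fits, zero-power spectra)."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class FormatError(ValueError):
    """File cannot be interpreted as an OCT time-series."""


class Modality(enum.Enum):
    EN_FACE = "en_face"
    B_SCAN = "b_scan"


class MetricName(enum.Enum):
    PFI = "PFI"
    MEAN_PSD = "MEAN_PSD"
    STD_PSD = "STD_PSD"
    LIV = "LIV"
    ALIV = "ALIV"
    SWIFTNESS = "SWIFTNESS"
    M = "M"
    ALPHA = "ALPHA"
    R2 = "R2"
    BIN_BLUE = "BIN_BLUE"
    BIN_GREEN = "BIN_GREEN"
    BIN_RED = "BIN_RED"
    OCT_DB_MEAN = "OCT_DB_MEAN"
    LOG_STD = "LOG_STD"


@dataclass(frozen=True)
class TimeSeriesStack:
    """A (time, row, col) movie of non-negative linear OCT intensity.

    Parameters
    ----------
    frames
        3D float array, time as leading axis, linear intensity in arbitrary
        units (camera counts are used as-is; all derived metrics are either
        ratios/variances or document their unit dependence).
    frame_rate_hz
        Frame repetition rate in Hz (e.g. a 204.8 ms repetition time gives
        about 4.9 Hz).
    modality
        EN_FACE (x-y plane) or B_SCAN (x-z cross section); selects rendering
        presets downstream.
    pixel_spacing
        Optional (row_um, col_um) physical spacing.
    """

    frames: np.ndarray
    frame_rate_hz: float
    modality: Modality = Modality.EN_FACE
    pixel_spacing: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValidationError(f"frames must be 3D (time, row, col); got ndim={frames.ndim}")
        if frames.shape[0] < 2:
            raise ValidationError(f"need at least 2 frames, got {frames.shape[0]}")
        if frames.shape[1] == 0 or frames.shape[2] == 0:
            raise ValidationError("frames empty along a spatial axis")
        if not np.issubdtype(frames.dtype, np.floating):
            frames = frames.astype(np.float64)
        if not np.all(np.isfinite(frames)):
            raise ValidationError("intensities must be finite")
        if frames.min() < 0:
            raise ValidationError("intensities must be non-negative")
        if not (self.frame_rate_hz > 0 and np.isfinite(self.frame_rate_hz)):
            raise ValidationError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        object.__setattr__(self, "frames", frames)
        if isinstance(self.modality, str):
            object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def nyquist_hz(self) -> float:
        return self.frame_rate_hz / 2.0


@dataclass
class MetricMap:
    """A named 2D scalar field derived from a stack.

    Invalid pixels carry NaN (``INVALID``), never a silent zero; renderers map
    them to black.
    """

    values: np.ndarray
    name: MetricName
    units: str = "dimensionless"
    display_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("MetricMap values must be 2D")
        if isinstance(self.name, str):
            self.name = MetricName(self.name)

    @property
    def invalid_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)


# ---------------------------------------------------------------------------
# Loading / saving stacks
# ---------------------------------------------------------------------------

def load_stack(
    path: str | Path,
    frame_rate_hz: float,
    modality: Modality | str = Modality.EN_FACE,
    *,
    shape: tuple[int, int, int] | None = None,
    dtype: str | np.dtype | None = None,
    pixel_spacing: tuple[float, float] | None = None,
) -> TimeSeriesStack:
    """Read a stack from a multi-page TIFF or a raw binary file.

    TIFF input holds one grayscale frame per page.  Raw binary input needs an
    explicit ``shape`` (n_frames, rows, cols) and ``dtype`` (float32 or
    uint16, native endianness unless the dtype string says otherwise).
    uint16 counts are promoted to float without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            raise FormatError("TIFF holds a single page; a time series needs >= 2")
        if frames.ndim != 3:
            raise FormatError(f"TIFF pages are not 2D grayscale (array ndim={frames.ndim})")
    else:
        if shape is None or dtype is None:
            raise FormatError("raw binary input requires explicit shape and dtype")
        frames = np.fromfile(path, dtype=np.dtype(dtype))
        expected = int(np.prod(shape))
        if frames.size != expected:
            raise FormatError(
                f"raw file holds {frames.size} samples, expected {expected} for shape {shape}"
            )
        frames = frames.reshape(shape)
    frames = frames.astype(np.float64, copy=False)
    if frames.min() < 0:
        raise ValidationError("negative intensities in input file")
    return TimeSeriesStack(frames, frame_rate_hz, Modality(modality) if isinstance(modality, str) else modality,
                           pixel_spacing)


def save_stack(stack: TimeSeriesStack, path: str | Path) -> Path:
    """Write a stack as a float32 multi-page TIFF (one frame per page)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Linear <-> dB
# ---------------------------------------------------------------------------

def db_floor(frames: np.ndarray, factor: float = 1e-6) -> float:
    """Default dB floor: (smallest positive intensity) * factor.

    Keeps the log map finite on zero pixels without affecting any genuine
    signal.  Falls back to ``factor`` itself for an all-zero stack.
    """
    positive = frames[frames > 0]
    if positive.size == 0:
        return float(factor)
    return float(positive.min() * factor)


def intensity_to_db(stack: TimeSeriesStack | np.ndarray, floor: float | None = None) -> np.ndarray:
    """Map linear intensity to decibels: 10*log10(max(I, floor)).

    Monotone in I and exactly offset-equivariant: dB(c*I) = dB(I) + 10*log10(c)
    for I >= floor, which is why variance-type metrics on dB data (LIV) are
    invariant to multiplicative intensity rescaling.
    """
    frames = stack.frames if isinstance(stack, TimeSeriesStack) else np.asarray(stack, dtype=np.float64)
    if floor is None:
        floor = db_floor(frames)
    if not floor > 0:
        raise ValidationError(f"floor must be > 0, got {floor}")
    return 10.0 * np.log10(np.maximum(frames, floor))


# ---------------------------------------------------------------------------
# Saving outputs
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonify(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_outputs(
    maps: Sequence[MetricMap],
    image: "ColorImage | None" = None,  # noqa: F821 - rendering import cycle
    out_dir: str | Path = ".",
    *,
    prefix: str = "",
    parameters: dict | None = None,
) -> dict:
    """Persist metric maps (float32 TIFF), an optional RGB image (8-bit PNG),
    and a JSON sidecar recording names, units, display ranges and processing
    parameters.  Returns the manifest dict that was written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"maps": [], "image": None, "parameters": _jsonify(parameters or {})}
    for m in maps:
        fname = f"{prefix}{m.name.value}.tif"
        tifffile.imwrite(out_dir / fname, m.values.astype(np.float32), photometric="minisblack")
        manifest["maps"].append(
            {
                "file": fname,
                "name": m.name.value,
                "units": m.units,
                "display_range": _jsonify(m.display_range),
            }
        )
    if image is not None:
        import imageio.v3 as iio

        fname = f"{prefix}fusion.png"
        rgb8 = np.clip(np.round(image.rgb * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(out_dir / fname, rgb8)
        manifest["image"] = {"file": fname, "provenance": _jsonify(image.provenance)}
    sidecar = out_dir / f"{prefix}manifest.json"
    sidecar.write_text(json.dumps(manifest, indent=2))
    return manifest


def load_metric_map(path: str | Path, name: MetricName | str, units: str = "dimensionless") -> MetricMap:
    """Read back a float TIFF metric map saved by :func:`save_outputs`."""
    values = tifffile.imread(Path(path))
    return MetricMap(values, MetricName(name) if isinstance(name, str) else name, units)
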