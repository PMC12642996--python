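"""Dynamic-speckle phantoms with region-wise ground-truth dynamics.

The study data behind the four metric families is not public, so testing
needs synthetic stacks whose dynamics are known by construction.  Dynamics
are modeled at the complex-field level — speckle is the carrier of the
dynamic signal, so intensity fluctuations must inherit fully-developed
speckle statistics (unit contrast, exponential intensity) rather than being
painted onto the intensity directly:

* STATIC — a frozen circular-Gaussian field; zero temporal variance.
* LORENTZIAN — an Ornstein-Uhlenbeck complex field with exponential
  autocorrelation (Brownian-type dynamics; Lorentzian intensity PSD whose
  width grows as the correlation time shrinks).
* TONE — a static field beating against a phase-rotating field at f0,
  emulating directional transport: a narrow intensity line at f0.
* POWER_LAW — a complex field spectrally shaped to |spectrum| ∝ f^(-α/2), so
  the intensity PSD tail falls as f^(-α) (motility-like 1/f dynamics).
* WHITE_NOISE — an uncorrelated field per frame; flat intensity spectrum.

Global additives: exponential detector noise on intensity, and an optional
narrowband intensity modulation shared by all pixels (instrument vibration,
e.g. the ~20 Hz line that scanned systems pick up).

Everything is reproducible from the spec's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .stack_io import Modality, TimeSeriesStack, ValidationError

__all__ = [
    "Static",
    "Lorentzian",
    "Tone",
    "PowerLaw",
    "WhiteNoise",
    "Vibration",
    "Region",
    "PhantomSpec",
    "generate_phantom",
    "preset_stacks",
    "shaped_noise_stack",
    "layered_masks",
]


# ---------------------------------------------------------------------------
# Dynamics menu
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Static:
    reflectivity: float = 1.0


@dataclass(frozen=True)
class Lorentzian:
    reflectivity: float = 1.0
    correlation_time_s: float = 0.5

    def __post_init__(self):
        if not self.correlation_time_s > 0:
            raise ValidationError("correlation_time_s must be > 0")


@dataclass(frozen=True)
class Tone:
    reflectivity: float = 1.0
    f0_hz: float = 10.0


@dataclass(frozen=True)
class PowerLaw:
    reflectivity: float = 1.0
    alpha: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")


@dataclass(frozen=True)
class WhiteNoise:
    level: float = 1.0


Dynamics = Union[Static, Lorentzian, Tone, PowerLaw, WhiteNoise]


@dataclass(frozen=True)
class Vibration:
    f_hz: float
    amplitude: float  # relative intensity modulation depth, < 1


@dataclass(frozen=True)
class Region:
    mask: np.ndarray  # boolean (rows, cols)
    dynamics: Dynamics
    label: int = 0


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]  # (n_frames, rows, cols)
    frame_rate_hz: float
    regions: Sequence[Region]
    detector_noise_level: float = 0.0
    vibration: Vibration | None = None
    modality: Modality = Modality.EN_FACE
    seed: int = 0

    def __post_init__(self):
        n, h, w = self.shape
        cover = np.zeros((h, w), dtype=int)
        for r in self.regions:
            if r.mask.shape != (h, w):
                raise ValidationError("region mask shape mismatch")
            cover += r.mask.astype(int)
        if np.any(cover != 1):
            raise ValidationError("region masks must partition the image exactly")
        nyq = self.frame_rate_hz / 2.0
        for r in self.regions:
            if isinstance(r.dynamics, Tone) and not (0 < r.dynamics.f0_hz <= nyq):
                raise ValidationError(f"tone frequency must lie in (0, {nyq}] Hz")


# ---------------------------------------------------------------------------
# Field generators (each returns a complex (T, n_pix) array)
# ---------------------------------------------------------------------------

def _cn(rng: np.random.Generator, size, var: float = 1.0) -> np.ndarray:
    """Circular complex Gaussian with E|E|^2 = var."""
    s = np.sqrt(var / 2.0)
    return rng.normal(0.0, s, size) + 1j * rng.normal(0.0, s, size)


def _field_static(rng, n_t, n_pix, d: Static):
    e0 = _cn(rng, (1, n_pix), d.reflectivity)
    return np.broadcast_to(e0, (n_t, n_pix)).copy()


def _field_lorentzian(rng, n_t, n_pix, d: Lorentzian, dt: float):
    rho = np.exp(-dt / d.correlation_time_s)
    e = np.empty((n_t, n_pix), dtype=complex)
    e[0] = _cn(rng, n_pix, d.reflectivity)
    innov = np.sqrt(1.0 - rho**2)
    for t in range(1, n_t):
        e[t] = rho * e[t - 1] + innov * _cn(rng, n_pix, d.reflectivity)
    return e


def _field_tone(rng, n_t, n_pix, d: Tone, dt: float):
    # static reference + phase-rotating component -> intensity beat note at f0
    e0 = _cn(rng, n_pix, d.reflectivity / 2.0)
    e1 = _cn(rng, n_pix, d.reflectivity / 2.0)
    phase = np.exp(2j * np.pi * d.f0_hz * dt * np.arange(n_t))
    return e0[None, :] + e1[None, :] * phase[:, None]


def _field_power_law(rng, n_t, n_pix, d: PowerLaw, dt: float):
    # shape white complex noise so the field spectrum magnitude ~ f^(-alpha/2)
    freqs = np.fft.fftfreq(n_t, d=dt)
    mag = np.empty_like(freqs)
    nonzero = freqs != 0
    fmin = np.min(np.abs(freqs[nonzero]))
    mag[nonzero] = np.abs(freqs[nonzero]) ** (-d.alpha / 2.0)
    mag[~nonzero] = fmin ** (-d.alpha / 2.0)
    spec = _cn(rng, (n_t, n_pix)) * mag[:, None]
    e = np.fft.ifft(spec, axis=0)
    # normalize mean intensity to the requested reflectivity
    power = np.mean(np.abs(e) ** 2)
    return e * np.sqrt(d.reflectivity / power)


def _field_white(rng, n_t, n_pix, d: WhiteNoise):
    return _cn(rng, (n_t, n_pix), d.level)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[TimeSeriesStack, np.ndarray]:
    """Render a spec into a stack plus an integer label map of region ids."""
    n_t, rows, cols = spec.shape
    dt = 1.0 / spec.frame_rate_hz
    rng = np.random.default_rng(spec.seed)
    intensity = np.zeros((n_t, rows, cols))
    labels = np.zeros((rows, cols), dtype=int)
    for region in spec.regions:
        idx = np.nonzero(region.mask)
        n_pix = idx[0].size
        labels[idx] = region.label
        if n_pix == 0:
            continue
        d = region.dynamics
        if isinstance(d, Static):
            e = _field_static(rng, n_t, n_pix, d)
        elif isinstance(d, Lorentzian):
            e = _field_lorentzian(rng, n_t, n_pix, d, dt)
        elif isinstance(d, Tone):
            e = _field_tone(rng, n_t, n_pix, d, dt)
        elif isinstance(d, PowerLaw):
            e = _field_power_law(rng, n_t, n_pix, d, dt)
        elif isinstance(d, WhiteNoise):
            e = _field_white(rng, n_t, n_pix, d)
        else:  # pragma: no cover
            raise ValidationError(f"unknown dynamics {d!r}")
        intensity[:, idx[0], idx[1]] = np.abs(e) ** 2
    if spec.vibration is not None:
        v = spec.vibration
        phase0 = rng.uniform(0, 2 * np.pi)
        mod = 1.0 + v.amplitude * np.sin(2 * np.pi * v.f_hz * dt * np.arange(n_t) + phase0)
        intensity *= mod[:, None, None]
    if spec.detector_noise_level > 0:
        noise = np.abs(_cn(rng, intensity.shape, spec.detector_noise_level)) ** 2
        intensity += noise
    stack = TimeSeriesStack(intensity, spec.frame_rate_hz, spec.modality)
    return stack, labels


def shaped_noise_stack(
    alpha: float,
    n_frames: int,
    shape: tuple[int, int],
    frame_rate_hz: float,
    c0: float = 1.0,
    b0: float = 0.0,
    seed: int = 0,
) -> TimeSeriesStack:
    """Real Gaussian noise whose one-sided periodogram averages c0·f^(-α)+b0.

    A direct spectral-domain construction (no speckle statistics), useful for
    validating spectral estimators and the power-law fit at the periodogram
    level.  The series is shifted to be non-negative; the shift only moves the
    DC bin, which detrended spectra discard.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    freqs = np.fft.rfftfreq(n_frames, d=1.0 / frame_rate_hz)
    S = np.zeros_like(freqs)
    S[1:] = c0 * freqs[1:] ** (-alpha) + b0
    n_bins = freqs.size
    X = np.empty((n_bins, rows, cols), dtype=complex)
    X[0] = 0.0
    interior = slice(1, n_bins - 1 if n_frames % 2 == 0 else n_bins)
    X[interior] = _cn(rng, (interior.stop - 1, rows, cols)) * np.sqrt(
        n_frames * S[interior, None, None]
    )
    if n_frames % 2 == 0:
        X[-1] = rng.normal(0.0, 1.0, (rows, cols)) * np.sqrt(n_frames * S[-1])
    series = np.fft.irfft(X, n=n_frames, axis=0)
    series -= series.min()
    return TimeSeriesStack(series, frame_rate_hz)


# ---------------------------------------------------------------------------
# Presets mirroring the three acquisition regimes
# ---------------------------------------------------------------------------

def layered_masks(rows: int, cols: int, n_layers: int) -> list[np.ndarray]:
    """Partition the image into n_layers horizontal bands (top to bottom)."""
    bounds = np.linspace(0, rows, n_layers + 1).astype(int)
    masks = []
    for k in range(n_layers):
        m = np.zeros((rows, cols), dtype=bool)
        m[bounds[k] : bounds[k + 1]] = True
        masks.append(m)
    return masks


def preset_stacks(
    name: str,
    rows: int = 48,
    cols: int = 48,
    seed: int = 0,
    vibration_on: bool = True,
) -> PhantomSpec:
    """Phantom specs for the three emulated acquisition regimes.

    RETINA_LIKE — en face, 512 frames at 100 Hz: static band, slow and fast
    Brownian bands, a directional-tone band.
    TRACHEA_LIKE — B-scan, 150 frames at 108 Hz: fast cilia band on top,
    medium epithelium, static connective tissue, plus a 20 Hz instrument
    vibration line.
    SPHEROID_LIKE — B-scan, 32 frames at 4.9 Hz: fast-decorrelating core,
    slow periphery, static background.
    """
    key = name.strip().upper()
    if key == "RETINA_LIKE":
        n_t, rate = 512, 100.0
        masks = layered_masks(rows, cols, 4)
        regions = [
            Region(masks[0], Static(1.0), label=0),
            Region(masks[1], Lorentzian(1.0, correlation_time_s=0.5), label=1),
            Region(masks[2], Lorentzian(1.0, correlation_time_s=0.05), label=2),
            Region(masks[3], Tone(1.0, f0_hz=10.0), label=3),
        ]
        return PhantomSpec((n_t, rows, cols), rate, regions, detector_noise_level=0.01,
                           modality=Modality.EN_FACE, seed=seed)
    if key == "TRACHEA_LIKE":
        n_t, rate = 150, 108.0
        masks = layered_masks(rows, cols, 3)
        regions = [
            Region(masks[0], Tone(1.0, f0_hz=40.0), label=2),          # cilia: fast beat
            Region(masks[1], Lorentzian(1.0, correlation_time_s=1.0), label=1),  # epithelium
            # connective tissue/cartilage backscatters ~12 dB more than the
            # dynamic layers (static structures dominate OCT brightness)
            Region(masks[2], Static(16.0), label=0),
        ]
        vib = Vibration(20.0, 0.03) if vibration_on else None
        return PhantomSpec((n_t, rows, cols), rate, regions, detector_noise_level=0.01,
                           vibration=vib, modality=Modality.B_SCAN, seed=seed)
    if key == "SPHEROID_LIKE":
        n_t, rate = 32, 4.9
        yy, xx = np.mgrid[0:rows, 0:cols]
        r = np.hypot(yy - rows / 2, xx - cols / 2)
        core = r < rows / 6
        ring = (r >= rows / 6) & (r < rows / 3)
        background = ~(core | ring)
        regions = [
            Region(core, Lorentzian(1.0, correlation_time_s=0.2), label=2),
            Region(ring, Lorentzian(1.0, correlation_time_s=2.0), label=1),
            Region(background, Static(0.2), label=0),
        ]
        return PhantomSpec((n_t, rows, cols), rate, regions, detector_noise_level=0.005,
                           modality=Modality.B_SCAN, seed=seed)
    raise ValidationError(f"unknown preset {name!r}")
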