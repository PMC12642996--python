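"""Per-pixel temporal spectra and time statistics shared by all metric families.

The temporal axis of a stack is short (32-512 frames), so the estimator is a
plain one-sided periodogram: no taper window, no segment averaging, no zero
padding.  Frequency bin centers are k*frame_rate/N for k = 0..floor(N/2), so
the axis ends at the Nyquist frequency for even N.

Also computed here are the first/second-order time statistics the motility and
RGB-binning families consume: temporal mean, population standard deviation,
its decimal log, and the lag-one product sum

    Gamma_I = (1/(N-1)) * sum_{k=1}^{N-1} I(t_k) * I(t_{k+1}),

kept exactly in this 1/(N-1) normalization (it is a product moment, not a
mean-removed autocorrelation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .stack_io import TimeSeriesStack, ValidationError

__all__ = [
    "SpectrumKind",
    "Detrend",
    "SpectrumCube",
    "TemporalStats",
    "frequency_axis",
    "compute_spectrum",
    "temporal_stats",
]


class SpectrumKind(enum.Enum):
    AMPLITUDE = "amplitude"  # |DFT|
    POWER = "power"          # |DFT|^2 / N  (periodogram)


class Detrend(enum.Enum):
    NONE = "none"
    MEAN = "mean"


@dataclass(frozen=True)
class SpectrumCube:
    """One-sided temporal spectrum per pixel, axes (freq_bin, row, col)."""

    spectra: np.ndarray
    freqs: np.ndarray
    kind: SpectrumKind
    includes_dc: bool
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.spectra.shape[0] != self.freqs.shape[0]:
            raise ValidationError("spectra leading axis must match freqs length")

    @property
    def nyquist_hz(self) -> float:
        return self.frame_rate_hz / 2.0

    def drop_dc(self) -> "SpectrumCube":
        """Return the cube without the zero-frequency bin."""
        if not self.includes_dc:
            return self
        return SpectrumCube(self.spectra[1:], self.freqs[1:], self.kind, False, self.frame_rate_hz)


@dataclass(frozen=True)
class TemporalStats:
    """Pixel-wise first/second-order time statistics of linear intensity."""

    mean: np.ndarray
    std: np.ndarray
    log_std: np.ndarray
    lag1_autocorr: np.ndarray


def frequency_axis(n_frames: int, frame_rate_hz: float) -> np.ndarray:
    """Bin centers k*frame_rate/N for k = 0..floor(N/2), in Hz."""
    if n_frames < 2:
        raise ValidationError("need n_frames >= 2")
    if not frame_rate_hz > 0:
        raise ValidationError("frame_rate_hz must be > 0")
    return np.fft.rfftfreq(n_frames, d=1.0 / frame_rate_hz)


def compute_spectrum(
    stack: TimeSeriesStack,
    kind: SpectrumKind | str = SpectrumKind.POWER,
    detrend: Detrend | str = Detrend.NONE,
) -> SpectrumCube:
    """One-sided DFT spectrum for every pixel.

    ``detrend=MEAN`` subtracts the temporal mean first (used before motility
    power-law fits, so the additive-noise term captures white noise rather
    than DC leakage); ``detrend=NONE`` keeps the DC bin (the RGB-binning
    static channel is exactly that bin).
    """
    kind = SpectrumKind(kind) if isinstance(kind, str) else kind
    detrend = Detrend(detrend) if isinstance(detrend, str) else detrend
    frames = stack.frames
    if not np.all(np.isfinite(frames)):
        raise ValidationError("stack contains non-finite samples")
    if detrend is Detrend.MEAN:
        frames = frames - frames.mean(axis=0, keepdims=True)
    dft = np.fft.rfft(frames, axis=0)
    if kind is SpectrumKind.AMPLITUDE:
        spectra = np.abs(dft)
    else:
        spectra = (np.abs(dft) ** 2) / stack.n_frames
    freqs = frequency_axis(stack.n_frames, stack.frame_rate_hz)
    return SpectrumCube(spectra, freqs, kind, includes_dc=True, frame_rate_hz=stack.frame_rate_hz)


def two_sided_power_sum(cube: SpectrumCube, n_frames: int) -> np.ndarray:
    """Total two-sided power reconstructed from a one-sided POWER cube.

    Interior bins are double-counted; DC and (for even N) the Nyquist bin are
    not.  With detrend=NONE this equals sum_t I(t)^2 (Parseval).
    """
    if cube.kind is not SpectrumKind.POWER or not cube.includes_dc:
        raise ValidationError("needs a POWER cube including DC")
    weights = np.full(cube.freqs.shape[0], 2.0)
    weights[0] = 1.0
    if n_frames % 2 == 0:
        weights[-1] = 1.0
    return np.tensordot(weights, cube.spectra, axes=(0, 0))


def temporal_stats(stack: TimeSeriesStack, log_floor: float = 1e-12) -> TemporalStats:
    """Temporal mean, population std, log10(std), and lag-1 product sum."""
    frames = stack.frames
    n = stack.n_frames
    mean = frames.mean(axis=0)
    std = frames.std(axis=0)  # population (1/N) convention
    log_std = np.log10(std + log_floor)
    lag1 = np.einsum("tij,tij->ij", frames[:-1], frames[1:]) / (n - 1)
    return TemporalStats(mean=mean, std=std, log_std=log_std, lag1_autocorr=lag1)
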