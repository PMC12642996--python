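"""PSD-moment metrics: PFI, spectral mean frequency, spectral spread, HSB preset.

Three per-pixel metrics summarize the fluctuation spectrum:

* PFI — mean absolute frame-to-frame intensity difference <|ΔI(t)|>, a
  magnitude measure that is homogeneous of degree 1 in intensity.
* <PSD> — power-weighted mean frequency of the one-sided power spectrum with
  the zero-frequency bin excluded; a speed measure in Hz.
* StD(PSD) — power-weighted spread about <PSD>; low for directional (tonal)
  transport, high for Brownian/noise-like broadband fluctuation.

The preset fuses them as hue(<PSD>, inverted so slow→blue), saturation
(StD(PSD), inverted so directional→saturated) and brightness(PFI), with
percentile thresholds 0.1/99.9 % (hue), 5 % lower (saturation) and 99.9 %
upper (brightness); B-scan brightness is shown on a decimal log scale to
compensate depth-dependent SNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rendering import ChannelMapping, ChannelSpec, ColorImage, Percentile, render
from .spectral import SpectrumCube, SpectrumKind, compute_spectrum
from .stack_io import INVALID, MetricMap, MetricName, Modality, TimeSeriesStack, ValidationError

__all__ = ["pfi", "psd_mean_freq", "psd_std_freq", "psd_moments_preset"]


def pfi(stack: TimeSeriesStack) -> MetricMap:
    """Phase Fluctuation Index: temporal mean of |I(t+1) - I(t)| per pixel."""
    diffs = np.abs(np.diff(stack.frames, axis=0))
    return MetricMap(diffs.mean(axis=0), MetricName.PFI, units="intensity")


def _positive_freq_power(cube: SpectrumCube) -> tuple[np.ndarray, np.ndarray]:
    if cube.kind is not SpectrumKind.POWER:
        raise ValidationError("PSD moments need a POWER cube")
    cube = cube.drop_dc()
    return cube.freqs, cube.spectra


def psd_mean_freq(cube: SpectrumCube) -> MetricMap:
    """Power-weighted mean frequency <PSD> in Hz, DC excluded.

    Pixels with zero total power carry the invalid sentinel.
    """
    freqs, power = _positive_freq_power(cube)
    total = power.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.tensordot(freqs, power, axes=(0, 0)) / total
    mean = np.where(total > 0, mean, INVALID)
    if not np.any(total > 0):
        warnings.warn("all pixels have zero spectral power; <PSD> map is all-invalid")
    return MetricMap(mean, MetricName.MEAN_PSD, units="Hz")


def psd_std_freq(cube: SpectrumCube) -> MetricMap:
    """Power-weighted spectral spread about <PSD>, in Hz, DC excluded."""
    freqs, power = _positive_freq_power(cube)
    total = power.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.tensordot(freqs, power, axes=(0, 0)) / total
        sq = np.tensordot(freqs**2, power, axes=(0, 0)) / total
        var = np.maximum(sq - mean**2, 0.0)
    std = np.where(total > 0, np.sqrt(var), INVALID)
    if not np.any(total > 0):
        warnings.warn("all pixels have zero spectral power; StD(PSD) map is all-invalid")
    return MetricMap(std, MetricName.STD_PSD, units="Hz")


@dataclass(frozen=True)
class PsdMomentsOptions:
    hue_percentiles: tuple[float, float] = (0.1, 99.9)
    saturation_lower_pct: float = 5.0
    brightness_upper_pct: float = 99.9


def psd_moments_preset(
    stack: TimeSeriesStack,
    options: PsdMomentsOptions | None = None,
) -> tuple[dict[str, MetricMap], ColorImage]:
    """Full PSD-moment pipeline: three metric maps plus the HSB fusion.

    Hue runs blue→red with increasing <PSD> (slow is cold); saturation is
    high where the spectrum is narrow (directional transport) and washes out
    for broadband/Brownian pixels; brightness is PFI, log-scaled for B-scans.
    """
    options = options or PsdMomentsOptions()
    cube = compute_spectrum(stack, SpectrumKind.POWER, detrend="none")
    maps = {
        "MEAN_PSD": psd_mean_freq(cube),
        "STD_PSD": psd_std_freq(cube),
        "PFI": pfi(stack),
    }
    # Inverted metrics on a red(0°)→blue(240°) arc: slow (low <PSD>) inverts to
    # hue coordinate 1 → 240° blue; fast lands at 0° red.
    mapping = ChannelMapping(
        hue=ChannelSpec("MEAN_PSD", Percentile(*options.hue_percentiles), invert=True),
        saturation=ChannelSpec("STD_PSD", Percentile(options.saturation_lower_pct, 100.0), invert=True),
        brightness=ChannelSpec(
            "PFI",
            Percentile(0.0, options.brightness_upper_pct),
            log=stack.modality is Modality.B_SCAN,
        ),
        hue_arc=(0.0, 240.0),
    )
    return maps, render(maps, mapping)
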