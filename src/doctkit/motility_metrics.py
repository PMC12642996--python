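"""Motility metrics: amplitude M and the inverse-power-law spectral fit (α, R²).

The motility amplitude is a modified standard deviation built from the lag-one
temporal product moment Γ_I = (1/(N-1)) Σ I(t_k) I(t_{k+1}):

    M = sqrt(Γ_I - <I>²) / <I>

It is exactly scale-invariant and nearly SNR-independent above SNR 1, because
uncorrelated noise cancels out of the lag-one product.  Negative radicands
(lag-one anti-correlated or noise-dominated pixels) are clamped to zero.

The spectral branch fits the per-pixel power spectral density — spatially
averaged over each pixel's 3×3 neighborhood for SNR — with the inverse power
law  PSD(f) = c0 f^(-α) + b0,  all three parameters constrained non-negative,
on positive frequencies only.  Intracellular motility produces 1/f-like
spectra (high R², α in roughly 0.5-3), whereas α ≈ 0 flags a noise-dominated
spectrum.  R² is defined against the flat mean-level null: it measures how
much better the power law explains the (relative-error-weighted) spectrum
than a constant would, which is exactly the noise-vs-motility question the
metric is used to answer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import least_squares

from .rendering import ChannelMapping, ChannelSpec, ColorImage, Manual, render
from .spectral import SpectrumCube, SpectrumKind, TemporalStats, compute_spectrum, temporal_stats
from .stack_io import INVALID, MetricMap, MetricName, TimeSeriesStack, ValidationError

__all__ = [
    "PowerLawFit",
    "WeightRule",
    "motility_amplitude",
    "smooth_spectra",
    "fit_inverse_power_law",
    "fit_power_law_maps",
    "motility_preset",
    "MotilityThresholds",
]


class WeightRule(enum.Enum):
    NONE = "none"
    RELATIVE = "relative"      # w = 1/(P+eps)^2: relative-error weighting
    INVERSE_F = "inverse-f"    # w = 1/f


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting PSD(f) = c0 * f^(-alpha) + b0 (all parameters >= 0)."""

    c0: float
    alpha: float
    b0: float
    r_squared: float
    converged: bool


def motility_amplitude(stats: TemporalStats) -> MetricMap:
    """M = sqrt(max(Γ_I - <I>², 0)) / <I>; zero-mean pixels flagged invalid."""
    mean = stats.mean
    radicand = stats.lag1_autocorr - mean**2
    # clamp negatives and float-cancellation noise (static pixels compute
    # Gamma and mean^2 as equal O(mean^2) quantities)
    radicand = np.where(radicand > 1e-12 * mean**2, radicand, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.sqrt(radicand) / mean
    m = np.where(mean > 0, m, INVALID)
    return MetricMap(m, MetricName.M, units="dimensionless")


def smooth_spectra(cube: SpectrumCube, include_center: bool = True) -> SpectrumCube:
    """3×3 spatial box mean of every frequency plane, edge-reflect padding.

    ``include_center=False`` averages only the 8 neighbors.
    """
    if cube.spectra.shape[1] < 3 or cube.spectra.shape[2] < 3:
        raise ValidationError("spatial extent must be at least 3x3")
    smoothed = uniform_filter(cube.spectra, size=(1, 3, 3), mode="reflect")
    if not include_center:
        smoothed = (smoothed * 9.0 - cube.spectra) / 8.0
    return SpectrumCube(smoothed, cube.freqs, cube.kind, cube.includes_dc, cube.frame_rate_hz)


def _power_law(f: np.ndarray, c0: float, alpha: float, b0: float) -> np.ndarray:
    return c0 * f ** (-alpha) + b0


def fit_inverse_power_law(
    spectrum: np.ndarray,
    freqs: np.ndarray,
    weight_rule: WeightRule | str = WeightRule.RELATIVE,
) -> PowerLawFit:
    """Constrained weighted least-squares fit of one positive-frequency PSD.

    Initialization: α0 = -slope of a log-log line fit on the upper half of the
    frequency axis (clamped to >= 0), c0 from its intercept, b0 = min(P).
    R² = 1 - SSE_w / SST_w with SST_w the weighted deviation from the plain
    mean level (the flat-spectrum null).
    """
    weight_rule = WeightRule(weight_rule) if isinstance(weight_rule, str) else weight_rule
    P = np.asarray(spectrum, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if f.size < 5:
        raise ValidationError("need >= 5 frequency bins")
    if np.any(f <= 0):
        raise ValidationError("fit operates on positive frequencies only")
    if not np.all(np.isfinite(P)) or np.any(P < 0):
        return PowerLawFit(INVALID, INVALID, INVALID, INVALID, False)
    if P.max() <= 0:
        return PowerLawFit(0.0, 0.0, 0.0, INVALID, True)

    eps = 1e-12 * P.max()
    if weight_rule is WeightRule.RELATIVE:
        sqrt_w = 1.0 / (P + eps)
    elif weight_rule is WeightRule.INVERSE_F:
        sqrt_w = 1.0 / np.sqrt(f)
    else:
        sqrt_w = np.ones_like(f)

    hi = f >= np.median(f)
    slope, intercept = np.polyfit(np.log(f[hi]), np.log(P[hi] + eps), 1)
    alpha0 = max(-slope, 0.0)
    c00 = max(float(np.exp(intercept)), eps)
    b00 = max(float(P.min()), 0.0)

    def residuals(p):
        return (_power_law(f, *p) - P) * sqrt_w

    try:
        res = least_squares(
            residuals,
            x0=[c00, alpha0, b00],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            max_nfev=2000,
        )
    except Exception:
        return PowerLawFit(INVALID, INVALID, INVALID, INVALID, False)
    c0, alpha, b0 = (float(v) for v in res.x)
    model = _power_law(f, c0, alpha, b0)
    w = sqrt_w**2
    sse = float(np.sum(w * (P - model) ** 2))
    sst = float(np.sum(w * (P - P.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else INVALID
    return PowerLawFit(c0, alpha, b0, r2, res.success)


def fit_power_law_maps(
    cube: SpectrumCube,
    weight_rule: WeightRule | str = WeightRule.RELATIVE,
) -> tuple[MetricMap, MetricMap]:
    """Per-pixel power-law fits over a positive-frequency POWER cube."""
    cube = cube.drop_dc()
    if cube.kind is not SpectrumKind.POWER:
        raise ValidationError("power-law fits need a POWER cube")
    _, rows, cols = cube.spectra.shape
    alpha = np.full((rows, cols), INVALID)
    r2 = np.full((rows, cols), INVALID)
    for i in range(rows):
        for j in range(cols):
            fit = fit_inverse_power_law(cube.spectra[:, i, j], cube.freqs, weight_rule)
            if fit.converged:
                alpha[i, j] = fit.alpha
                r2[i, j] = fit.r_squared
    return (
        MetricMap(alpha, MetricName.ALPHA, units="dimensionless"),
        MetricMap(r2, MetricName.R2, units="dimensionless"),
    )


@dataclass(frozen=True)
class MotilityThresholds:
    """Manual per-channel display ranges (the interactive-GUI thresholds)."""

    alpha: tuple[float, float] = (0.0, 3.0)
    r2: tuple[float, float] = (0.0, 1.0)
    m: tuple[float, float] = (0.0, 1.0)


def motility_preset(
    stack: TimeSeriesStack,
    thresholds: MotilityThresholds | None = None,
    weight_rule: WeightRule | str = WeightRule.RELATIVE,
    include_center: bool = True,
) -> tuple[dict[str, MetricMap], ColorImage]:
    """Full motility pipeline: M, 3×3-averaged spectra, α/R² fits, HSB fusion.

    The spectrum is computed from mean-detrended signals so the additive term
    b0 captures white noise rather than DC leakage.  Rendering uses manual
    (not percentile) thresholds: α→hue, R²→saturation, M→brightness.
    """
    thresholds = thresholds or MotilityThresholds()
    stats = temporal_stats(stack)
    m_map = motility_amplitude(stats)
    cube = compute_spectrum(stack, SpectrumKind.POWER, detrend="mean")
    cube = smooth_spectra(cube, include_center=include_center)
    alpha_map, r2_map = fit_power_law_maps(cube, weight_rule)
    maps = {"ALPHA": alpha_map, "R2": r2_map, "M": m_map}
    mapping = ChannelMapping(
        hue=ChannelSpec("ALPHA", Manual(*thresholds.alpha)),
        saturation=ChannelSpec("R2", Manual(*thresholds.r2)),
        brightness=ChannelSpec("M", Manual(*thresholds.m)),
        hue_arc=(240.0, 0.0),
    )
    return maps, render(maps, mapping)
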