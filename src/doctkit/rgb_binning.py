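"""RGB frequency binning with a neural-gas-derived cut-off frequency.

The amplitude spectrum of every pixel is compressed into three channels:
blue carries the static information (the DC amplitude), green the slow band
(0, cutoff] and red the fast band (cutoff, Nyquist].  The cut-off is found
automatically by clustering the image-summed, DC-removed spectrum on the
frequency axis with the neural gas algorithm — a rank-based competitive
learner — and placing the boundary midway between the two unit positions.

A full-field time-domain variant (``FFOCT`` mode) discards the DC bin *and*
the first non-DC bin (their DC holds unmodulated background light from all
depths rather than static OCT signal) and uses three clusters, whose two
cut-offs delimit the blue/green/red bands.

Channel enhancement follows binning: per-channel clipping at the 0.1th and
99.99th percentiles, rescale to [0, 1], histogram matching onto the map of
log10(StD(I(t))) (256-bin monotone CDF lookup), and a final percentile
stretch saturating 0.35 % of pixels per tail.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .rendering import ColorImage
from .spectral import SpectrumCube, SpectrumKind
from .stack_io import MetricMap, MetricName, ValidationError

__all__ = [
    "NeuralGasConfig",
    "BinningMode",
    "neural_gas_1d",
    "cutoffs_from_units",
    "bin_spectrum",
    "histogram_match",
    "enhance_channels",
    "rgb_binning_preset",
]


@dataclass(frozen=True)
class NeuralGasConfig:
    """Neural-gas hyperparameters (learning rate and rank-neighborhood decay
    run geometrically from initial to final over ``epochs * n_samples``
    presentations)."""

    n_units: int = 2
    epochs: int = 10
    lr_initial: float = 0.1
    lr_final: float = 0.001
    radius_initial: float = 0.1
    radius_final: float = 0.01
    n_samples: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 2:
            raise ValidationError("need at least 2 units")
        if self.epochs < 1:
            raise ValidationError("need at least 1 epoch")
        if not (self.lr_initial >= self.lr_final > 0):
            raise ValidationError("need lr_initial >= lr_final > 0")
        if not (self.radius_initial >= self.radius_final > 0):
            raise ValidationError("need radius_initial >= radius_final > 0")


class BinningMode(enum.Enum):
    STANDARD = "standard"
    FFOCT = "ffoct"


def neural_gas_1d(
    weights: np.ndarray,
    freqs: np.ndarray,
    config: NeuralGasConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cluster spectral mass on the frequency axis; return sorted unit positions.

    Training samples are frequencies drawn with probability proportional to
    ``weights`` (the summed, DC-removed amplitude spectrum).  Each
    presentation ranks the units by distance to the sample and moves unit
    ``r`` by ``eps(t) * exp(-r / lambda(t)) * (x - w)``; ``eps`` and
    ``lambda`` decay geometrically from their initial to final values.
    """
    config = config or NeuralGasConfig()
    weights = np.asarray(weights, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if weights.shape != freqs.shape:
        raise ValidationError("weights and freqs must have the same length")
    if np.any(weights < 0):
        raise ValidationError("weights must be non-negative")
    total = weights.sum()
    if not total > 0:
        raise ValidationError("all-zero weights: no spectral mass to cluster")
    support = np.count_nonzero(weights)
    if support == 1:
        # degenerate distribution: every unit converges to the single mode
        return np.full(config.n_units, freqs[np.argmax(weights)], dtype=float)
    if support < config.n_units:
        raise ValidationError(
            f"only {support} distinct frequencies carry mass; "
            f"cannot place {config.n_units} units"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p = weights / total
    samples = rng.choice(freqs, size=config.epochs * config.n_samples, p=p)

    # init at distinct random samples
    distinct = np.unique(samples[: config.n_samples])
    if distinct.size < config.n_units:
        distinct = np.unique(samples)
    if distinct.size < config.n_units:
        raise ValidationError("fewer distinct samples than units")
    units = rng.choice(distinct, size=config.n_units, replace=False).astype(float)

    n_present = samples.size
    t = np.arange(n_present) / max(n_present - 1, 1)
    eps_sched = config.lr_initial * (config.lr_final / config.lr_initial) ** t
    lam_sched = config.radius_initial * (config.radius_final / config.radius_initial) ** t
    for x, eps, lam in zip(samples, eps_sched, lam_sched):
        ranks = np.argsort(np.argsort(np.abs(units - x)))
        units += eps * np.exp(-ranks / lam) * (x - units)
    return np.sort(units)


def cutoffs_from_units(units: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Midpoints of adjacent unit pairs, snapped to the nearest frequency-bin edge.

    Bin edges sit halfway between adjacent bin centers of ``freqs``.
    Coincident units produce a degenerate cutoff at the shared position
    (flagged with a warning).
    """
    units = np.sort(np.asarray(units, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    if units.size < 2:
        raise ValidationError("need at least 2 units")
    mids = 0.5 * (units[:-1] + units[1:])
    if np.any(np.diff(units) == 0):
        warnings.warn("coincident neural-gas units: degenerate cutoff")
    edges = 0.5 * (freqs[:-1] + freqs[1:])
    snapped = np.array([edges[np.argmin(np.abs(edges - m))] if edges.size else m for m in mids])
    return snapped


def bin_spectrum(
    cube: SpectrumCube,
    cutoffs: np.ndarray | list[float],
    mode: BinningMode | str = BinningMode.STANDARD,
) -> tuple[MetricMap, MetricMap, MetricMap]:
    """Sum per-pixel amplitudes into blue/green/red frequency bands.

    STANDARD: blue = DC amplitude alone; green = sum over (0, cutoff];
    red = sum over (cutoff, Nyquist].  FFOCT: DC and the first non-DC bin are
    discarded; the two cutoffs delimit the three bands low/mid/high →
    blue/green/red.
    """
    mode = BinningMode(mode) if isinstance(mode, str) else mode
    if cube.kind is not SpectrumKind.AMPLITUDE:
        raise ValidationError("binning operates on AMPLITUDE spectra")
    if not cube.includes_dc:
        raise ValidationError("binning needs the full cube including DC")
    cutoffs = np.sort(np.atleast_1d(np.asarray(cutoffs, dtype=float)))
    nyq = cube.nyquist_hz
    if np.any(cutoffs <= 0) or np.any(cutoffs >= nyq):
        raise ValidationError(f"cutoffs must lie strictly inside (0, {nyq}) Hz")
    freqs, amps = cube.freqs, cube.spectra
    if mode is BinningMode.STANDARD:
        if cutoffs.size != 1:
            raise ValidationError("STANDARD mode takes exactly one cutoff")
        c = cutoffs[0]
        blue = amps[0]
        green_sel = (freqs > 0) & (freqs <= c)
        red_sel = freqs > c
    else:
        if cutoffs.size != 2:
            raise ValidationError("FFOCT mode takes exactly two cutoffs")
        c1, c2 = cutoffs
        keep = np.ones(freqs.size, dtype=bool)
        keep[0] = False  # DC: background light, not static OCT signal
        if freqs.size > 1:
            keep[1] = False  # first non-DC bin discarded as well
        blue_sel = keep & (freqs <= c1)
        green_sel = keep & (freqs > c1) & (freqs <= c2)
        red_sel = keep & (freqs > c2)
        blue = amps[blue_sel].sum(axis=0)
    green = amps[green_sel].sum(axis=0)
    red = amps[red_sel].sum(axis=0)
    return (
        MetricMap(blue, MetricName.BIN_BLUE, units="amplitude"),
        MetricMap(green, MetricName.BIN_GREEN, units="amplitude"),
        MetricMap(red, MetricName.BIN_RED, units="amplitude"),
    )


# ---------------------------------------------------------------------------
# Channel enhancement
# ---------------------------------------------------------------------------

def _clip_rescale(values: np.ndarray, lo_pct: float, hi_pct: float) -> np.ndarray:
    lo, hi = np.percentile(values, [lo_pct, hi_pct])
    if hi <= lo:
        warnings.warn("constant channel: passthrough after rescale to 0")
        return np.zeros_like(values)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def histogram_match(channel: np.ndarray, target: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Monotone CDF lookup matching ``channel``'s histogram onto ``target``'s.

    Both inputs are finite arrays; output lives on the target's value range,
    rescaled to [0, 1].
    """
    ch = np.asarray(channel, dtype=float)
    tg = np.asarray(target, dtype=float)
    tg = tg[np.isfinite(tg)]
    if ch.max() == ch.min() or tg.max() == tg.min():
        warnings.warn("degenerate histogram-match input; returning rescaled channel")
        return _clip_rescale(ch, 0.0, 100.0)
    src_hist, src_edges = np.histogram(ch, bins=n_bins, range=(ch.min(), ch.max()))
    src_cdf = np.cumsum(src_hist) / ch.size
    tgt_hist, tgt_edges = np.histogram(tg, bins=n_bins, range=(tg.min(), tg.max()))
    tgt_cdf = np.cumsum(tgt_hist) / tg.size
    # per-pixel source quantile, then inverse target CDF
    idx = np.clip(np.searchsorted(src_edges, ch, side="right") - 1, 0, n_bins - 1)
    quantiles = src_cdf[idx]
    tgt_centers = 0.5 * (tgt_edges[:-1] + tgt_edges[1:])
    matched = np.interp(quantiles, tgt_cdf, tgt_centers)
    # place on [0,1] using the *target's* range so the matched distribution
    # stays aligned with the (identically rescaled) target distribution
    lo, hi = tg.min(), tg.max()
    return np.clip((matched - lo) / (hi - lo), 0.0, 1.0)


def _percentile_stretch(values: np.ndarray, tail_fraction: float) -> np.ndarray:
    pct = 100.0 * tail_fraction
    return _clip_rescale(values, pct, 100.0 - pct)


def enhance_channels(
    channels: tuple[MetricMap, MetricMap, MetricMap],
    target: MetricMap,
    stretch_sat: float = 0.0035,
    clip_percentiles: tuple[float, float] = (0.1, 99.99),
) -> ColorImage:
    """Contrast pipeline: clip → rescale → histogram-match to log-StD → stretch.

    ``channels`` arrive in (blue, green, red) order; the returned image is RGB.
    """
    blue, green, red = channels
    if not (blue.values.shape == green.values.shape == red.values.shape == target.values.shape):
        raise ValidationError("channel/target shapes differ")
    out = []
    ranges = {}
    for m in (red, green, blue):
        rescaled = _clip_rescale(m.values, *clip_percentiles)
        matched = histogram_match(rescaled, target.values)
        stretched = _percentile_stretch(matched, stretch_sat)
        out.append(stretched)
        ranges[m.name.value] = (float(m.values.min()), float(m.values.max()))
    rgb = np.stack(out, axis=-1)
    return ColorImage(
        np.clip(rgb, 0.0, 1.0),
        provenance={
            "clip_percentiles": clip_percentiles,
            "stretch_sat": stretch_sat,
            "target": target.name.value,
            "channel_ranges": ranges,
        },
    )


# ---------------------------------------------------------------------------
# Full preset
# ---------------------------------------------------------------------------

def rgb_binning_preset(
    stack,
    mode: BinningMode | str = BinningMode.STANDARD,
    config: NeuralGasConfig | None = None,
    cutoff_override: np.ndarray | list[float] | None = None,
):
    """Full RGB-binning pipeline on a stack.

    Returns ``(maps, image, cutoffs)`` where maps holds the three channel sums
    plus the log-StD target map.
    """
    from .spectral import compute_spectrum, temporal_stats

    mode = BinningMode(mode) if isinstance(mode, str) else mode
    config = config or NeuralGasConfig(n_units=3 if mode is BinningMode.FFOCT else 2)
    if mode is BinningMode.FFOCT and config.n_units != 3:
        raise ValidationError("FFOCT mode requires a 3-unit neural gas")
    cube = compute_spectrum(stack, SpectrumKind.AMPLITUDE, detrend="none")
    if cutoff_override is not None:
        cutoffs = np.sort(np.atleast_1d(np.asarray(cutoff_override, dtype=float)))
    else:
        summed = cube.spectra.reshape(cube.freqs.size, -1).sum(axis=1)
        start = 2 if mode is BinningMode.FFOCT else 1  # remove DC (and first bin in FFOCT)
        units = neural_gas_1d(summed[start:], cube.freqs[start:], config)
        cutoffs = cutoffs_from_units(units, cube.freqs)
        nyq = cube.nyquist_hz
        cutoffs = np.clip(cutoffs, np.min(cube.freqs[1:]) / 2, nyq * (1 - 1e-9))
    blue, green, red = bin_spectrum(cube, cutoffs, mode)
    stats = temporal_stats(stack)
    target = MetricMap(stats.log_std, MetricName.LOG_STD, units="log10(intensity)")
    image = enhance_channels((blue, green, red), target)
    image.provenance["cutoffs_hz"] = [float(c) for c in cutoffs]
    image.provenance["mode"] = mode.value
    maps = {"BIN_BLUE": blue, "BIN_GREEN": green, "BIN_RED": red, "LOG_STD": target}
    return maps, image, cutoffs
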