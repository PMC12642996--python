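# Methods

This note records the models, conventions and numerical choices behind
`doctkit`, in the order the processing runs.

## Stack model and dB conversion

A measurement is a `(time, row, col)` array of non-negative linear OCT
intensity with a frame rate; B-scan rows are depth, en face rows are y.
Intensity units are arbitrary (camera counts are used as-is): every metric
is either a ratio/variance, invariant to the unit, or documents its unit
dependence (PFI is homogeneous of degree 1; the RGB band sums carry the
input unit).

dB conversion is `10·log10(max(I, floor))`. The floor defaults to the
stack's smallest positive sample × 1e−6, keeping the log finite on zero
pixels without perturbing signal; it is overridable wherever dB enters a
pipeline. The conversion is monotone and offset-equivariant
(`dB(cI) = dB(I) + 10log10(c)`), which is what makes variance-type dB
metrics (LIV, aLIV) exactly invariant to multiplicative intensity rescaling.

## Spectral engine

Records are short (32–512 frames), so the spectral estimator is a plain
one-sided periodogram: no taper, no Welch segmenting (there is no room for
segments), no zero-padding. Frequencies are k·rate/N, k = 0…⌊N/2⌋. POWER
normalization is |DFT|²/N; only ratios and fit shapes matter downstream, so
the constant is a documented convention, not a tunable. `detrend="mean"`
removes the temporal mean before transforming and is used ahead of the
motility power-law fits so the additive term b₀ captures white noise rather
than DC leakage; `detrend="none"` keeps DC for the RGB static channel.

Time statistics use the population (1/N) variance convention throughout,
with one deliberate exception: the lag-one product moment
Γ_I = (1/(N−1)) Σ_{k=1}^{N−1} I(t_k)I(t_{k+1}) keeps its printed 1/(N−1)
normalization — it is a raw product moment, not a mean-removed
autocorrelation, and the motility amplitude depends on that exact form.

## PSD moments

PFI is the temporal mean of |I(t+1) − I(t)| on linear intensity at lag one
frame. ⟨PSD⟩ and StD(PSD) are the power-weighted mean and spread of the
positive-frequency power spectrum; the DC bin is always excluded, and
zero-power pixels are flagged invalid (NaN) rather than zeroed. StD(PSD)
is interpreted as the power-weighted spectral spread about ⟨PSD⟩ — the
plain second central moment in frequency. The preset renders hue from
inverted ⟨PSD⟩ clipped at the 0.1/99.9 percentiles (slow → blue, fast →
red), saturation from inverted StD(PSD) lower-clipped at 5 % (narrow,
directional spectra saturated; broadband/Brownian washed out), and
brightness from PFI upper-clipped at 99.9 %; B-scan brightness switches to
a decimal log scale to compensate depth-dependent SNR.

## RGB frequency binning

Binning operates on amplitude (|DFT|) spectra. The cut-off between the
green and red bands is found by clustering the image-summed, DC-removed
spectrum on the frequency axis with a 1-D neural gas: 10 epochs over a
10 000-sample training set drawn with probability proportional to spectral
mass; learning rate 0.1 → 0.001 and rank-neighborhood constant 0.1 → 0.01,
both on geometric schedules (the endpoints are fixed; the schedule shape
was open and geometric decay is the standard choice). With λ ≤ 0.1 the
non-winner update weight is e^(−1/0.1) ≈ 5·10⁻⁵, so training is effectively
hard competitive learning. The training-set construction (sampling
frequencies by spectral mass) is this package's interpretation — the
clustering must live on the frequency axis for "the cut-off frequency
centered between the units" to be meaningful — and is the module's main
fidelity risk against other implementations. Cut-offs are midpoints of
adjacent unit positions snapped to the nearest frequency-bin edge.

Standard binning: blue = DC amplitude alone; green = Σ amplitudes in
(0, cutoff]; red = Σ in (cutoff, Nyquist]. The full-field variant discards
the DC *and* the first non-DC bin (their DC carries unmodulated background
light, not static signal) and uses a 3-unit gas whose two cut-offs delimit
blue/green/red.

Enhancement per channel: clip at the 0.1th and 99.99th percentiles
(linear-interpolated percentile values), rescale to [0, 1], histogram-match
onto the map of log10(StD(I(t))) via a 256-bin monotone CDF lookup placed
on the target's value range, then a deterministic percentile stretch
saturating 0.35 % of pixels per tail. The stretch replaces an interactive
auto-contrast step used elsewhere so that reruns are bitwise reproducible.
Matching makes the three channels' distributions identical, so channel
dominance comparisons between channels are effectively rank comparisons.

## LIV, aLIV, Swiftness

LIV is the population time-variance of dB intensity. For the window-size
curve, window sizes default to ⌈geomspace(2, N, 9)⌉ deduplicated (for
N = 32: 2, 3, 4, 6, 8, 12, 16, 23, 32); per size w the LIV is averaged over
windows placed at stride w/2 (disjoint placement is an option), and the
abscissa is T = (w − 1)·frame period, so a 1-frame window sits at T = 0
where the saturation law passes through the origin. The fit is
LIV(T) = a(1 − e^(−sT)) with a, s ≥ 0, initialized at a₀ = max LIV and
s₀ = 1/T_half (first T reaching a₀/2; fallback 1/median T). aLIV ≡ a,
Swiftness ≡ s. Curves that are zero to float precision return a = 0 with
the rate flagged invalid (the time constant of a flat zero curve is
undefined). Known limitation: when a record is too short for the curve to
approach saturation, (a, s) becomes ill-conditioned — a can blow up with
a·s roughly fixed — which is visible on 32-frame records; the fusion
renderings are robust because display ranges clip, but single-pixel aLIV
values from unsaturated curves should not be over-interpreted.

Renderings: en face fuses Swiftness → hue (blue→green→red), aLIV →
brightness with saturation fixed at maximum; cross sections fuse
Swiftness → hue, aLIV → saturation, mean dB intensity → brightness. The
conventional single-metric view puts the metric on a red→green hue arc over
dB-intensity brightness. The subsampled-record workaround for very long
en face stacks (e.g. 64 frames at 8-frame stride from 512) is exposed as
options, not hardcoded.

## Motility metrics

M = √(max(Γ_I − ⟨I⟩², 0))/⟨I⟩. The radicand is clamped at zero — the
printed form can go negative for lag-one anti-correlated or noise-dominated
pixels — and values below the float-cancellation floor (10⁻¹²·⟨I⟩²) are
treated as zero so static pixels are exactly 0. Because white noise cancels
from the lag-one product, M's only SNR dependence is through the mean shift
of additive noise: M(SNR) ∝ 1/(1 + 1/SNR), i.e. ~2 % between SNR 10 and ∞
— the quantitative content of "nearly SNR-independent above SNR 1".

Spectra for the power-law fit are mean-detrended periodograms averaged over
each pixel's 3×3 neighborhood (center included by default; a
center-excluded 8-neighbor mode is available), reflect-padded at edges.
The fit is PSD(f) = c₀f^(−α) + b₀ on positive frequencies with all three
parameters bounded ≥ 0, solved by trust-region least squares. Default
weights are relative-error weights 1/(P + ε)² (ε = 10⁻¹²·max P) so the
steep low-frequency bins do not dominate; `none` and `inverse-f` rules are
selectable. Initialization: α₀ = −slope of a log–log line on the upper
half of the frequency axis (clamped ≥ 0), c₀ from its intercept,
b₀ = min P.

R² is defined as 1 − SSE_w/SST_w with SSE_w the weighted residual sum and
SST_w the weighted deviation from the *plain mean level* of the spectrum —
that is, variance explained relative to a flat-spectrum (noise-only) null.
This choice is deliberate: measuring SST about the *weighted* mean caps R²
near 0.56 even for a clean 1/f^1.5 periodogram after 9-fold averaging
(periodogram noise is ~χ²; the weighted mean sits at the high-frequency
floor), destroying the ">0.95 indicates motility" reading. Against the
flat null, 1/f^1.5 spectra score ≈ 0.99 and flat spectra ≈ 0.3–0.4, which
matches the metric's intended semantics: α ≈ 0 and low R² both flag a
noise-dominated spectrum.

Rendering uses manual thresholds (α → hue, R² → saturation, M →
brightness); percentile thresholds are deliberately not applied here.

## Rendering engine

Channels normalize by percentile or manual (lo, hi) bounds, clip, map
affinely to [0, 1], and optionally invert. Hue travels a configurable arc;
the default 240°→0° runs blue→green→red without wrapping through magenta.
Invalid pixels (failed fits, zero-power spectra) always render black —
never colored — so fit failures cannot masquerade as fast dynamics.
Constant maps under a percentile rule degenerate to 0.5 with a warning.

## Phantom generator

Dynamics are modeled at the complex-field level so intensity fluctuation
inherits fully developed speckle statistics (unit contrast, exponential
intensity): static = frozen circular-Gaussian field; Brownian =
Ornstein–Uhlenbeck field with correlation time τ (Lorentzian intensity
PSD); directional tone = static reference beating against a phase-rotating
field at f₀ (intensity line at f₀); motility = field spectrally shaped to
|spectrum| ∝ f^(−α/2) so the intensity PSD tail falls as f^(−α); white
noise = uncorrelated field per frame. Detector noise is additive
exponential intensity (shot-noise-like, non-negative by construction);
instrument vibration is a global narrowband intensity modulation (e.g. the
~20 Hz line that scanned systems pick up). A separate shaped-noise
generator produces real Gaussian series whose periodogram averages
c₀f^(−α) + b₀ exactly, for validating spectral estimators at the
periodogram level without speckle statistics.

Presets mirror three acquisition regimes: en face 512 frames @ 100 Hz
(static/slow/fast Brownian/tone bands); B-scan 150 @ 108 Hz (40 Hz cilia
tone over a τ = 1 s epithelium over static connective tissue at 16× the
dynamic layers' reflectivity — static structures dominate OCT brightness —
plus a 3 % 20 Hz vibration); B-scan 32 @ 4.9 Hz (fast core, slow ring,
static background). The 16× static reflectivity matters: with
equal-reflectivity layers, the exponential per-pixel speckle statistics of
the DC channel make the static/dynamic rank distributions overlap so
heavily that no binning algorithm could reach clean per-layer channel
dominance; a realistic brightness contrast restores it.

What the phantoms do *not* emulate: the OCT point-spread function and
confocal gating, depth-dependent SNR decay, sample drift and bulk motion,
and spatially correlated speckle (pixels are independent). Tests passing
on these phantoms therefore validate the *algorithms* — formula
correctness, fit recovery, class separability under ideal speckle — not
robustness to real-world acquisition artifacts.

## Problem sizes and determinism

Test and acceptance runs use desk-scale images (≤ 48×48 pixels, 32–512
frames, ≤ 100 Monte-Carlo replicates), chosen so the full suite runs in
well under a minute of fitting time while every statistical check retains
comfortable margins. Every stochastic stage (phantom fields, neural-gas
sampling) draws from a named substream of one top-level seed, so adding a
stage never perturbs another's draws and CLI reruns are bitwise
reproducible.
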