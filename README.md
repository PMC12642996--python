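# doctkit

**Dynamic OCT (DOCT) analysis toolkit** — four families of
speckle-fluctuation metrics computed from repeated OCT frames, one shared
spectral engine, one shared HSB rendering engine, and a dynamic-speckle
phantom generator that provides ground-truth inputs for testing.

Dynamic OCT acquires a time series of OCT images at a fixed sample position
and contrasts tissue by the *temporal* fluctuation of the backscattered
speckle, which reports on sub-resolution scatterer motion: organelle
transport, cytoplasmic motility, diffusion. Several research communities
built their own post-processing around this idea; `doctkit` implements the
four most widely used algorithm families on a common stack container so they
can be applied, compared and tested on the same data:

| family | metrics | core quantity |
|---|---|---|
| PSD moments | PFI, ⟨PSD⟩, StD(PSD) | mean ⟨\|ΔI(t)\|⟩ and the power-weighted mean frequency ⟨PSD⟩ = Σ f·P(f) / Σ P(f) and spread of the per-pixel power spectrum (DC excluded) |
| RGB frequency binning | blue/green/red band sums | per-pixel amplitude spectrum split at a cut-off frequency placed by neural-gas clustering of the image-summed spectrum; DC amplitude = static (blue) channel |
| LIV family | LIV, aLIV, Swiftness | time variance of dB intensity vs. window length T, fitted with LIV(T) = a·(1 − e^(−sT)); aLIV = a (dB², magnitude), Swiftness = s (s⁻¹, speed) |
| motility family | M, α, R² | M = √(Γ_I − ⟨I⟩²)/⟨I⟩ from the lag-1 product moment Γ_I = (1/(N−1)) Σ I(t_k)I(t_{k+1}); constrained weighted fit of PSD(f) = c₀f^(−α) + b₀ |

Each family ships with its publication rendering preset (HSB or RGB fusion
of three metric maps). The phantom module generates complex-field speckle
movies with region-wise known dynamics (static, Ornstein–Uhlenbeck/Brownian,
directional tone, 1/f^α motility, white noise) at the three acquisition
regimes the presets emulate (en face 512 frames @ 100 Hz; B-scan 150 @
~108 Hz; B-scan 32 @ 4.9 Hz).

## Worked example

Generate a spheroid-regime phantom (32 frames at 4.9 Hz, B-scan geometry:
fast-decorrelating core, slow ring, static background) and run all four
pipelines on it:

```bash
doctkit phantom --preset spheroid_like --rows 24 --cols 24 --seed 7 --out demo
doctkit all --input demo/spheroid_like_stack.tif --frame-rate 4.9 \
        --modality b_scan --seed 7 --out demo/analysis
```

The run logs each metric's range as it is produced:

```
INFO doctkit: MEAN_PSD ranges from 0.2614 to 1.748 Hz
INFO doctkit: STD_PSD ranges from 0.298 to 0.9301 Hz
INFO doctkit: PFI ranges from 0.0026 to 1.368 intensity
INFO doctkit: cutoff frequencies: 1.15 Hz
INFO doctkit: ALIV ranges from 0.0001449 to 6.677e+06 dB^2
INFO doctkit: SWIFTNESS ranges from 1.109e-06 to 10.78 1/s
INFO doctkit: ALPHA ranges from 2.257e-30 to 17.14 dimensionless
INFO doctkit: R2 ranges from 0.1223 to 0.9999 dimensionless
INFO doctkit: M ranges from 0 to 1.324 dimensionless
```

Reading these numbers: ⟨PSD⟩ stays below the 2.45 Hz Nyquist limit of the
4.9 Hz frame rate; the neural gas places the green/red cut-off at 1.15 Hz,
between the slow ring's and fast core's spectral mass; R² near 1 marks
pixels whose spectrum is 1/f-like rather than flat. The extreme per-pixel
aLIV values are honest fit pathology on a 32-frame record — pixels whose
LIV curve has not begun to saturate give an ill-conditioned (a, s) pair —
and are clipped away by the display ranges of the fusion rendering
(`demo/analysis/*_fusion.png`, four color panels plus 14 float-TIFF metric
maps and JSON provenance sidecars).

Everything is scriptable from Python as well:

```python
import doctkit as dk

spec = dk.preset_stacks("TRACHEA_LIKE", rows=48, cols=48, seed=11)
stack, labels = dk.generate_phantom(spec)
maps, image, cutoffs = dk.rgb_binning_preset(stack)
maps, fusion, single = dk.aliv_swiftness(stack)
```

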