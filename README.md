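# hsfli

Depth-selective macroscopic fluorescence lifetime imaging with
high-spatial-frequency structured illumination — fully in silico.

The package simulates time-gated, three-phase sinusoidally illuminated
fluorescence acquisitions of turbid phantoms, decomposes them into planar
(`I_DC`), surface-modulated (`I_AC`) and subsurface (`I_sub`) components,
calibrates spatial frequency against sampling depth through a Monte
Carlo–derived fluorescence modulation transfer function (MTF), and
recovers depth-selective lifetimes and FRET fractions by IRF-convolved
nonlinear least-squares fitting.

## Modules

| module | contents |
| --- | --- |
| `hsfli.core_io` | `AcquisitionConfig`, `GatedStack`, `InstrumentResponse`; HDF5 native container, TIFF+JSON interchange |
| `hsfli.structured` | 8-bit sinusoidal pattern generation, three-phase demodulation (per pixel and per gate), source modulation depth, MTF and the MTF-vs-depth Monte Carlo sweep |
| `hsfli.mcfluor` | voxelized two-step time-resolved Monte Carlo (numba kernel): excitation transport, fluorescence source formation (yield + exponential lifetime), emission transport, launch-position pattern reweighting |
| `hsfli.camera_phantoms` | phantom builders (tilted tube, 8-tube depth ladder, well plate, two-layer), Gaussian IRF synthesis, gated-ICCD camera model (boxcar/trapezoid gates, gain, Poisson noise), end-to-end dataset generator with ground-truth sidecar |
| `hsfli.lifetime` | decay model Γ(t) = IRF ⊛ Σ Aᵢ e^(−t/τᵢ), NLSF (mono/bi-exponential, Poisson weights, optional time shift and IRF oversampling), FRET fraction f₁, amplitude-weighted lifetime τₐ, per-pixel and per-ROI fitting |
| `hsfli.pipeline` / `hsfli.cli` | YAML-configured end-to-end runs, MTF calibration with depth-limit report, report rendering; CLI verbs `simulate`, `demodulate`, `mtf`, `fit`, `pipeline`, `report` |

## CLI

```bash
# end-to-end: simulate a 3-tube depth ladder, demodulate, fit, tabulate
hsfli pipeline --photons 200000 --seed 1 --out run1

# MTF vs depth sweep with a depth-limit report at threshold 0.01
hsfli mtf --fx 0.2 --fx 0.6 --depths 0.5:3.0:0.5 --photons 300000 --out run1

# demodulate three stored phase stacks
hsfli demodulate run1/stacks/fx0.60_phase0.h5 run1/stacks/fx0.60_phase1.h5 \
    run1/stacks/fx0.60_phase2.h5 --out run1/demod
```

Run configs are YAML; see `hsfli.pipeline.RunConfig` for the schema.

## Notes on estimators

The three-phase AC magnitude √2/3·√(ΣΔ²) folds noise upward; the package
provides (a) a Poisson-variance debias (`demodulate_triplet(...,
debias=True)`) and (b) phase-aligned coherent ROI demodulation
(`demodulate_roi_gated`) whose complex averaging suppresses the fold by
~√N_ROI. High-level fitting paths use (b); the raw per-pixel estimator is
kept exact per its defining identity.
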