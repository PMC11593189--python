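# hsichem

Hyperspectral-imaging chemometrics pipeline for analyzing chewed food boluses
(moisture content, reducing sugars, chewiness) during oral processing,
exercised end-to-end on a synthetic scene generator so every stage is testable
without instrument data.

## What it does

- **`hsichem.synthetic`** — generates synthetic scenes: Gaussian-band
  endmember spectra (water 960/1450 nm, starch/sugar ~990 nm, fat 1200 nm,
  broad fiber band), smooth spatial concentration fields with a controllable
  coefficient of variation, Beer–Lambert-style reflectance `R = exp(-Σ c·ε)`,
  dark/white reference frames and detector noise. Label trajectories over
  chew time (0/6/12/18 s) are saturating curves anchored at measured endpoint
  values for white and 50% whole-wheat bread formulations.
- **`hsichem.io`** — ENVI-style cube reading/writing (bsq/bil/bip), black/white
  reflectance calibration `R = (I − B)/(W − B)`, center/explicit ROI
  extraction, mean spectra, threshold-based foreground masking.
- **`hsichem.preprocess`** — the three spectral pretreatments compared in the
  pipeline: Savitzky–Golay smoothing (SG), Gaussian filtering (GF) and
  normalization (N: unit-vector, min-max or SNV), applied per spectrum to
  vectors, matrices or whole cubes.
- **`hsichem.chemometrics`** — from-scratch NIPALS PLS1 and SVD-based PCR with
  mean-centering, Kennard–Stone or random calibration/prediction splits,
  seeded k-fold / leave-one-out cross-validation, parsimonious latent-variable
  selection and the six metrics RC²/RMSEC, RCV²/RMSECV, RP²/RMSEP, crossed
  into a pretreatment × model comparison table.
- **`hsichem.mapping`** — pixel-wise application of a trained model to a
  calibrated cube, shared percentile-robust display scaling, deterministic
  blue→red pseudo-color PNG rendering with sidecar metadata.
- **`hsichem.texture`** — library-free symmetric normalized GLCM and its
  contrast `Σ (i−j)² P(i,j)` averaged over the four distance-1 directions,
  map quantization, Spearman correlation matrices with significance stars
  (t-approximation, exact permutation option for small n), gravimetric
  moisture arithmetic and the linear absorbance↔concentration standard curve.
- **`hsichem.pipeline` / `hsichem.cli`** — a seeded, deterministic
  orchestration of generate → calibrate → ROI → preprocess → fit/compare →
  map → texture → correlate with YAML configuration.

## CLI

```bash
hsichem run-all --seed 3 --outdir out/            # full pipeline, small default
hsichem generate  --outdir out/ --max-scenes 8    # ENVI scenes + sample table
hsichem calibrate --scenes out/scenes --outdir out/cal
hsichem fit --spectra out/cal/mean_spectra.csv --table out/sample_table.csv --outdir out/fit
hsichem map --cube out/cal/B0_t0_p0_r0_refl.hdr --model out/fit/model_mc.json --outdir out/maps
hsichem texture --maps 'out/maps/*_map.csv' --outdir out/tex
hsichem correlate --table out/sample_table.csv --contrast-table out/contrast_table.csv --outdir out/corr
```

All commands accept `--config config.yaml` (see `PipelineConfig.from_dict`
for the schema) and `--seed` to override the global seed; every stage seed is
derived from the global one by a stable hash, so runs are bit-reproducible.

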