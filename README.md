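# her2forecast

Imaging-informed, mechanically coupled reaction–diffusion forecasting of
breast-tumor response to neoadjuvant chemotherapy and HER2-targeted
therapy.

The package derives voxelwise modeling quantities from multi-modal breast
imaging (multi-b-value diffusion-weighted MRI, dynamic contrast-enhanced
MRI, antibody-PET uptake), calibrates a tumor-growth model on two imaging
time points, and forecasts response at surgery with and without the
targeted-therapy term:

- **`grid_io` (`her2forecast.grid`)** — volumetric data model, NIfTI I/O,
  block down-sampling, trilinear resampling, YAML run configuration.
- **`synthetic_patient` (`her2forecast.synthetic`)** — virtual-patient
  generator: aligned two-visit datasets (DW/CE stacks, PET, masks, dose
  schedule) with known ground truth, including a packaged pCR-like /
  non-pCR-like pair and parameter-recovery twins.
- **`image_quantities` (`her2forecast.quantities`)** — ADC fitting,
  fuzzy-c-means tumor ROI, k-means tissue labels, normalized AUC and PET
  drug-distribution maps, ADC-to-cellularity conversion, carrying
  capacity, tumor volume.
- **`mechanics` (`her2forecast.mechanics`)** — cell-gradient-driven linear
  elastic equilibrium (sparse direct/ILU-preconditioned solver), von Mises
  stress, exponential stress damping of tumor diffusivity.
- **`forward_model` (`her2forecast.model`)** — explicit finite-difference
  integration (Δt = 0.25 day, 7-point flux-form stencil, no-flux breast
  boundary) of logistic growth + therapy sink, with the MRI-based and
  PET/MRI-based variants.
- **`calibration` (`her2forecast.calibrate`)** — bounded least-squares fit
  of the global rates {D₀, α₁, α₂, β₁, β₂, μ} and the voxelwise
  proliferation map k(x) on a factor-4 down-sampled grid.
- **`forecast` (`her2forecast.forecast`)** — re-initialization at scan 2,
  run to surgery, percent-change response metrics, and the two-variant /
  two-patient comparison report.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including two
seeded multi-minute experiments (parameter recovery on a synthetic twin
and the qualitative two-patient response pattern). The full suite takes
roughly 15 minutes on one CPU. One acceptance sub-check is expected to
fail: the chemotherapy efficacy/decay split (α₁, β₁) is structurally
non-identifiable from two imaging time points (see the note inside
`test_criterion_6_parameter_recovery`); D₀, μ, and the k-map recovery
checks pass.

## CLI

All stages share one on-disk layout written by `synthesize`:

```bash
her2forecast --config run.yaml --seed 3 --outdir data synthesize
her2forecast --config run.yaml --outdir derived derive --data data --scan 1
her2forecast --config run.yaml --outdir fit calibrate --data data --variant pet_mri
her2forecast --config run.yaml --outdir fit predict  --data data --calibration fit --variant pet_mri
her2forecast --config run.yaml --outdir fit compare  --prediction-dir fit
```

A minimal `run.yaml`:

```yaml
study:
  chemo_half_life_days:
    drug1: [4.0, 12.0]
    drug2: [1.0, 3.0]
synthetic:
  shape: [24, 24, 24]
  spacing: [2.0, 2.0, 2.0]
  scan2_time: 42.0
  surgery_time: 115.0
```

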