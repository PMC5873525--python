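# pasquant

Quantification pipeline for flat passive aerosol samplers analysed by
microscopy.  Calibrated grayscale micrographs of the collection surface are
segmented into particle tables; each particle's airborne-concentration
contribution is recovered by inverting the still-air deposition flux under
one of three mesh-cap attenuation models; totals are reported for the PM10,
PM2.5 and respirable sampling conventions, with blank correction and
dM/dlog(da) size distributions.  A statistics module provides mixed-model
intraclass correlations with bootstrap confidence intervals, paired
squared-deviation model comparisons, through-origin regression and
descriptives.  A synthetic module generates ground-truth-known fixtures for
every stage: lognormal aerosols deposited at size-dependent velocity,
rendered micrographs, and multi-occasion study tables.

## Layout

| module               | contents                                                                 |
| -------------------- | ------------------------------------------------------------------------ |
| `pasquant.physics`   | slip correction, settling/diffusion/deposition velocities, the three gamma models (`mesh`, `hybrid`, `area`), projected ↔ aerodynamic diameter conversion, particle mass |
| `pasquant.imaging`   | Rényi-entropy and triangle thresholding, connected-component extraction, area/edge filter rules, edge-exclusion geometry, particle-table CSV I/O |
| `pasquant.quantify`  | flux-inversion mass concentrations, fraction efficiency curves, blank correction, binned size distributions |
| `pasquant.stats`     | mixed-model ICC (REML via statsmodels, plus a fast balanced-design path), basic-bootstrap CIs, model deviation t-tests, origin regression, descriptives |
| `pasquant.synthetic` | deposition simulator, micrograph renderer, study-table generator |
| `pasquant.cli`       | `pasquant analyze / quantify / simulate / stats` subcommands, YAML config |

## CLI

```sh
# generate ground-truth fixtures (particle CSV + manifest + optional TIFFs)
pasquant simulate --seed 1 --mmad 5 --gsd 2 --mass 1.0 --render 3 --out-dir fixtures/

# segment a directory of TIFF/PNG micrographs into a particle table
pasquant analyze fixtures/ --config config.yaml --out particles.csv

# concentrations for every gamma model and fraction
pasquant quantify particles.csv --model all --out results.csv

# ICC report from a long-format study table
pasquant stats study.csv --b 1000 --seed 1 --out report.csv
```

All commands are deterministic given inputs, config and seed.  Exit codes:
0 ok, 1 input error, 2 configuration error.  A config YAML can pin every
physical constant (temperature, viscosity, mean free path, shape factors,
densities, filter rules, blank groups); defaults follow the standard
deployment: 1.71 px/µm calibration, 450 × 600 µm tiles, 8 h duration,
60-tile analyzed area, open-area ratio 0.27.

## Notes

- The analyzed-image area enters the mass balance directly; the fraction of
  the sampler opening covered by the images is carried as metadata only
  (deposition flux per unit area is uniform in expectation).
- Entropy thresholding genuinely places its threshold a couple of noise
  standard deviations above the background mode, so noisy renders segment
  with one-pixel specks; the triangle method is the robust fallback, as
  field practice also found.
- Basic-bootstrap ICC intervals undercover at small occasion counts; see
  `icc_bootstrap_ci`'s docstring for measured calibration and a parametric
  alternative.
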