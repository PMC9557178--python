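# geoprev

Bayesian geostatistical prevalence mapping for georeferenced cluster surveys.

`geoprev` fits a binomial spatial regression with a logit link: per cluster
*j*, `Y_j ~ Binomial(n_j, p_j)` with
`logit(p_j) = alpha + x_j . beta + zeta_j`, where `zeta` is a zero-mean
latent Gaussian field with Matérn covariance (range `rho`, marginal SD
`sigma`, smoothness `nu`, `kappa = sqrt(8 nu) / rho`). Priors are an
improper flat prior on the intercept, Normal(0, precision 1e-4) on each
coefficient, and penalized-complexity priors on the field hyperparameters.
Inference is MCMC (elliptical slice sampling for the latent field, adaptive
random-walk Metropolis for the fixed effects and hyperparameters, plus an
ancillary interweaving move for the confounded fixed-effect/field
direction). The package also produces kriging-style posterior prevalence
surfaces with 95% credible bounds, WAIC model comparison, descriptive
prevalence tables with trend/reduction statistics, and a synthetic
multi-wave cluster-survey generator with known ground truth so the whole
pipeline is testable without restricted survey microdata.

## Layout

| module | contents |
| --- | --- |
| `geoprev.core_io` | cluster CSV, text raster and GeoJSON region I/O; nearest-cell covariate extraction; point-in-polygon region assignment; equirectangular projection |
| `geoprev.synthetic` | covariate surfaces, cluster placement, latent-field draws, binomial outcomes, bundled `simulate_dataset` |
| `geoprev.descriptives` | count-weighted prevalence tables, trend series, relative reduction rate |
| `geoprev.covariate_prep` | population z-scoring with stored constants; pairwise collinearity screen |
| `geoprev.spatial_model` | Matérn correlation/covariance, binomial likelihood, priors, MCMC (`fit_mcmc`), WAIC, model ranking |
| `geoprev.prediction` | exact Gaussian conditional field (kriging), posterior prevalence surfaces |
| `geoprev.pipeline` / `geoprev.cli` | config-driven orchestration with a reproducibility manifest |

## CLI

All stages run from one YAML config:

```bash
geoprev run --config config.yaml --seed 1 --out runs/demo
geoprev simulate --config config.yaml     # or any single stage:
geoprev describe|prep|fit|predict|compare --config config.yaml
```

Example config:

```yaml
seed: 1
out_dir: runs/demo
simulate:
  counts_per_wave: [535, 517, 571, 619, 305]
  grid: {n_rows: 25, n_cols: 25, origin_lon: 34.0, origin_lat: 14.0, cell_size: 0.2}
  beta_true: [-0.39, 0.09]
chains: {n_chains: 2, n_iter: 20000, burn_in: 5000}
waves_to_fit: [pooled, "2000", "2005", "2011", "2016", "2019"]
predict_draws: 200
```

Each run writes a `manifest.json` recording the seed, per-stage outputs and
a sha256 per file; re-running with the same config and seed reproduces the
hashes bit-for-bit.

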