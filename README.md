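# bgwr

Bayesian geographically weighted regression (BGWR) for areal data, with
per-region variable selection and probabilistic clustering of the resulting
coefficient surfaces.

Spatial epidemiology and small-area analysis often need regression
coefficients that vary over space: the association between a covariate and
an outcome in one district need not hold in another.  GWR handles this by
fitting a local regression at every region `s`, weighting each observation
`i` by a kernel `w_i(s) = f(d_i(s) | b)` that decays with distance under a
bandwidth `b`.  This package implements the Bayesian version

    y_i | beta(s), sigma^2(s) ~ N(x_i' beta(s),  sigma^2(s) / w_i(s))
    beta_j(s) ~ N(0, sigma_beta^2),   sigma^2(s) ~ IG(alpha1, alpha2)
    sigma_beta^2 ~ IG(a_beta, b_beta),   b ~ Uniform(0, D)

fitted by Metropolis-within-Gibbs MCMC with conjugate, region-batched
updates, and adds:

- **Per-region variable selection** — reversible-jump indicators
  `gamma_j(s) ~ Bern(psi_j)` so each covariate can matter in some regions
  and not others, with posterior inclusion probabilities per
  (region, covariate).
- **Coefficient clustering** — Gaussian-mixture (EM + BIC) and
  Dirichlet-process-mixture (truncated stick-breaking) clustering of the
  region-wise posterior coefficient vectors, consensus partitions by
  Dahl's least-squares coassignment method or the per-region mode, a
  two-stage across-sample aggregation, and Rand-index accuracy scoring.
- **Spatial weights** — Euclidean / great-circle / graph-hop distances and
  exponential / Gaussian / bi-square kernels, plus leave-one-out CV
  bandwidth selection.
- **Model assessment** — WAIC and DIC with their effective-parameter
  measures.
- **Synthetic study designs** — seeded generators for a 64-region
  constant-coefficient design and a 159-region spatially varying design
  with three contiguous coefficient clusters, for recovery and accuracy
  benchmarking.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import bgwr

# a 64-region lattice, 3 observations per region, beta = (2, 0, 0, 4, 8)
study = bgwr.louisiana_like(seed=1)

draws = bgwr.run_bgwr(
    study.table, study.area_map,
    kernel=bgwr.KernelSpec("exponential"),        # bandwidth estimated
    priors=bgwr.PriorSpec(D=100.0),
    settings=bgwr.McmcSettings(iterations=3000, burn_in=1000, seed=1),
)
print("posterior means:", draws.beta.mean(axis=(0, 1)).round(3))
print("mean bandwidth: ", round(draws.bandwidth.mean(), 1))
print("WAIC:", round(bgwr.assess_fit(draws, study.table, study.area_map).waic, 1))
```

prints

```
posterior means: [2.041 0.011 0.022 3.907 8.029]
mean bandwidth:  60.8
WAIC: 537.6
```

The five posterior means recover the generating coefficients
(2, 0, 0, 4, 8) to within sampling error, and the bandwidth posterior is
diffuse over its Uniform(0, 100) prior — with `D` ten times the maximum
pairwise distance, every weight stays above exp(-0.1) = 0.904 and the
model correctly behaves like a global regression on this design.

For a spatially varying surface, fix the kernel scale by cross-validation
and cluster the coefficient draws:

```python
study = bgwr.georgia_like(setting=3, seed=5)      # 3 true clusters: 51/49/59
bw, _ = bgwr.select_bandwidth_cv(study.table, study.area_map,
                                 "bisquare", [1, 1.5, 2, 2.5, 3, 4, 5])
draws = bgwr.run_bgwr(
    study.table, study.area_map,
    bgwr.KernelSpec("bisquare", bandwidth=bw), bgwr.PriorSpec(D=10.0),
    bgwr.McmcSettings(iterations=2000, burn_in=500, seed=5),
)
config = bgwr.two_stage_configuration(draws, n_samples=50,
                                      clusterer="gmm", config_method="mode",
                                      seed=7)
print("clusters:", config.n_clusters,
      " Rand index vs truth:",
      round(bgwr.rand_index(config.assignment, study.true_clusters), 3))
```

A command-line surface wraps the same stages:

```sh
bgwr simulate --design louisiana --seed 1 --output-dir sim/
bgwr fit sim/map.csv sim/data.csv --output-dir fit/ --iterations 3000 --burn-in 1000
bgwr select sim/map.csv sim/data.csv --output-dir sel/ --iterations 20000 --burn-in 2000
bgwr cluster fit/draws --clusterer dpmm --config-method mode --output-dir clus/
bgwr assess fit/draws sim/map.csv sim/data.csv
bgwr run --config pipeline.yaml          # simulate -> fit -> cluster -> assess
```

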