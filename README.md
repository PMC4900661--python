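# halfsib

Bayesian multi-trait analysis of balanced half-sib progeny trials, built
around the three traits that drive jatropha (*Jatropha curcas*) breeding:
weight of 100 seeds (W100S, g), seed oil content (SOC, %) and phorbol
ester concentration (PEC, mg/g — the toxicity trait to be reduced).
It is aimed at quantitative geneticists and breeding-program analysts who
want variance components, genetic diversity and selection indices from
one reproducible pipeline.

## The model

For trait *i*, family *j*, block *k*:

```
y_ijk = mu_i + b_ik + g_ij + e_ijk
```

with family (genotypic) effect vectors `g_j ~ iid N(0, G0)` and record
residual vectors `e_jk ~ iid N(0, R0)`, where `G0` and `R0` are
unstructured trait covariance matrices. A Gibbs sampler with a flat
prior on the fixed effects and scaled inverse-Wishart priors
`G0 ~ IW(Sigma_g, n0)`, `R0 ~ IW(Sigma_e, n0)` (`n0 = 5`) produces
thinned post-burn-in posterior draws of everything.

Downstream stages:

* **diagnostics** — Geweke Z, effective sample size, and posterior
  summaries (mean, median, KDE mode, SD, shortest 95% HPD interval);
* **genetic_params** — heritabilities `h2 = sigma_g^2/(sigma_g^2+sigma_e^2)`,
  genotypic/phenotypic correlations and phenotypic covariance `P = G0 + R0`,
  reported both per-draw and plug-in;
* **clustering** — squared Mahalanobis distances
  `d2 = (g1-g2)' S^-1 (g1-g2)` between posterior-mean genotypic values,
  Ward minimum-variance agglomeration in whitened coordinates, and the
  Mojena cut (first fusion level above `mean + 1.25 * sd`);
* **selection** — Hazel indices `b = P^-1 G w`, accuracy
  `R_IH = sigma_I/sigma_H`, monetary gain `delta_G = i R_IH sigma_H` and
  correlated responses `S = (i/sigma_I) G'b`, for a 3-scenario x
  3-economic-weight grid with weights in monetary units per genetic
  standard deviation (`w_i = m_i / sigma_g,i`);
* **synthetic** — a seeded generator for balanced trials whose default
  dispersion parameters are the posterior-mean `G0`/`R0` of a published
  179-family trial, so every stage is testable without field data.

## Worked example

```python
import numpy as np
from halfsib import (default_config, simulate_phenotypes, fit_gibbs, McmcConfig,
                     genotypic_value_means, run_scenarios, ward_cluster, mojena_cut)

cfg = default_config(seed=1)                       # 179 families x 2 blocks
table, true_g = simulate_phenotypes(cfg)
samples = fit_gibbs(table, cfg=McmcConfig(n_iter=20000, burn_in=5000, thin=10, seed=1))
G0, R0 = samples.G0.mean(axis=0), samples.R0.mean(axis=0)
print(np.round(np.diag(G0), 3), np.round(np.diag(R0), 3))

gv = genotypic_value_means(samples)
k = mojena_cut(ward_cluster(gv, R0)).k
print("clusters:", k)

report = run_scenarios(cfg.G0_true, cfg.R0_true).set_index("scenario")
print(report.loc["w1/scenario1", "R_IH"].round(4),
      report.loc["w1/scenario3", "R_IH"].round(4))
```

prints (seed 1):

```
[11.886  0.42   0.289] [8.401 2.547 0.371]
clusters: 4
0.2639 0.7048
```

The first line shows the genetic and residual variances recovered from
one simulated trial (truths 15.522/0.359/0.373 and 7.498/2.416/0.312;
with 179 families a single realization scatters around the truth —
coverage of the 95% HPD intervals across replicates is what the test
suite checks).
The last line gives the accuracy of a selection index measuring SOC
alone (0.26) versus all three traits (0.70): measuring the extra traits
nearly triples the correlation between the index and the aggregate
breeding objective. The cluster count from one simulated trial varies
with the seed; the generator draws family effects independently, so it
carries no real population substructure.

A CLI mirrors the library (`halfsib simulate | fit | diagnose | params |
cluster | index | all`); `halfsib index --matrices matrices.yaml` runs
the selection-index stage directly from externally supplied covariance
matrices, skipping MCMC.

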