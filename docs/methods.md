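# Methods

## Model and sampler

The observation model is a balanced multi-trait mixed model: for trait
*i*, family *j*, block *k*,

    y_ijk = mu_i + b_ik + g_ij + e_ijk,

with `g_j ~ iid N(0, G0)` across families (relationship matrix =
identity: families are treated as unrelated half-sib groups, no
pedigree or genomic kinship) and `e_jk ~ iid N(0, R0)` across records.
Residuals are homogeneous across observations but correlated across
traits — the full unstructured `R0` is estimated, which is what nonzero
residual trait covariances require. Block effects are fixed; the model
as written is over-parameterized, so a corner-point constraint absorbs
the first block into the trait means.

Priors: improper flat on all location effects (`V_b -> infinity`, so
the location full conditional has no shrinkage term), and scaled
inverse-Wishart `IW(Sigma, n0)` with `n0 = 5` on both `G0` and `R0`.
The scale matrices default to `0.5 * diag(sample phenotypic variance) *
(n0 - t - 1)`, centring each prior on half the phenotypic variance —
weakly informative and data-scaled. With 179 families and 358 records
the posterior degrees of freedom (184 and 363) dominate `n0 = 5`; the
recovery tests confirm insensitivity at this data size. Both scales are
configurable.

The Gibbs cycle is:

1. **Location effects, one joint multivariate-normal block.** The
   mixed-model-equations coefficient matrix has block-arrow structure:
   conditional on the fixed effects the families are independent, with
   identical 3x3 conditional precision `n_blocks * R0^-1 + G0^-1`. The
   joint draw of (beta, g) is therefore produced exactly as
   beta ~ p(beta | G0, R0, y) via the Schur complement of the family
   block, followed by g | beta vectorized over families. This is
   algebraically the same draw as factorizing the full system but costs
   O(q) instead of O(q^3) per iteration (about 0.3 ms/iteration for
   179 families x 3 traits).
2. `G0 ~ IW(Sigma_g + sum_j g_j g_j', n0 + n_families)`.
3. `R0 ~ IW(Sigma_e + sum residual outer products, n0 + n_records)`.

Defaults reproduce the reference protocol: 100 000 cycles, 40 000
burn-in, thinning 10, hence 6 000 retained draws. `thin` must divide
`n_iter - burn_in` exactly. All randomness flows from a single seed
through one `numpy` Generator; identical seeds give identical chains.
Incomplete tables are a hard error (no silent imputation or dropping):
the balanced-structure factorization assumes every family x block x
trait cell is present, and the reference data are complete.

## Diagnostics

* **Geweke Z** compares the first 10% and last 50% window means (the
  conventional windows), standardized by each window's spectral density
  at frequency zero estimated from an AR model with AIC-selected order
  (up to lag 20); a perfectly predictable window (residual variance
  numerically zero, e.g. a deterministic trend) contributes zero
  spectral variance.
* **ESS** divides the chain length by the integrated autocorrelation
  time with autocorrelations accumulated in Geyer pairs until the first
  non-positive pair sum (initial positive sequence), capped at n.
* **HPD** is the shortest contiguous window of the sorted draws
  containing the target mass — exact under unimodality, which holds for
  the variance-component posteriors here; ties go to the lowest window.
* **Posterior mode** maximizes a Gaussian KDE (scipy's plug-in
  bandwidth) on a 512-point grid over the sample range.

Constant chains raise for Z and ESS (zero variance) and are flagged
`degenerate` by the summary instead of raising, so a pathological
parameter never silently produces numbers.

## Derived genetic parameters

Heritability `h2_i = sigma_g,i^2 / (sigma_g,i^2 + sigma_e,i^2)`, pairwise
correlations `cov/sqrt(var*var)` (clamped to [-1, 1] against floating
error) and `P = G0 + R0`. Every quantity is reported in two labeled
variants: the posterior summary of per-draw values and the plug-in value
from posterior-mean matrices. The two are close for concentrated
posteriors but are not interchangeable, and published tables do not
always say which was used; reporting both avoids adjudicating.

## Diversity clustering

Squared Mahalanobis distances between posterior-mean genotypic-value
vectors use a metric covariance `S` that defaults to the residual
covariance `R0` — the classical choice for generalized distances
between genotype means — with `G0` or `G0 + R0` selectable, since which
matrix a given study inverted is often ambiguous. Ward clustering is
performed on whitened coordinates (`x -> L^-1 x`, `S = L L'`) rather
than via Lance–Williams updates on the distance matrix, so the
minimum-SSE objective holds exactly in the Mahalanobis metric; an
exhaustive SSE-minimizing agglomerator verifies the merge sequence in
the tests. Fusion levels are the *increase* in total within-cluster SSE
at each merge (scipy's Ward height h corresponds to `h^2/2`), not the
accumulated SSE — the Mojena cut depends on this convention. Mojena's
rule cuts before the first merge whose level exceeds
`mean + omega * sd` of all n-1 levels (sample sd, n-1 divisor;
`omega = 1.25`); no exceedance means a single cluster. Dendrograms
export to Newick with branch lengths equal to parent minus child fusion
level, so leaf depth equals the root fusion level.

## Selection indices

Economic weights are expressed in monetary units per genetic standard
deviation, `w_i = m_i / sigma_g,i`; this reading reproduces the
reference single-trait-index accuracies to four decimals under all
three weight sets, which the alternative (`w_i = m_i`) does not. The
breeding goal always contains all three traits; only the measured
(index) trait set varies across scenarios — the reference tables report
responses for all three traits even under the single-trait index, which
confirms that convention. The response formula is
`S = (i / sigma_I) * G'b` (the standard correlated-response form; the
product form `i * sigma_I * b'G` does not reproduce the reference
responses). Default intensity `i = 1.75` corresponds to truncation
selection of the top 10%; family ranking scores posterior-mean genotypic
values (with raw phenotypic deviations available by supplying any other
family x trait matrix) and selects `ceil(0.10 * n)` families with ties
broken by family ID.

The scenario grid evaluated by `run_scenarios` is: index traits {SOC},
{SOC, W100S}, {SOC, W100S, PEC}; monetary units (per genetic SD)
all 1, SOC doubled, and (SOC 4, W100S 2, PEC 1).

## Synthetic data

The generator emulates the balanced 179-family x 2-block trial with one
record per family x block x trait (the plot-mean reduction used by the
reference analysis; no plot-level nesting, spatial structure, multi-year
repeated measures, or missingness). Default `G0`/`R0` are the reference
posterior means; trait means (60 g, 35%, 2 mg/g) and ~1% block
contrasts are plausible, configurable, and irrelevant to
variance-component recovery. Covariances may be positive semidefinite
(an eigen-factor replaces Cholesky when singular), enabling exact
degenerate checks. Family effects are drawn independently, so simulated
trials carry no population substructure; a cluster count obtained on
synthetic data exercises the machinery but says nothing about real
germplasm structure, and passing recovery tests demonstrate correctness
of the estimator under the model's own assumptions, not robustness to
field realities (spatial trends, outliers, missing plots).

## Problem sizes and numerical choices

The test suite runs reduced configurations chosen to keep Monte-Carlo
error well inside the asserted tolerances: the recovery experiment uses
10 replicates of the full 179-family design at 20 000 cycles / 5 000
burn-in / thin 10 (1 500 retained draws), shared fixtures use 60
families at 3 000 cycles, and the conjugate-oracle checks use
single-trait models where the marginal posterior of the residual
variance is a closed-form inverse-gamma. Positive definiteness is
asserted for every retained covariance draw. Matrix validation treats
eigenvalues below -1e-10 (relative) as indefinite; the Mahalanobis
metric additionally rejects condition numbers above 1e12 with an
explicit message.

## Known limitations

* No pedigree/genomic relationship matrices, no heterogeneous residual
  variances, no multi-year repeatability models, no REML/ANOVA
  estimators.
* Missing phenotypes are rejected, not imputed.
* Reported reference quantities that depend on the original raw records
  (the posterior point estimates themselves, observed ESS values, the
  exact cluster count of the real germplasm) are outside what synthetic
  data can reproduce; the package targets the deterministic
  transformations of published covariance estimates and the statistical
  calibration of the sampler.
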