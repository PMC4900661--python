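"""Gibbs sampler for the multi-trait half-sib mixed model.

Model, per family j, block k and trait i (balanced, complete data):

    y[ijk] = mu_i + b_ik + g_ij + e_ijk

with fixed effects beta = (mu_i, block deviations), family effects
g_j ~ iid N(0, G0) across families (relationship matrix = identity) and
record residual vectors e_jk ~ iid N(0, R0) — homogeneous across
observations, correlated across traits.  Priors: improper flat on beta
(V_b -> infinity) and scaled inverse-Wishart on each covariance matrix,

    G0 ~ IW(Sigma_g, n0),   R0 ~ IW(Sigma_e, n0),   n0 = 5 by default.

The chain cycles three full-conditional blocks:

1. (beta, g) jointly from their multivariate-normal full conditional.
   The mixed-model-equations coefficient matrix has a block-arrow
   structure (families are conditionally independent given beta), so the
   joint draw is produced exactly as beta ~ p(beta | G0, R0, y) via the
   Schur complement, then g | beta vectorized over families.
2. G0 ~ IW(Sigma_g + sum_j g_j g_j', n0 + n_families).
3. R0 ~ IW(Sigma_e + sum residual outer products, n0 + n_records).

Over-parameterization of Eq-style block effects is removed by a
corner-point constraint: the first block is absorbed into the trait
means, so beta has n_blocks coefficients per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from halfsib.traits import CANONICAL_TRAITS, TraitSet, as_cov_matrix


@dataclass
class ModelSpec:
    """Priors and model structure for :func:`fit_gibbs`.

    ``prior_scale_g``/``prior_scale_e`` default to the weakly informative,
    data-scaled choice ``0.5 * diag(phenotypic variance) * (n0 - t - 1)``,
    which centres each inverse-Wishart prior on half the observed
    phenotypic variance.  ``beta_prior`` is always flat (improper
    uniform); ``include_genetic=False`` drops the family term, leaving a
    fixed-effects model used by the conjugate-oracle tests.
    """

    prior_df: int = 5
    prior_scale_g: np.ndarray | None = None
    prior_scale_e: np.ndarray | None = None
    include_genetic: bool = True
    init_G0: np.ndarray | None = None
    init_R0: np.ndarray | None = None


@dataclass
class McmcConfig:
    """Chain-length settings; defaults retain (100000-40000)/10 = 6000 draws."""

    n_iter: int = 100_000
    burn_in: int = 40_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.burn_in) % self.thin:
            raise ValueError("thin must divide (n_iter - burn_in)")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws of all model unknowns.

    Arrays are indexed (draw, ...); ``beta`` is (draws, n_blocks, traits)
    under the corner-point parameterization (row 0 = trait means for
    block 1, row k>0 = deviation of block k+1).
    """

    traits: tuple[str, ...]
    families: tuple[str, ...]
    blocks: tuple[str, ...]
    beta: np.ndarray
    g: np.ndarray
    G0: np.ndarray
    R0: np.ndarray
    draw_index: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.G0.shape[0]

    def cov_chains(self) -> dict[str, np.ndarray]:
        """Scalar chains for every distinct entry of G0 and R0, labeled
        ``sigma2_g_<trait>``, ``sigma_g_<t1>_<t2>`` (genetic) and the
        ``_e_`` analogues (residual)."""
        out: dict[str, np.ndarray] = {}
        t = len(self.traits)
        for label, arr in (("g", self.G0), ("e", self.R0)):
            for a in range(t):
                out[f"sigma2_{label}_{self.traits[a]}"] = arr[:, a, a]
                for b in range(a + 1, t):
                    out[f"sigma_{label}_{self.traits[a]}_{self.traits[b]}"] = arr[:, a, b]
        return out


def _canonical_trait_order(labels, traits: TraitSet) -> list[str]:
    known = [n for n in traits.names if n in labels]
    extra = sorted(set(labels) - set(traits.names))
    return known + extra


def _pivot_complete(data: pd.DataFrame, traits: TraitSet):
    """Arrange the long table as a dense (families, blocks, traits) array,
    rejecting incomplete or duplicated designs."""
    trait_order = _canonical_trait_order(data["trait"].unique(), traits)
    fams = sorted(data["family_id"].astype(str).unique())
    blocks = sorted(data["block_id"].astype(str).unique())
    if len(fams) < 2:
        raise ValueError("at least 2 families are required")
    piv = data.set_index(["family_id", "block_id", "trait"])["value"]
    if piv.index.duplicated().any():
        raise ValueError("duplicated (family, block, trait) records")
    full = pd.MultiIndex.from_product([fams, blocks, trait_order])
    values = piv.reindex(full)
    if values.isna().any():
        n_missing = int(values.isna().sum())
        raise ValueError(
            f"incomplete data: {n_missing} missing (family, block, trait) cells; "
            "the sampler requires a complete balanced table"
        )
    y = values.to_numpy().reshape(len(fams), len(blocks), len(trait_order))
    return y, fams, blocks, trait_order


def default_prior_scale(phen_var: np.ndarray, prior_df: int) -> np.ndarray:
    """Data-scaled prior scale matrix: half the phenotypic variance on the
    diagonal, converted to inverse-Wishart scale units."""
    t = len(phen_var)
    factor = max(prior_df - t - 1, 1)
    return 0.5 * np.diag(phen_var) * factor


def fit_gibbs(data: pd.DataFrame, spec: ModelSpec | None = None, cfg: McmcConfig | None = None,
              traits: TraitSet = CANONICAL_TRAITS) -> PosteriorSamples:
    """Run the Gibbs sampler on a complete long-format phenotype table.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``family_id, block_id, trait, value``; every
        family x block x trait cell present exactly once.
    spec : ModelSpec
        Priors; defaults to ``ModelSpec()``.
    cfg : McmcConfig
        Chain settings; defaults reproduce the study protocol
        (100k cycles, 40k burn-in, thin 10).

    Returns
    -------
    PosteriorSamples
        ``cfg.n_retained`` thinned post-burn-in draws.  Identical seeds
        give identical chains.
    """
    spec = spec or ModelSpec()
    cfg = cfg or McmcConfig()
    y, fams, blocks, trait_order = _pivot_complete(data, traits)
    q, nb, t = y.shape
    n_records = q * nb

    if spec.prior_df < t:
        raise ValueError(f"prior_df must be >= number of traits ({t})")
    phen_var = y.reshape(-1, t).var(axis=0, ddof=1)
    Sg = (
        as_cov_matrix(spec.prior_scale_g, "prior_scale_g", dim=t)
        if spec.prior_scale_g is not None
        else default_prior_scale(phen_var, spec.prior_df)
    )
    Se = (
        as_cov_matrix(spec.prior_scale_e, "prior_scale_e", dim=t)
        if spec.prior_scale_e is not None
        else default_prior_scale(phen_var, spec.prior_df)
    )

    rng = np.random.default_rng(cfg.seed)

    # Fixed-effect design per block (corner point): x_k = (1, e_{k-1}).
    p = nb
    X = np.zeros((nb, p))
    X[:, 0] = 1.0
    for k in range(1, nb):
        X[k, k] = 1.0
    A_ff = q * (X.T @ X)                      # (p, p)
    a_f = X.sum(axis=0)                       # column of the beta-by-family cross block
    B = q * np.outer(a_f, a_f)                # A_fg @ A_fg'
    Ysum = y.sum(axis=1)                      # (q, t) per-family sums over blocks
    M_f = np.einsum("kp,jkt->pt", X, y)       # (p, t) X' y totals
    Ytot = Ysum.sum(axis=0)                   # (t,)

    # Initial values: block means for beta, half phenotypic variance for both
    # covariance matrices (overridable for overdispersed-start experiments).
    G0 = np.asarray(spec.init_G0, float) if spec.init_G0 is not None else 0.5 * np.diag(phen_var)
    R0 = np.asarray(spec.init_R0, float) if spec.init_R0 is not None else 0.5 * np.diag(phen_var)
    g = np.zeros((q, t))

    n0 = spec.prior_df
    n_ret = cfg.n_retained
    out_beta = np.empty((n_ret, p, t))
    out_g = np.empty((n_ret, q, t))
    out_G0 = np.empty((n_ret, t, t))
    out_R0 = np.empty((n_ret, t, t))
    draw_idx = np.empty(n_ret, dtype=int)
    r = 0

    for it in range(1, cfg.n_iter + 1):
        Rinv = np.linalg.inv(R0)
        if spec.include_genetic:
            Ginv = np.linalg.inv(G0)
            V = np.linalg.inv(nb * Rinv + Ginv)     # family-effect conditional covariance
            W = Rinv @ V @ Rinv
            # beta marginal (g integrated out): precision and shifted rhs.
            P_beta = np.kron(A_ff, Rinv) - np.kron(B, W)
            r_beta = (M_f @ Rinv - np.outer(a_f, W @ Ytot)).ravel()
        else:
            P_beta = np.kron(A_ff, Rinv)
            r_beta = (M_f @ Rinv).ravel()
        L = np.linalg.cholesky(P_beta)
        mean = np.linalg.solve(P_beta, r_beta)
        z = rng.standard_normal(p * t)
        beta = (mean + np.linalg.solve(L.T, z)).reshape(p, t)

        fitted = X @ beta                           # (nb, t) fixed part per block
        if spec.include_genetic:
            resid_sum = Ysum - fitted.sum(axis=0)[None, :]
            g_mean = resid_sum @ (V @ Rinv).T
            Lv = np.linalg.cholesky(V)
            g = g_mean + rng.standard_normal((q, t)) @ Lv.T
            SG = g.T @ g
            G0 = invwishart.rvs(df=n0 + q, scale=Sg + SG, random_state=rng)
            G0 = np.atleast_2d(G0)

        E = (y - fitted[None, :, :] - g[:, None, :]).reshape(-1, t)
        R0 = invwishart.rvs(df=n0 + n_records, scale=Se + E.T @ E, random_state=rng)
        R0 = np.atleast_2d(R0)

        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            out_beta[r] = beta
            out_g[r] = g
            out_G0[r] = G0
            out_R0[r] = R0
            draw_idx[r] = it
            r += 1

    return PosteriorSamples(
        traits=tuple(trait_order),
        families=tuple(fams),
        blocks=tuple(blocks),
        beta=out_beta,
        g=out_g,
        G0=out_G0,
        R0=out_R0,
        draw_index=draw_idx,
    )


def genotypic_value_means(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior-mean genotypic values, families x traits (canonical order)."""
    if samples.n_draws == 0:
        raise ValueError("no retained draws")
    m = samples.g.mean(axis=0)
    return pd.DataFrame(m, index=pd.Index(samples.families, name="family_id"),
                        columns=list(samples.traits))


def posterior_mean_cov(samples: PosteriorSamples) -> tuple[np.ndarray, np.ndarray]:
    """Posterior means of G0 and R0."""
    return samples.G0.mean(axis=0), samples.R0.mean(axis=0)


def save_chain(samples: PosteriorSamples, path, g_path=None) -> None:
    """Persist covariance chains as labeled CSV (one row per retained draw);
    optionally archive the full g draws as a compressed ``.npz``."""
    chains = samples.cov_chains()
    df = pd.DataFrame({"draw": samples.draw_index, **chains})
    df.to_csv(path, index=False)
    if g_path is not None:
        np.savez_compressed(
            g_path,
            g=samples.g,
            beta=samples.beta,
            families=np.array(samples.families),
            blocks=np.array(samples.blocks),
            traits=np.array(samples.traits),
            draw=samples.draw_index,
        )


def load_chain(path) -> pd.DataFrame:
    """Load a saved covariance chain table (diagnostics input)."""
    return pd.read_csv(path)


def samples_from_chain_table(table: pd.DataFrame, traits: TraitSet = CANONICAL_TRAITS) -> PosteriorSamples:
    """Rebuild a covariance-only :class:`PosteriorSamples` from a saved
    chain table (beta and g are not stored in the CSV and come back empty)."""
    names = [n for n in traits.names if f"sigma2_g_{n}" in table.columns]
    t = len(names)
    if t == 0:
        raise ValueError("chain table has no recognizable sigma2_g_<trait> columns")
    n = len(table)
    G0 = np.zeros((n, t, t))
    R0 = np.zeros((n, t, t))
    for label, arr in (("g", G0), ("e", R0)):
        for a, na in enumerate(names):
            arr[:, a, a] = table[f"sigma2_{label}_{na}"]
            for b in range(a + 1, t):
                col = f"sigma_{label}_{na}_{names[b]}"
                arr[:, a, b] = arr[:, b, a] = table[col]
    draw = table["draw"].to_numpy() if "draw" in table.columns else np.arange(n)
    return PosteriorSamples(
        traits=tuple(names), families=(), blocks=(),
        beta=np.empty((n, 0, t)), g=np.empty((n, 0, t)),
        G0=G0, R0=R0, draw_index=np.asarray(draw),
    )
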