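"""Derived genetic parameters from posterior draws of G0 and R0.

Per-trait heritability h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2), trait-pair
genotypic and phenotypic correlations, and phenotypic (co)variances
P = G0 + R0.  Each quantity is reported two ways, explicitly labeled:

* ``per_draw`` — the ratio computed inside every retained draw, then
  summarized (posterior mean, HPD, ...);
* ``plug_in`` — the ratio of posterior-mean matrices.

The two differ in finite samples (a ratio of means is not the mean of
ratios); the package reports both rather than adjudicating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from halfsib.diagnostics import PosteriorSummary, summarize, summary_table
from halfsib.mcmc import PosteriorSamples
from halfsib.traits import as_cov_matrix


def heritability(sigma_g2: float, sigma_e2: float) -> float:
    """Narrow-sense family heritability, sigma_g2 / (sigma_g2 + sigma_e2)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma_g2 + sigma_e2
    if tot <= 0:
        raise ValueError("sigma_g2 + sigma_e2 must be positive")
    return sigma_g2 / tot


def correlation_from_cov(cov: float, var1: float, var2: float) -> float:
    """cov / sqrt(var1 * var2), clamped to [-1, 1] against rounding noise."""
    if var1 <= 0 or var2 <= 0:
        raise ValueError("variances must be positive")
    r = cov / np.sqrt(var1 * var2)
    return float(np.clip(r, -1.0, 1.0))


def phenotypic_cov(G0, R0) -> np.ndarray:
    """Phenotypic covariance matrix P = G0 + R0 (entrywise sum)."""
    G0 = as_cov_matrix(G0, "G0", semidefinite=True)
    R0 = as_cov_matrix(R0, "R0", dim=G0.shape[0], semidefinite=True)
    return G0 + R0


def _corr_matrix(C: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(C))
    r = C / np.outer(d, d)
    return np.clip(r, -1.0, 1.0)


@dataclass
class GeneticParamsReport:
    """Heritabilities, correlations and phenotypic variances.

    ``*_summary`` entries are posterior summaries of per-draw values;
    ``*_plug_in`` are computed once from posterior-mean G0 and R0.
    """

    traits: tuple[str, ...]
    h2_summary: dict[str, PosteriorSummary]
    h2_plug_in: dict[str, float]
    sigma_p2_summary: dict[str, PosteriorSummary]
    sigma_p2_plug_in: dict[str, float]
    r_g_summary: dict[tuple[str, str], PosteriorSummary]
    r_g_plug_in: dict[tuple[str, str], float]
    r_p_summary: dict[tuple[str, str], PosteriorSummary]
    r_p_plug_in: dict[tuple[str, str], float]
    G0_mean: np.ndarray
    R0_mean: np.ndarray


def derive_report(samples: PosteriorSamples) -> GeneticParamsReport:
    """Compute the full derived-parameter report from posterior samples."""
    if samples.n_draws == 0:
        raise ValueError("no retained draws")
    names = samples.traits
    t = len(names)
    G, R = samples.G0, samples.R0
    P = G + R

    dg = np.einsum("dii->di", G)
    de = np.einsum("dii->di", R)
    dp = dg + de
    h2_draws = dg / dp

    G0_mean = G.mean(axis=0)
    R0_mean = R.mean(axis=0)
    P_mean = G0_mean + R0_mean

    def _pair_corr(M):
        d = np.sqrt(np.einsum("dii->di", M))
        out = {}
        for a in range(t):
            for b in range(a + 1, t):
                out[(names[a], names[b])] = np.clip(M[:, a, b] / (d[:, a] * d[:, b]), -1, 1)
        return out

    rg_draws = _pair_corr(G)
    rp_draws = _pair_corr(P)

    rg_plug = _corr_matrix(G0_mean)
    rp_plug = _corr_matrix(P_mean)

    def _summ(arr):
        # chains too short for Z/ESS/KDE still get the order statistics
        if arr.size < 20:
            return PosteriorSummary(
                PM=float(np.mean(arr)),
                PMD=float(np.median(arr)),
                PMO=float(np.median(arr)),
                PSD=float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
                HPD_low=float(np.min(arr)),
                HPD_high=float(np.max(arr)),
                Z=np.nan,
                ESS=np.nan,
                degenerate=arr.size == 1 or np.ptp(arr) == 0.0,
            )
        return summarize(arr)

    return GeneticParamsReport(
        traits=names,
        h2_summary={names[i]: _summ(h2_draws[:, i]) for i in range(t)},
        h2_plug_in={
            names[i]: heritability(G0_mean[i, i], R0_mean[i, i]) for i in range(t)
        },
        sigma_p2_summary={names[i]: _summ(dp[:, i]) for i in range(t)},
        sigma_p2_plug_in={names[i]: float(P_mean[i, i]) for i in range(t)},
        r_g_summary={k: _summ(v) for k, v in rg_draws.items()},
        r_g_plug_in={
            (names[a], names[b]): float(rg_plug[a, b])
            for a in range(t) for b in range(a + 1, t)
        },
        r_p_summary={k: _summ(v) for k, v in rp_draws.items()},
        r_p_plug_in={
            (names[a], names[b]): float(rp_plug[a, b])
            for a in range(t) for b in range(a + 1, t)
        },
        G0_mean=G0_mean,
        R0_mean=R0_mean,
    )


def variance_component_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior summaries for every distinct (co)variance entry plus the
    per-draw heritabilities — the classic variance-component report."""
    chains = dict(samples.cov_chains())
    dg = np.einsum("dii->di", samples.G0)
    de = np.einsum("dii->di", samples.R0)
    for i, name in enumerate(samples.traits):
        chains[f"h2_{name}"] = dg[:, i] / (dg[:, i] + de[:, i])
    return summary_table(chains)


def correlation_table(report: GeneticParamsReport, variant: str = "per_draw") -> pd.DataFrame:
    """Square trait table: heritability on the diagonal, genotypic
    correlation above it, phenotypic correlation below, plus a phenotypic
    variance row.  ``variant`` selects posterior-mean-of-ratio
    (``per_draw``) or ratio-of-posterior-means (``plug_in``) entries."""
    if variant not in ("per_draw", "plug_in"):
        raise ValueError("variant must be 'per_draw' or 'plug_in'")
    names = report.traits
    t = len(names)
    M = np.zeros((t, t))
    for i, n in enumerate(names):
        M[i, i] = (
            report.h2_summary[n].PM if variant == "per_draw" else report.h2_plug_in[n]
        )
    for a in range(t):
        for b in range(a + 1, t):
            key = (names[a], names[b])
            if variant == "per_draw":
                M[a, b] = report.r_g_summary[key].PM
                M[b, a] = report.r_p_summary[key].PM
            else:
                M[a, b] = report.r_g_plug_in[key]
                M[b, a] = report.r_p_plug_in[key]
    out = pd.DataFrame(M, index=list(names), columns=list(names))
    sp2 = [
        report.sigma_p2_summary[n].PM if variant == "per_draw" else report.sigma_p2_plug_in[n]
        for n in names
    ]
    out.loc["sigma_p2"] = sp2
    return out
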