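"""Hazel selection indices.

The breeding objective is the aggregate genotype H = w'g over the goal
traits; selection acts on the linear index I = b'x of the measured
(index) traits.  With P the phenotypic covariance of the index traits,
G the genetic covariance between index and goal traits and C the
genetic covariance of the goal traits, the optimal coefficients are

    b = P^-1 G w,
    sigma_I^2 = b'Pb,   sigma_H^2 = w'Cw,   R_IH = sigma_I / sigma_H,
    delta_G = i * R_IH * sigma_H,           S = (i / sigma_I) * G'b,

where i is the selection intensity (1.75 for the top 10%) and S the
expected per-generation response of every goal trait.  Economic weights
are specified in monetary units per genetic standard deviation:
w_i = m_i / sigma_g,i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from halfsib.traits import CANONICAL_TRAITS, TraitSet, as_cov_matrix

DEFAULT_INTENSITY = 1.75  # standardized selection differential for the top 10%


@dataclass(frozen=True)
class IndexScenario:
    """One selection-index configuration.

    ``index_traits`` are the traits measured and combined in I;
    ``goal_traits`` the traits in the breeding objective H (all three by
    default); ``monetary_units`` the per-goal-trait economic values m_i
    in monetary units per genetic standard deviation.
    """

    name: str
    index_traits: tuple[str, ...]
    goal_traits: tuple[str, ...] = CANONICAL_TRAITS.names
    monetary_units: tuple[float, ...] = (1.0, 1.0, 1.0)
    intensity: float = DEFAULT_INTENSITY

    def __post_init__(self) -> None:
        if not self.index_traits or not self.goal_traits:
            raise ValueError("index and goal trait sets must be non-empty")
        if len(self.monetary_units) != len(self.goal_traits):
            raise ValueError("one monetary unit per goal trait required")
        if self.intensity <= 0:
            raise ValueError("selection intensity must be positive")


@dataclass
class IndexResult:
    """Solved index for one scenario: coefficients, accuracies and responses."""

    scenario: str
    index_traits: tuple[str, ...]
    goal_traits: tuple[str, ...]
    b: np.ndarray
    sigma_I: float
    sigma_H: float
    R_IH: float
    delta_G: float
    S: dict[str, float]


def economic_weights(monetary_units, G0, goal_traits: tuple[str, ...] = CANONICAL_TRAITS.names,
                     traits: TraitSet = CANONICAL_TRAITS) -> np.ndarray:
    """w_i = m_i / sqrt(genetic variance of goal trait i)."""
    G0 = as_cov_matrix(G0, "G0", dim=traits.n, semidefinite=True)
    m = np.asarray(monetary_units, dtype=float)
    idx = [traits.index(n) for n in goal_traits]
    var = np.diag(G0)[idx]
    if np.any(var <= 0):
        bad = [goal_traits[i] for i in range(len(idx)) if var[i] <= 0]
        raise ValueError(f"zero genetic variance for goal trait(s) {bad}")
    return m / np.sqrt(var)


def build_matrices(scn: IndexScenario, G0, R0, traits: TraitSet = CANONICAL_TRAITS):
    """Restrict the full trait covariances to the scenario's P, G, C.

    P: phenotypic covariance of the index traits; G: genetic covariance
    of index traits (rows) with goal traits (columns); C: genetic
    covariance of the goal traits.
    """
    G0 = as_cov_matrix(G0, "G0", dim=traits.n)
    R0 = as_cov_matrix(R0, "R0", dim=traits.n)
    ii = [traits.index(n) for n in scn.index_traits]
    gi = [traits.index(n) for n in scn.goal_traits]
    P_full = G0 + R0
    P = P_full[np.ix_(ii, ii)]
    G = G0[np.ix_(ii, gi)]
    C = G0[np.ix_(gi, gi)]
    return P, G, C


def solve_index(scn: IndexScenario, G0, R0, traits: TraitSet = CANONICAL_TRAITS) -> IndexResult:
    """Solve the Hazel index for one scenario."""
    P, G, C = build_matrices(scn, G0, R0, traits)
    w = economic_weights(scn.monetary_units, G0, scn.goal_traits, traits)
    try:
        b = np.linalg.solve(P, G @ w)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"index phenotypic matrix P is singular: {exc}") from exc
    var_I = float(b @ P @ b)
    var_H = float(w @ C @ w)
    sigma_I = math.sqrt(max(var_I, 0.0))
    sigma_H = math.sqrt(max(var_H, 0.0))
    if sigma_H == 0.0:
        raise ValueError("aggregate genotype has zero variance")
    R_IH = sigma_I / sigma_H
    delta_G = scn.intensity * R_IH * sigma_H
    if sigma_I == 0.0:
        S_vec = np.zeros(len(scn.goal_traits))
    else:
        S_vec = scn.intensity / sigma_I * (G.T @ b)
    return IndexResult(
        scenario=scn.name,
        index_traits=scn.index_traits,
        goal_traits=scn.goal_traits,
        b=b,
        sigma_I=sigma_I,
        sigma_H=sigma_H,
        R_IH=R_IH,
        delta_G=delta_G,
        S={n: float(s) for n, s in zip(scn.goal_traits, S_vec)},
    )


#: The three study scenarios: an established oil-content program
#: progressively adding seed weight and toxicity to the index.
PAPER_SCENARIO_TRAITS = {
    "1": ("SOC",),
    "2": ("SOC", "W100S"),
    "3": ("SOC", "W100S", "PEC"),
}

#: Economic-weight sets, keyed by trait (monetary units per genetic SD).
PAPER_WEIGHT_SETS = {
    "w1": {"W100S": 1.0, "SOC": 1.0, "PEC": 1.0},
    "w2": {"W100S": 1.0, "SOC": 2.0, "PEC": 1.0},
    "w3": {"W100S": 2.0, "SOC": 4.0, "PEC": 1.0},
}


def paper_scenarios(intensity: float = DEFAULT_INTENSITY) -> list[IndexScenario]:
    """The 3 scenarios x 3 weight sets of the study, canonical goal order."""
    out = []
    for wname, wmap in PAPER_WEIGHT_SETS.items():
        for sname, idx_traits in PAPER_SCENARIO_TRAITS.items():
            m = tuple(wmap[n] for n in CANONICAL_TRAITS.names)
            out.append(
                IndexScenario(
                    name=f"{wname}/scenario{sname}",
                    index_traits=idx_traits,
                    monetary_units=m,
                    intensity=intensity,
                )
            )
    return out


def run_scenarios(G0, R0, scenarios: list[IndexScenario] | None = None,
                  traits: TraitSet = CANONICAL_TRAITS) -> pd.DataFrame:
    """Evaluate a list of scenarios (the study grid by default) and return
    a report table: accuracy, monetary gain and per-trait responses."""
    scenarios = scenarios if scenarios is not None else paper_scenarios()
    rows = []
    for scn in scenarios:
        res = solve_index(scn, G0, R0, traits)
        row = {
            "scenario": res.scenario,
            "index_traits": "+".join(res.index_traits),
            "R_IH": res.R_IH,
            "delta_G": res.delta_G,
        }
        for n in res.goal_traits:
            row[f"S_{n}"] = res.S[n]
        rows.append(row)
    return pd.DataFrame(rows)


def rank_families(gv: pd.DataFrame, result: IndexResult, scn: IndexScenario,
                  top_fraction: float = 0.10) -> pd.DataFrame:
    """Score families by I = b'(genotypic values on the index traits) and
    flag the top ceil(top_fraction * n); ties broken by family ID."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    missing = set(scn.index_traits) - set(gv.columns)
    if missing:
        raise ValueError(f"genotypic values missing index traits {sorted(missing)}")
    scores = gv.loc[:, list(scn.index_traits)].to_numpy(dtype=float) @ result.b
    out = pd.DataFrame({"family_id": gv.index.astype(str), "score": scores})
    out = out.sort_values(["score", "family_id"], ascending=[False, True], kind="mergesort")
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    n_sel = math.ceil(top_fraction * len(out))
    out["selected"] = out["rank"] <= n_sel
    return out
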