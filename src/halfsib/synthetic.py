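"""Synthetic half-sib trial generator.

Emulates the structure of a balanced progeny trial: ``n_families``
half-sib families evaluated in ``n_blocks`` complete blocks for the
three canonical traits,

    y[trait, family, block] = mu[trait] + b[block, trait] + g[family, trait] + e,

with family effects g ~ N(0, G0) and residuals e ~ N(0, R0) drawn
independently per record across the trait dimension.  Default G0 and
R0 are the posterior-mean trait covariance matrices estimated from the
179-family jatropha trial, so simulated data reproduce the dispersion
structure of that study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from halfsib.traits import CANONICAL_TRAITS, TraitSet, as_cov_matrix, psd_factor

# Posterior-mean genetic (G0) and residual (R0) covariance matrices of the
# jatropha half-sib trial, canonical trait order (W100S, SOC, PEC).
DEFAULT_G0 = np.array(
    [
        [15.522, 0.891, -0.319],
        [0.891, 0.359, -0.004],
        [-0.319, -0.004, 0.373],
    ]
)
DEFAULT_R0 = np.array(
    [
        [7.498, 0.008, -0.080],
        [0.008, 2.416, 0.016],
        [-0.080, 0.016, 0.312],
    ]
)

#: Plausible trait-scale means (g, %, mg/g); configurable, irrelevant to
#: variance-component recovery.
DEFAULT_MU = np.array([60.0, 35.0, 2.0])

PHENOTYPE_COLUMNS = ("family_id", "block_id", "trait", "value")


def _default_block_effects(n_blocks: int, n_traits: int = 3) -> np.ndarray:
    """Small fixed block contrasts, summing to zero per trait."""
    base = np.array([60.0, 35.0, 2.0])[:n_traits] * 0.01  # ~1% of the trait mean
    dev = np.linspace(1.0, -1.0, n_blocks)[:, None] * base[None, :]
    return dev - dev.mean(axis=0, keepdims=True)


@dataclass
class SimulationConfig:
    """Parameters of a simulated balanced half-sib trial."""

    n_families: int = 179
    n_blocks: int = 2
    mu: np.ndarray = field(default_factory=lambda: DEFAULT_MU.copy())
    block_effects: np.ndarray | None = None
    G0_true: np.ndarray = field(default_factory=lambda: DEFAULT_G0.copy())
    R0_true: np.ndarray = field(default_factory=lambda: DEFAULT_R0.copy())
    seed: int = 0
    traits: TraitSet = CANONICAL_TRAITS

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_blocks < 1:
            raise ValueError("n_families and n_blocks must be positive")
        t = self.traits.n
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (t,):
            raise ValueError(f"mu must have shape ({t},)")
        if self.block_effects is None:
            self.block_effects = _default_block_effects(self.n_blocks, t)
        self.block_effects = np.asarray(self.block_effects, dtype=float)
        if self.block_effects.shape != (self.n_blocks, t):
            raise ValueError(f"block_effects must have shape ({self.n_blocks}, {t})")
        if not np.allclose(self.block_effects.sum(axis=0), 0.0, atol=1e-8):
            raise ValueError("block_effects must sum to zero per trait")
        self.G0_true = as_cov_matrix(self.G0_true, "G0_true", dim=t, semidefinite=True)
        self.R0_true = as_cov_matrix(self.R0_true, "R0_true", dim=t, semidefinite=True)


def default_config(**overrides) -> SimulationConfig:
    """Study-condition configuration: 179 families, 2 blocks, posterior-mean
    G0/R0 of the jatropha trial as true dispersion parameters."""
    return SimulationConfig(**overrides)


def family_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"F{i:0{width}d}" for i in range(1, n + 1)]


def block_ids(n: int) -> list[str]:
    return [f"B{i}" for i in range(1, n + 1)]


def simulate_phenotypes(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a complete phenotype table.

    Returns
    -------
    phenotypes : pandas.DataFrame
        Long format with columns ``family_id, block_id, trait, value``;
        one record per family x block x trait.
    true_g : pandas.DataFrame
        The simulated family (genotypic) effects, families x traits, for
        recovery experiments.
    """
    rng = np.random.default_rng(config.seed)
    q, nb, t = config.n_families, config.n_blocks, config.traits.n
    Lg = psd_factor(config.G0_true)
    Le = psd_factor(config.R0_true)
    g = rng.standard_normal((q, t)) @ Lg.T
    e = rng.standard_normal((q, nb, t)) @ Le.T
    # y[j, k, i] = mu_i + b_ki + g_ji + e_jki
    y = config.mu[None, None, :] + config.block_effects[None, :, :] + g[:, None, :] + e

    fams = family_ids(q)
    blocks = block_ids(nb)
    rows = pd.DataFrame(
        {
            "family_id": np.repeat(fams, nb * t),
            "block_id": np.tile(np.repeat(blocks, t), q),
            "trait": np.tile(list(config.traits.names), q * nb),
            "value": y.reshape(-1),
        }
    )
    true_g = pd.DataFrame(g, index=pd.Index(fams, name="family_id"), columns=list(config.traits.names))
    return rows, true_g


def validate_phenotypes(table: pd.DataFrame, traits: TraitSet = CANONICAL_TRAITS) -> pd.DataFrame:
    """Check the long-format contract: required columns, known traits, no
    duplicated (family, block, trait) triples."""
    missing = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    unknown = set(table["trait"]) - set(traits.names)
    if unknown:
        raise ValueError(f"unknown trait labels: {sorted(unknown)}")
    dup = table.duplicated(subset=["family_id", "block_id", "trait"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicated (family, block, trait) records")
    if table["value"].isna().any():
        raise ValueError("phenotype table contains missing values")
    return table


def write_phenotypes(table: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write the long-format table as headered CSV (optional seed header)."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        table.to_csv(fh, index=False)


def read_phenotypes(path, traits: TraitSet = CANONICAL_TRAITS) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#", dtype={"family_id": str, "block_id": str, "trait": str})
    return validate_phenotypes(table, traits)


def write_truth(config: SimulationConfig, path) -> None:
    """Persist the true simulation parameters as a YAML sidecar."""
    payload = {
        "seed": int(config.seed),
        "n_families": int(config.n_families),
        "n_blocks": int(config.n_blocks),
        "traits": list(config.traits.names),
        "units": list(config.traits.units),
        "mu": config.mu.tolist(),
        "block_effects": config.block_effects.tolist(),
        "G0_true": config.G0_true.tolist(),
        "R0_true": config.R0_true.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_truth(path) -> SimulationConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    traits = TraitSet(tuple(payload["traits"]), tuple(payload["units"]))
    return SimulationConfig(
        n_families=payload["n_families"],
        n_blocks=payload["n_blocks"],
        mu=np.asarray(payload["mu"]),
        block_effects=np.asarray(payload["block_effects"]),
        G0_true=np.asarray(payload["G0_true"]),
        R0_true=np.asarray(payload["R0_true"]),
        seed=payload["seed"],
        traits=traits,
    )
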