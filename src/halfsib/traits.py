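"""Trait bookkeeping and covariance-matrix validation.

Every matrix in the package follows one canonical trait order:
row/column 1 = W100S (weight of 100 seeds, g), 2 = SOC (seed oil
content, %), 3 = PEC (phorbol ester concentration, mg/g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TraitSet:
    """An ordered set of trait labels with measurement units.

    The default instance is the canonical three-trait set used by the
    half-sib trial model; single-trait sets are accepted by the sampler
    (the model collapses to a univariate mixed model).
    """

    names: tuple[str, ...] = ("W100S", "SOC", "PEC")
    units: tuple[str, ...] = ("g", "%", "mg/g")

    def __post_init__(self) -> None:
        if len(self.names) != len(self.units):
            raise ValueError("names and units must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("trait names must be unique")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """Position of ``name`` in the canonical order."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown trait {name!r}; known traits: {self.names}") from None


CANONICAL_TRAITS = TraitSet()


def as_cov_matrix(m, name: str, dim: int | None = None, semidefinite: bool = False) -> np.ndarray:
    """Validate ``m`` as a symmetric positive-(semi)definite covariance matrix.

    Parameters
    ----------
    m : array-like
        Square matrix.
    name : str
        Used in error messages so the offending matrix is identifiable.
    dim : int, optional
        Required dimension.
    semidefinite : bool
        Accept positive semidefinite matrices (zero variance allowed).

    Returns
    -------
    numpy.ndarray
        A float copy of ``m``.
    """
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {a.shape}")
    if dim is not None and a.shape[0] != dim:
        raise ValueError(f"{name} must be {dim}x{dim}, got {a.shape[0]}x{a.shape[1]}")
    if not np.allclose(a, a.T, atol=1e-10 * max(1.0, float(np.abs(a).max(initial=0.0)))):
        raise ValueError(f"{name} is not symmetric")
    eig = np.linalg.eigvalsh(a)
    floor = -1e-10 * max(1.0, float(eig.max(initial=0.0)))
    if semidefinite:
        if eig.min(initial=0.0) < floor:
            raise ValueError(f"{name} is not positive semidefinite (min eigenvalue {eig.min():.3g})")
    else:
        if eig.min() <= 0:
            raise ValueError(f"{name} is not positive definite (min eigenvalue {eig.min():.3g})")
    return a.copy()


def psd_factor(m: np.ndarray) -> np.ndarray:
    """Square-root factor ``L`` with ``L @ L.T == m`` for a PSD matrix.

    Uses Cholesky when possible and an eigendecomposition fallback for
    singular matrices (needed for degenerate, zero-variance simulations).
    """
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(m)
        return v * np.sqrt(np.clip(w, 0.0, None))
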