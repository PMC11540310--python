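"""Additive trait architecture, true genotypic values, and phenotypes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TraitArchitecture:
    """Causal-locus indices and the full-length true effect vector.

    ``beta`` has length L with exact zeros at non-causal markers.
    """

    qtn_indices: np.ndarray
    beta: np.ndarray
    qtn_var: float = 0.35

    def __post_init__(self):
        object.__setattr__(self, "qtn_indices", np.asarray(self.qtn_indices, dtype=int))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        off = np.setdiff1d(np.arange(len(self.beta)), self.qtn_indices)
        if np.any(self.beta[off] != 0.0):
            raise ValueError("beta must be exactly zero off the causal loci")


@dataclass(frozen=True)
class PhenotypeSet:
    u: np.ndarray
    y: np.ndarray
    h2: float
    sigma_g2: float
    sigma_e2: float


def assign_qtn(L: int, n_qtn: int, rng: np.random.Generator | int) -> np.ndarray:
    """Choose ``n_qtn`` causal markers uniformly without replacement (sorted)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_qtn > L:
        raise ValueError("n_qtn cannot exceed the number of markers")
    return np.sort(rng.choice(L, size=n_qtn, replace=False))


def sample_qtn_effects(qtn_indices: np.ndarray, L: int, qtn_var: float = 0.35,
                       rng: np.random.Generator | int = 0) -> TraitArchitecture:
    """Draw i.i.d. Normal(0, qtn_var) effects at causal loci, zero elsewhere."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    beta = np.zeros(L)
    beta[qtn_indices] = rng.normal(0.0, np.sqrt(qtn_var), size=len(qtn_indices))
    return TraitArchitecture(qtn_indices=np.asarray(qtn_indices), beta=beta, qtn_var=qtn_var)


def genotypic_value(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """True genotypic values u = X @ beta for score matrix X."""
    return np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)


def simulate_phenotypes(u: np.ndarray, h2: float,
                        rng: np.random.Generator | int = 0) -> PhenotypeSet:
    """Add Normal noise so the target heritability holds in expectation.

    The genetic variance uses the population (denominator N) convention;
    the residual variance is sigma_g^2 / h2 - sigma_g^2.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    u = np.asarray(u, dtype=float)
    sigma_g2 = float(np.var(u))  # ddof=0
    if sigma_g2 == 0.0:
        raise ValueError("genetic variance is zero; heritability is undefined")
    sigma_e2 = sigma_g2 / h2 - sigma_g2
    y = u + rng.normal(0.0, np.sqrt(sigma_e2), size=len(u))
    return PhenotypeSet(u=u, y=y, h2=h2, sigma_g2=sigma_g2, sigma_e2=sigma_e2)
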