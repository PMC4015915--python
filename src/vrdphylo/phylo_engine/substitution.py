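"""Reversible n-state substitution models and among-site rate heterogeneity.

One general time-reversible (GTR) core serves both the 20-state protein
partition and k-state standard characters (the symmetric Mk model is GTR
with equal exchangeabilities and uniform frequencies).  Rate matrices are
rescaled to one expected substitution per unit branch length.  Rate
variation across sites follows the usual discretised gamma (equal-weight
categories represented by their means) plus a proportion of invariant
sites; the mixture of the invariant class (rate 0) and the scaled gamma
categories has mean rate exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property, lru_cache

import numpy as np
from scipy.special import gammainc, gammaincinv

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"


@lru_cache(maxsize=1024)
def _gamma_category_rates(a: float, m: int) -> np.ndarray:
    if m == 1:
        return np.ones(1)
    edges = gammaincinv(a, np.arange(1, m) / m) / a  # scale = 1/a, mean 1
    upper = gammainc(a + 1, np.append(edges * a, np.inf))
    seg = np.diff(np.insert(upper, 0, 0.0))
    out = seg * m
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible rate matrix defined by exchangeabilities and frequencies."""

    n_states: int
    exchangeabilities: np.ndarray  # symmetric, positive off-diagonal
    stationary_frequencies: np.ndarray
    alphabet: str | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.stationary_frequencies, dtype=float)
        n = self.n_states
        if r.shape != (n, n) or not np.allclose(r, r.T):
            raise ValueError("exchangeabilities must be a symmetric n x n matrix")
        if pi.shape != (n,) or not np.isclose(pi.sum(), 1.0) or (pi <= 0).any():
            raise ValueError("frequencies must be a positive simplex")
        off = r[~np.eye(n, dtype=bool)]
        if (off <= 0).any():
            raise ValueError("off-diagonal exchangeabilities must be positive")
        object.__setattr__(self, "exchangeabilities", r)
        object.__setattr__(self, "stationary_frequencies", pi)
        if self.alphabet is not None and len(self.alphabet) != n:
            raise ValueError("alphabet length must equal n_states")

    @classmethod
    def mk(cls, n_states: int, alphabet: str | None = None) -> "SubstitutionModel":
        """Symmetric k-state model (equal rates, uniform frequencies)."""
        if alphabet is None and n_states <= 10:
            alphabet = "0123456789"[:n_states]
        return cls(n_states, np.ones((n_states, n_states)),
                   np.full(n_states, 1.0 / n_states), alphabet)

    @classmethod
    def gtr(cls, exchangeabilities, frequencies, alphabet=None) -> "SubstitutionModel":
        r = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if r.ndim == 1:  # upper-triangle vector
            n = pi.size
            full = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            full[iu] = r
            full += full.T
            r = full
        return cls(pi.size, r, pi, alphabet)

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Q with stationary mean rate 1."""
        n = self.n_states
        pi = self.stationary_frequencies
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    @cached_property
    def _eigen(self):
        """Symmetric-form eigendecomposition: Q = U diag(w) V with V = U^-1."""
        pi = self.stationary_frequencies
        sqrt_pi = np.sqrt(pi)
        b = self.rate_matrix * (sqrt_pi[:, None] / sqrt_pi[None, :])
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        u = v / sqrt_pi[:, None]
        vi = v.T * sqrt_pi[None, :]
        return w, u, vi

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an array of effective branch lengths; shape (..., n, n)."""
        lengths = np.asarray(lengths, dtype=float)
        if not np.isfinite(lengths).all() or (lengths < 0).any():
            raise ValueError("branch lengths must be finite and non-negative")
        w, u, vi = self._eigen
        e = np.exp(np.multiply.outer(lengths, w))
        return np.einsum("ik,...k,kj->...ij", u, e, vi)


def transition_matrix(m: SubstitutionModel, t: float, rate: float = 1.0) -> np.ndarray:
    """Transition-probability matrix exp(Q * rate * t); rows sum to 1."""
    if not np.isfinite(t):
        raise ValueError("branch length must be finite")
    p = m.transition_matrices(np.asarray(t * rate))
    return np.clip(p, 0.0, None)


@dataclass(frozen=True)
class RateHeterogeneity:
    """Discrete-gamma rate variation plus a proportion of invariant sites."""

    gamma_shape: float = 1.0
    n_categories: int = 4
    p_invariant: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.n_categories < 1:
            raise ValueError("gamma shape and category count must be positive")
        if not 0 <= self.p_invariant <= 1:
            raise ValueError("p_invariant must be in [0, 1]")

    def category_rates(self) -> np.ndarray:
        """Mean-1 equal-probability gamma category rates (category means)."""
        return _gamma_category_rates(self.gamma_shape, self.n_categories)

    def mixture_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the variable classes, scaled so that the
        full mixture including the invariant class has mean rate 1."""
        if self.p_invariant == 1.0:  # degenerate: all sites invariant
            return np.ones(self.n_categories), np.zeros(self.n_categories)
        rates = self.category_rates() / (1.0 - self.p_invariant)
        weights = np.full(self.n_categories,
                          (1.0 - self.p_invariant) / self.n_categories)
        return rates, weights
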