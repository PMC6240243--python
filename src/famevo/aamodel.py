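"""Amino-acid substitution model for site-rate (conservation) inference.

A reversible 20-state rate matrix is assembled from an empirical
exchangeability matrix and a frequency vector, Q_ij = s_ij * pi_j,
normalized to one expected substitution per unit branch length.  The
default exchangeabilities are reconstructed from the BLOSUM62 log-odds
scores shipped with Biopython: since the BLOSUM score is (up to rounding)
2 * log2 of the odds ratio q_ij / (p_i p_j), the back-transform
``2 ** (score / 2)`` recovers relative exchangeabilities of an empirical
reversible model.  Rate variation across sites uses the standard
discretized gamma with equal-probability categories (mean-of-bin rates,
unit mean).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignments import AMINO_ACIDS

__all__ = [
    "blosum_exchangeabilities",
    "aa_rate_matrix",
    "discrete_gamma_rates",
    "ReversibleMatrix",
]

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@lru_cache(maxsize=1)
def blosum_exchangeabilities() -> np.ndarray:
    """Symmetric 20x20 exchangeabilities back-transformed from BLOSUM62."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AMINO_ACIDS)
    S = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                S[i, j] = 2.0 ** (blosum[a, b] / 2.0)
    return S


def aa_rate_matrix(
    freqs: np.ndarray | None = None, exchangeabilities: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(Q, pi): normalized reversible amino-acid rate matrix and frequencies.

    ``freqs`` defaults to uniform; it is cleaned (floored at 1e-4,
    renormalized) so alignments missing some residues stay well-posed.
    """
    n = len(AMINO_ACIDS)
    pi = np.full(n, 1.0 / n) if freqs is None else np.asarray(freqs, float)
    pi = np.maximum(pi, 1e-4)
    pi = pi / pi.sum()
    S = blosum_exchangeabilities() if exchangeabilities is None else exchangeabilities
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    Q = Q / rate
    return Q, pi


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability bins of Gamma(alpha, mean 1)."""
    if alpha <= 0 or k < 1:
        raise ValueError("alpha > 0 and k >= 1 required")
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X ; X in (a,b)] for Gamma(alpha, scale th) = alpha*th*(P(alpha+1,b/th)-P(alpha+1,a/th))
    upper = gammainc(alpha + 1, edges[1:] * alpha)
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    rates = k * (upper - lower)
    return rates / rates.mean() * 1.0


class ReversibleMatrix:
    """Eigendecomposed reversible rate matrix; cheap P(t) for many t."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = pi
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        B = (B + B.T) / 2.0  # enforce exact symmetry
        self._eval, self._evec = np.linalg.eigh(B)
        self._left = self._evec.T * sqrt_pi[None, :]
        self._right = self._evec / sqrt_pi[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("t must be >= 0")
        P = (self._right * np.exp(self._eval * t)[None, :]) @ self._left
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)
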