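"""GTR+Gamma nucleotide substitution model.

The general time-reversible (GTR) model is parameterised by the stationary
base frequencies ``pi`` (order A, C, G, T) and six symmetric exchangeability
parameters (order AC, AG, AT, CG, CT, GT).  Among-site rate heterogeneity is
modelled by a discrete gamma distribution with shape ``alpha`` and ``ncat``
equal-probability categories, each represented by its category mean (the
standard discretisation for likelihood phylogenetics).

The instantaneous rate matrix is normalised so that one unit of branch length
corresponds to one expected substitution per site at the stationary
distribution; gamma category rates have mean one, so the normalisation is
preserved under rate heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

#: Canonical nucleotide state order used throughout the package.
STATES = "ACGT"

#: Index pairs addressed by the six exchangeabilities (AC, AG, AT, CG, CT, GT).
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class ModelError(ValueError):
    """Raised for invalid substitution-model parameters."""


@dataclass(frozen=True)
class GTRModel:
    """A GTR+Gamma substitution model.

    Parameters
    ----------
    freqs:
        Stationary base frequencies (A, C, G, T); must be positive and sum
        to one within 1e-6 (they are renormalised exactly on construction).
    rates:
        Six positive exchangeabilities in the order AC, AG, AT, CG, CT, GT.
        Only relative values matter.
    alpha:
        Gamma shape for among-site rate variation, or ``None`` for a
        rate-homogeneous model.
    ncat:
        Number of discrete gamma categories (ignored when ``alpha`` is None).
    """

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rates: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    alpha: float | None = None
    ncat: int = 4

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (4,):
            raise ModelError("freqs must have exactly four entries")
        if np.any(freqs <= 0):
            raise ModelError("base frequencies must be positive")
        if abs(freqs.sum() - 1.0) > 1e-6:
            raise ModelError("base frequencies must sum to 1")
        object.__setattr__(self, "freqs",
                           tuple(float(f) for f in freqs / freqs.sum()))
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (6,):
            raise ModelError("rates must have exactly six entries")
        if np.any(rates <= 0):
            raise ModelError("exchangeabilities must be positive")
        object.__setattr__(self, "rates", tuple(float(r) for r in rates))
        if self.alpha is not None and self.alpha <= 0:
            raise ModelError("gamma shape alpha must be positive")
        if self.ncat < 1:
            raise ModelError("ncat must be >= 1")

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    def with_alpha(self, alpha: float | None) -> "GTRModel":
        return replace(self, alpha=alpha)

    def category_rates(self) -> np.ndarray:
        """Rates of the discrete gamma categories (a single 1.0 if homogeneous)."""
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.ncat)


def jukes_cantor(alpha: float | None = None, ncat: int = 4) -> GTRModel:
    """The Jukes–Cantor model as a GTR special case."""
    return GTRModel(alpha=alpha, ncat=ncat)


def gtr_rate_matrix(model: GTRModel) -> np.ndarray:
    """Normalised GTR instantaneous rate matrix Q.

    Satisfies: rows sum to zero, detailed balance pi_i q_ij = pi_j q_ji, and
    -sum_i pi_i q_ii = 1 (one expected substitution per unit branch length).
    """
    pi = model.pi
    q = np.zeros((4, 4))
    for r, (i, j) in zip(model.rates, _PAIRS):
        q[i, j] = r * pi[j]
        q[j, i] = r * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(q)))
    return q / scale


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability gamma categories.

    The gamma density has shape ``alpha`` and mean one.  Category ``k`` covers
    the (k/K, (k+1)/K) quantile slice and is represented by the conditional
    mean of the rate over that slice, computed in closed form from the
    regularised incomplete gamma function:  the partial expectation of a
    Gamma(alpha, rate=alpha) variable up to x equals ``gammainc(alpha+1,
    alpha*x)``.  The rates are non-decreasing and average exactly one.
    """
    if alpha <= 0:
        raise ModelError("gamma shape alpha must be positive")
    if ncat < 1:
        raise ModelError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha, scale=1.0 / alpha)
    cum = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * edges), [1.0]])
    rates = ncat * np.diff(cum)
    # guard against vanishing categories at extreme shapes
    return np.clip(rates, 1e-12, None)


@dataclass(frozen=True)
class EigenGTR:
    """Cached spectral decomposition of a GTR rate matrix.

    Because Q is reversible it is similar to a symmetric matrix via
    ``B = D Q D^-1`` with ``D = diag(sqrt(pi))``; transition matrices are then
    ``P(t) = D^-1 V exp(L t) V' D`` with ``B = V L V'``.
    """

    evals: np.ndarray
    left: np.ndarray   # D^-1 V        (4, 4)
    right: np.ndarray  # V' D          (4, 4)

    @classmethod
    def from_model(cls, model: GTRModel) -> "EigenGTR":
        q = gtr_rate_matrix(model)
        sq = np.sqrt(model.pi)
        b = sq[:, None] * q / sq[None, :]
        b = 0.5 * (b + b.T)  # symmetrise away round-off
        evals, vecs = np.linalg.eigh(b)
        return cls(evals=evals, left=vecs / sq[:, None], right=vecs.T * sq[None, :])

    def transition_matrices(self, lengths) -> np.ndarray:
        """P(t) for an array of branch lengths; output shape ``lengths.shape + (4, 4)``."""
        t = np.asarray(lengths, dtype=float)
        expo = np.exp(t[..., None] * self.evals)  # (..., 4)
        p = np.einsum("ij,...j,jk->...ik", self.left, expo, self.right)
        np.clip(p, 0.0, None, out=p)
        # renormalise rows exactly; round-off otherwise accumulates over nodes
        p /= p.sum(axis=-1, keepdims=True)
        return p


def transition_matrix(model: GTRModel, t: float) -> np.ndarray:
    """Convenience single-branch P(t)."""
    return EigenGTR.from_model(model).transition_matrices(np.array(t))
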