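"""Reversible amino-acid substitution models with discrete-gamma rates.

A :class:`RateModel` bundles a symmetric exchangeability matrix S, the
equilibrium frequencies pi, and K discrete-gamma rate categories of
equal weight 1/K.  The instantaneous rate matrix is

    q_ij = s_ij * pi_j   (i != j),   diagonal so rows sum to 0,

scaled so the expected substitution rate sum_i pi_i * (-q_ii) equals 1;
branch lengths are then expected substitutions per site.  Transition
probabilities come from the symmetric-form eigendecomposition

    B = diag(sqrt(pi)) Q diag(1/sqrt(pi))   (symmetric),
    P(t) = diag(1/sqrt(pi)) V exp(L t) V' diag(sqrt(pi)),

which is numerically stable and computed once per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from ._lg_data import LG_FREQUENCIES, LG_LOWER_TRIANGLE

N_STATES = 20


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Mean rates of K equal-probability gamma(alpha, alpha) bins.

    Standard mean-per-bin discretization of continuous gamma rate
    heterogeneity: bin boundaries are the k/K quantiles and each
    category rate is the conditional mean within its bin, renormalized
    so the category mean is exactly 1.

    >>> discrete_gamma_rates(1.0, 1)
    array([1.])
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.ones(1)
    # boundaries of gamma(shape=alpha, rate=alpha)
    probs = np.arange(1, K) / K
    bounds = _gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # partial expectation: E[X; X<=x] = gammainc(alpha+1, alpha*x) for mean-1 gamma
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1, alpha * bounds[1:]))
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    rates = K * (upper - lower)
    return rates / rates.mean()


def _build_exchangeabilities(lower: list[float]) -> np.ndarray:
    S = np.zeros((N_STATES, N_STATES))
    it = iter(lower)
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    return S


@dataclass
class RateModel:
    """Reversible substitution model + gamma rate categories.

    Parameters
    ----------
    exchangeabilities : (20, 20) symmetric non-negative matrix, zero diagonal.
    frequencies : length-20 equilibrium distribution.
    alpha : gamma shape (> 0); ignored when K == 1.
    K : number of equal-weight rate categories (>= 1).
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float = 1.0
    K: int = 1
    name: str = "custom"
    category_rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeabilities must be 20x20")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(S < 0) or np.any(np.diag(S) != 0):
            raise ValueError("exchangeabilities must be non-negative, zero diagonal")
        if pi.shape != (N_STATES,) or np.any(pi < 0):
            raise ValueError("frequencies must be 20 non-negative reals")
        pi = pi / pi.sum()
        self.exchangeabilities = S
        self.frequencies = pi
        self.category_rates = discrete_gamma_rates(self.alpha, self.K)

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))  # expected rate
        Q /= mu
        self.Q = Q
        # symmetric-form eigendecomposition
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)  # symmetrize against round-off
        eigval, eigvec = np.linalg.eigh(B)
        self._eigval = eigval
        self._U = eigvec / sq[:, None]  # diag(1/sqrt(pi)) V
        self._Ut = (eigvec * sq[:, None]).T  # V' diag(sqrt(pi))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t); rows sum to 1, entries clipped at 0 against round-off."""
        if t < 0:
            raise ValueError("negative branch length")
        if t == 0:
            return np.eye(N_STATES)
        P = (self._U * np.exp(self._eigval * t)) @ self._Ut
        np.clip(P, 0.0, None, out=P)
        return P

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.K, 1.0 / self.K)

    def with_categories(self, alpha: float, K: int) -> "RateModel":
        return RateModel(
            self.exchangeabilities.copy(),
            self.frequencies.copy(),
            alpha=alpha,
            K=K,
            name=self.name,
        )


def poisson_model(alpha: float = 1.0, K: int = 1) -> RateModel:
    """Equal exchangeabilities and uniform frequencies (20-state
    Jukes-Cantor analogue); analytically convenient for simulation and
    oracles."""
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return RateModel(S, pi, alpha=alpha, K=K, name="Poisson")


def lg_model(
    alpha: float = 1.0, K: int = 1, frequencies: np.ndarray | None = None
) -> RateModel:
    """LG model; pass empirical *frequencies* for the '+F' variant."""
    S = _build_exchangeabilities(LG_LOWER_TRIANGLE)
    pi = np.asarray(LG_FREQUENCIES) if frequencies is None else frequencies
    return RateModel(S, pi, alpha=alpha, K=K, name="LG")


def empirical_frequencies(aln, pseudocount: float = 0.5) -> np.ndarray:
    """Residue frequencies counted from an alignment ('+F')."""
    from .alignment import AMINO_ACIDS

    counts = np.array(
        [np.count_nonzero(aln.matrix == aa) for aa in AMINO_ACIDS], dtype=float
    )
    counts += pseudocount
    return counts / counts.sum()


def poisson_distance(p_different: float, cap: float = 10.0) -> float:
    """Closed-form ML distance under the Poisson model from the
    proportion of differing sites; saturated pairs capped."""
    limit = (N_STATES - 1) / N_STATES
    if p_different >= limit:
        return cap
    d = -limit * np.log(1.0 - p_different / limit)
    return float(min(d, cap))
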