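"""Exact distribution propagation and closed-form variance of mutant load.

For an infinite population of cells with ``M`` mitochondria each, the state is
a probability vector ``p`` over mutant counts 0..M.  One cell cycle is the
composition of a mutation step (column-stochastic matrix ``J``, binomial new
mutants among wild types) and a segregation step (matrix ``K``, hypergeometric
sampling of M copies from the duplicated pool of 2M).  After n divisions the
state is (K J)^n p0.  With no mutation, the variance of the mutant frequency
has the closed form

    Var(P_n) = p0 (1 - p0) [1 - (1 - 1/(2M-1))^n],

which rises from 0 to the binomial limit p0(1-p0): segregational drift never
changes the mean but steadily converts heteroplasmy into between-cell
variance.  With oogamy the zygote starts at 2^Q M copies and the first Q
divisions are partition-only, giving a suppressed-variance recurrence.

These formulas serve as the exact oracle against which the stochastic engine
is validated.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .cells import FitnessParams

__all__ = [
    "mutation_matrix",
    "segregation_matrix",
    "propagate_distribution",
    "distribution_moments",
    "conditional_segregation_variance",
    "variance_closed_form",
    "oogamy_variance_recurrence",
    "oogamy_variance_approx",
    "variance_profile",
    "expected_fitness_of_distribution",
    "delta_distribution",
]

_STOCHASTIC_TOL = 1e-12


def _validate_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("distribution must be a 1-d vector of length M+1 >= 2")
    if np.any(p < -_STOCHASTIC_TOL):
        raise ValueError("distribution has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"distribution must sum to 1, got {p.sum()}")
    return p


def delta_distribution(M: int, m0: int) -> np.ndarray:
    """Point mass at mutant count m0: the state of a clonal zygote."""
    if not 0 <= m0 <= M:
        raise ValueError(f"m0 must be in 0..{M}, got {m0}")
    p = np.zeros(M + 1)
    p[m0] = 1.0
    return p


def _renormalize(mat: np.ndarray) -> np.ndarray:
    # Guard against tiny negative round-off; keep columns exactly stochastic.
    mat = np.where((mat < 0) & (mat > -_STOCHASTIC_TOL), 0.0, mat)
    if np.any(mat < 0):
        raise FloatingPointError("transition matrix has negative entries")
    return mat / mat.sum(axis=0, keepdims=True)


def mutation_matrix(M: int, mu: float) -> np.ndarray:
    """Column-stochastic (M+1)x(M+1) mutation matrix J.

    Entry (q, m) is the probability a cell with m mutants ends the mutation
    step with q: Binomial(M - m, mu) pmf at q - m new mutants.  Mutation is
    one-way, so J is lower-triangular (q >= m).
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be a probability in [0, 1], got {mu}")
    q = np.arange(M + 1)[:, None]
    m = np.arange(M + 1)[None, :]
    k, n = q - m, M - m
    valid = (k >= 0) & (k <= n)
    if mu == 0.0:
        J = np.where(valid & (k == 0), 1.0, 0.0)
    elif mu == 1.0:
        J = np.where(valid & (k == n), 1.0, 0.0)
    else:
        # log-space binomial pmf: stable for extreme mu and large M
        kk = np.where(valid, k, 0)
        logpmf = (
            gammaln(n + 1)
            - gammaln(kk + 1)
            - gammaln(n - kk + 1)
            + kk * np.log(mu)
            + (n - kk) * np.log1p(-mu)
        )
        J = np.where(valid, np.exp(logpmf), 0.0)
    return _renormalize(J)


def segregation_matrix(M: int) -> np.ndarray:
    """Column-stochastic segregation matrix K.

    Entry (q, m): a cell with m mutants duplicates to 2m of 2M copies; a
    daughter sampling M of them without replacement receives q mutants —
    Hypergeom(2M, 2m, M) pmf at q.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    q = np.arange(M + 1)[:, None]
    m = np.arange(M + 1)[None, :]
    K = stats.hypergeom.pmf(q, 2 * M, 2 * m, M)
    return _renormalize(K)


def propagate_distribution(p0: np.ndarray, mu: float, n: int) -> np.ndarray:
    """Apply n cell cycles: p_n = (K J)^n p0.

    Iterated multiplication (n is small in every use here) with column
    renormalization keeps the result a probability vector under floating
    point.
    """
    p = _validate_distribution(p0)
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    M = p.size - 1
    if n == 0:
        return p.copy()
    step = segregation_matrix(M) @ mutation_matrix(M, mu)
    for _ in range(n):
        p = step @ p
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def distribution_moments(p: np.ndarray) -> tuple[float, float]:
    """Mean and variance of the mutant *count* under distribution p."""
    p = _validate_distribution(p)
    i = np.arange(p.size)
    mean = float(i @ p)
    var = float((i - mean) ** 2 @ p)
    return mean, var


def conditional_segregation_variance(m: int, M: int) -> float:
    """Variance of a daughter's mutant count given the parent holds m of M:
    m (M - m) / (2M - 1)."""
    if not 0 <= m <= M:
        raise ValueError(f"m must be in 0..{M}, got {m}")
    return m * (M - m) / (2 * M - 1)


def variance_closed_form(p0: float, M: int, n: int) -> float:
    """Var(P_n) = p0(1-p0)[1 - (1 - 1/(2M-1))^n] for mutation-free drift."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return p0 * (1.0 - p0) * (1.0 - (1.0 - 1.0 / (2 * M - 1)) ** n)


def oogamy_variance_recurrence(p0: float, M: int, Q: int, n: int) -> float:
    """Mutant-frequency variance after n partition-only divisions of a
    2^Q M zygote (1 <= n <= Q), from the recurrence

        Var(P_n) = p0(1-p0)/(2^{1+Q-n} M - 1)
                   + Var(P_{n-1}) (1 - 1/(2^{1+Q-n} M - 1)),

    with Var(P_0) = 0.  The large early copy number suppresses drift relative
    to the isogamous closed form.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if not 1 <= n <= Q:
        raise ValueError(f"n must satisfy 1 <= n <= Q={Q}, got {n}")
    var = 0.0
    for k in range(1, n + 1):
        denom = 2.0 ** (1 + Q - k) * M - 1.0
        var = p0 * (1.0 - p0) / denom + var * (1.0 - 1.0 / denom)
    return var


def oogamy_variance_approx(p0: float, M: int, Q: int, n: int) -> float:
    """Large-copy-number approximation of the oogamy recurrence:
    Var(P_n) ~= p0(1-p0)(2^n - 1) / (2^Q M)."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if not 1 <= n <= Q:
        raise ValueError(f"n must satisfy 1 <= n <= Q={Q}, got {n}")
    return p0 * (1.0 - p0) * (2.0**n - 1.0) / (2.0**Q * M)


def variance_profile(p0: float, M: int, Q: int, n: int) -> float:
    """Mutant-frequency variance after n mutation-free divisions of a 2^Q M
    zygote, continuing past the Q partition-only rounds with the standard
    replicative-segregation coefficient 1/(2M-1).  Q=0 reduces to the
    closed form."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    var = 0.0
    for k in range(1, n + 1):
        denom = (2.0 ** (1 + Q - k) * M - 1.0) if k <= Q else (2.0 * M - 1.0)
        var = p0 * (1.0 - p0) / denom + var * (1.0 - 1.0 / denom)
    return var


def expected_fitness_of_distribution(p: np.ndarray, fp: FitnessParams) -> float:
    """Expected cell fitness sum_i p_i (1 - s (i/M)^xi) under load
    distribution p; used by the extended-lifecycle approximation, where the
    adult's fitness is read off the analytic distribution instead of a full
    cell-lineage simulation."""
    p = _validate_distribution(p)
    M = p.size - 1
    loads = np.arange(M + 1) / M
    return float(p @ (1.0 - fp.s * loads**fp.xi))
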