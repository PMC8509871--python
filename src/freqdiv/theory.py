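"""Closed-form expectations for temporal allele-frequency divergence.

These calculators encode the neutral and selected predictions that the
empirical variance scan is compared against:

* the Wright-Fisher variance coefficient ``C_t = 1 - (1 - 1/2N)^t``;
* the selective-divergence contribution ``[p(1-p)]^2 Var(sum_i s_i)`` under
  three temporal-covariance structures of the total selection coefficient
  (perfectly constant per locus, i.i.d. per generation, or geometric decay
  of the covariance with time separation, as produced by recombination
  eroding linkage disequilibrium);
* the drift perturbation caused by a mean selective displacement of a
  cohort, ``D_t * c * (1 - 2p) * E[sum_i s_i]`` with an order-1 constant c;
* the migration divergence ``m^2 Var(p* - p | p)``;
* the sampling standard error of a binned variance coefficient and the
  detection limit (minimum number of independent loci) that follows from it.
"""

from __future__ import annotations

import math

__all__ = [
    "wf_variance_coefficient",
    "selective_divergence",
    "drift_perturbation",
    "migration_divergence",
    "se_variance_coefficient",
    "detection_limit",
]


def wf_variance_coefficient(N: float, t: float) -> float:
    """Neutral Wright-Fisher variance coefficient after t generations.

    ``C_t = 1 - (1 - 1/2N)**t`` for a diploid population of size N; this is
    the frequency-independent coefficient in ``Var(dp | p) = C_t p(1-p)``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    return 1.0 - (1.0 - 1.0 / (2.0 * N)) ** t


def _cov_sum(t: int, rho: float) -> float:
    """sum_{i,j<t} rho^|i-j| : number of (co)variance terms weighted by decay."""
    if rho == 1.0:
        return float(t * t)
    if rho == 0.0:
        return float(t)
    # t + 2 * sum_{k=1}^{t-1} (t-k) rho^k, via geometric sums
    s1 = (rho - rho**t) / (1.0 - rho)  # sum rho^k, k=1..t-1
    s2 = (rho - t * rho**t + (t - 1) * rho ** (t + 1)) / (1.0 - rho) ** 2
    # s2 = sum_{k=1}^{t-1} k rho^k
    return t + 2.0 * (t * s1 - s2)


def selective_divergence(
    sigma2_per_gen: float, t: int, p: float, covariance_model="full", rho=None
) -> float:
    """Among-locus variance of t-generation frequency change due to selection.

    Returns ``[p(1-p)]^2 * sigma2 * K(t)`` where K counts the variance and
    covariance terms of the per-generation total selection coefficients:
    ``K = t**2`` for perfectly temporally correlated coefficients
    (``covariance_model="full"``), ``K = t`` for i.i.d. per-generation
    coefficients (``"none"``), and the geometric interpolation
    ``K = sum_{i,j} rho**|i-j|`` for ``"decay"`` with decay rate rho per
    generation (the two-locus hitchhiking picture, where LD decays as
    (1-r)^|i-j|).
    """
    if sigma2_per_gen < 0:
        raise ValueError("sigma2_per_gen must be >= 0")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    t = int(t)
    if covariance_model == "full":
        k = float(t * t)
    elif covariance_model == "none":
        k = float(t)
    elif covariance_model == "decay":
        if rho is None or not 0.0 <= rho <= 1.0:
            raise ValueError("decay model needs rho in [0, 1]")
        k = _cov_sum(t, float(rho))
    else:
        raise ValueError(f"unknown covariance_model {covariance_model!r}")
    return (p * (1.0 - p)) ** 2 * sigma2_per_gen * k


def drift_perturbation(D_t: float, c: float, p: float, mean_total_s: float) -> float:
    """Perturbation of the drift variance by a mean selective displacement.

    A cohort whose frequencies are displaced by selection experiences
    slightly different drift; to first order the perturbation to C_t is
    ``D_t * c * (1 - 2p) * E[sum_i s_i]`` with c a frequency-independent
    constant of order 1. It vanishes at p = 1/2 and is antisymmetric under
    p -> 1-p.
    """
    return D_t * c * (1.0 - 2.0 * p) * mean_total_s


def migration_divergence(m: float, var_source_diff: float) -> float:
    """Divergence contributed by migration: ``m**2 * Var(p* - p | p)``."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must lie in [0, 1]")
    if var_source_diff < 0:
        raise ValueError("variance must be >= 0")
    return m * m * var_source_diff


def se_variance_coefficient(C: float, L: float) -> float:
    """Large-L standard error of a variance coefficient estimated from L loci.

    Assuming approximately Gaussian frequency changes, the sampling variance
    of the sample variance is ``2 Var^2 / (L-1) ~ 2 Var^2 / L``, giving
    ``SE(C) = sqrt(2/L) * C``.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    return math.sqrt(2.0 / L) * C


def detection_limit(
    C: float, sigma2: float, p: float, t: float, n_se: float = 1.0
) -> float:
    """Minimum number of independent loci to detect a selection signal.

    The excess-variance signal ``t**2 p(1-p) sigma2`` is detectable once it
    reaches ``n_se`` standard errors of C, i.e. ``n_se * sqrt(2/L) * C``.
    Solving for L gives ``L = 2 * (n_se * C / (t**2 p(1-p) sigma2))**2``.
    Returns ``inf`` for a zero signal.
    """
    if C <= 0 or t <= 0:
        raise ValueError("C and t must be positive")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    signal = t * t * p * (1.0 - p) * sigma2
    if signal <= 0:
        return math.inf
    return 2.0 * (n_se * C / signal) ** 2
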