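"""PAC surrogate likelihood, tract-length prior, and the posterior objective.

The joint probability of ``n`` haplotypes is factored sequentially,
P(h_1) * P(h_2 | h_1) * ... * P(h_n | h_1..h_{n-1}), and each conditional
replaced by the copying-HMM approximation pi_hat, giving the Product of
Approximate Conditionals (PAC) surrogate log-likelihood.  A log-normal
prior on the mean tract length (log10 lam ~ N(-0.5, 0.4^2), placing 95%
mass on [0.05, 2] kb) regularises the tract-length scale; the posterior
objective is log f(lam) + log l_PAC when lam is free, and the plain
crossover-only PAC log-likelihood on the no-conversion boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .copying_hmm import (
    ModelParams,
    conditional_log_prob,
    conditional_log_prob_crossover_only,
    estimate_theta,
)
from .data_io import HaplotypeMatrix

__all__ = [
    "OrderingPolicy",
    "pac_log_likelihood",
    "first_haplotype_log_prob",
    "log_prior_lambda",
    "log_posterior",
]

_PRIOR_MU = -0.5  # mean of log10(lam)
_PRIOR_SD = 0.4  # sd of log10(lam)
_LN10 = math.log(10.0)


@dataclass(frozen=True)
class OrderingPolicy:
    """How haplotypes are ordered in the sequential PAC product.

    PAC values depend on the conditioning order.  The default uses the
    input order, which keeps every computation deterministic; ``averaged``
    takes the mean log-likelihood over ``n_orders`` random permutations
    drawn from ``seed``.
    """

    mode: str = "fixed"
    n_orders: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "averaged"):
            raise ValueError("mode must be 'fixed' or 'averaged'")
        if self.mode == "averaged" and self.n_orders < 1:
            raise ValueError("n_orders must be >= 1")

    def orderings(self, n: int):
        if self.mode == "fixed":
            yield np.arange(n)
        else:
            rng = np.random.default_rng(self.seed)
            for _ in range(self.n_orders):
                yield rng.permutation(n)


def first_haplotype_log_prob(h1: np.ndarray, S: int, theta_hat: float) -> float:
    """Log-probability of the first haplotype in the PAC product.

    A uniform allele model, ``S * log(1/2)``, independent of the
    recombination parameters; it is identical in the numerator and
    denominator of the likelihood-ratio statistic and cancels there.
    """
    if S < 1:
        raise ValueError("need S >= 1 sites")
    return S * math.log(0.5)


def log_prior_lambda(lam: float) -> float:
    """Log-density of the mean tract length under log10(lam) ~ N(-0.5, 0.4^2).

    Returns -inf for non-positive ``lam`` (the optimizer's box excludes it).
    """
    if lam <= 0:
        return -math.inf
    z = (math.log10(lam) - _PRIOR_MU) / _PRIOR_SD
    return (
        -math.log(lam * _LN10 * _PRIOR_SD * math.sqrt(2.0 * math.pi))
        - 0.5 * z * z
    )


def _single_order_loglik(
    data: HaplotypeMatrix,
    params: ModelParams,
    order: np.ndarray,
    crossover_only: bool,
) -> float:
    H = data.alleles[order]
    pos = data.positions
    ll = first_haplotype_log_prob(H[0], data.n_sites, params.theta_hat)
    for k in range(1, data.n):
        if crossover_only:
            ll += conditional_log_prob_crossover_only(
                H[k], H[:k], pos, params.rho, params.theta_hat
            )
        else:
            ll += conditional_log_prob(H[k], H[:k], pos, params)
    return ll


def pac_log_likelihood(
    data: HaplotypeMatrix,
    params: ModelParams,
    policy: OrderingPolicy = OrderingPolicy(),
    crossover_only: bool = False,
) -> float:
    """PAC surrogate log-likelihood of the haplotype matrix.

    With ``crossover_only=True`` the conditionals come from the pure
    crossover copying model (gamma and lam ignored), which equals the full
    model at gamma = 0.
    """
    if data.n < 2:
        raise ValueError("need at least two haplotypes")
    if data.n_sites < 1:
        raise ValueError("need at least one segregating site")
    vals = [
        _single_order_loglik(data, params, order, crossover_only)
        for order in policy.orderings(data.n)
    ]
    return float(np.mean(vals))


def log_posterior(
    data: HaplotypeMatrix,
    params: ModelParams,
    policy: OrderingPolicy = OrderingPolicy(),
) -> float:
    """Log of the MAP objective: log f(lam) + log l_PAC.

    On the no-conversion boundary (gamma = 0) the model carries no tract
    length, so the prior term is omitted and the value is the
    crossover-only PAC log-likelihood.
    """
    if params.gamma == 0:
        return pac_log_likelihood(data, params, policy, crossover_only=True)
    return log_prior_lambda(params.lam) + pac_log_likelihood(data, params, policy)


def default_params(
    data: HaplotypeMatrix, rho: float, gamma: float, lam: float
) -> ModelParams:
    """Convenience constructor filling theta_hat from the sample size."""
    return ModelParams(
        rho=rho, gamma=gamma, lam=lam, theta_hat=estimate_theta(data.n)
    )
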