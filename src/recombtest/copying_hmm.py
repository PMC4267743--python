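"""Interleaved haplotype-copying HMM.

A target haplotype is modelled as an imperfect mosaic copy of ``k``
previously observed haplotypes.  Two coupled hidden chains run along the
sites: a crossover chain ``X`` (the background donor index) and a gene
conversion chain ``G`` taking values in {empty} plus the donor indices.
When the current site lies inside a conversion tract (``G != empty``) the
conversion donor is copied and the crossover chain is frozen, which
produces the prefix / internal-fragment / suffix pattern characteristic of
gene conversion; outside tracts the crossover donor is copied and the
crossover chain moves as a Poisson jump process.  Tract initiation and
termination are Poisson with rates ``gamma`` and ``1/lam``, and a new
tract may begin inside an ongoing one, so overlapping and nested
conversions are represented by donor renewal.

The forward recursion over the ``k * (k + 1)`` joint states yields the
approximate conditional probability pi_hat(target | panel, rho, gamma,
lam) used by the PAC likelihood.  Both chains scale their per-kb rates by
``1/k``, mirroring the per-haplotype recombination intensity of the
original PAC model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import forward_crossover_only, forward_joint

__all__ = [
    "ModelParams",
    "TransitionContext",
    "EMPTY",
    "estimate_theta",
    "crossover_transition",
    "conversion_transition",
    "initial_state_probs",
    "emission_prob",
    "conditional_log_prob",
    "conditional_log_prob_crossover_only",
]

#: Sentinel for the conversion chain's "not in a tract" state.
EMPTY: int | None = None


@dataclass(frozen=True)
class ModelParams:
    """Copying-model parameters.

    Attributes
    ----------
    rho
        Population-scaled crossover rate per kb (>= 0).
    gamma
        Population-scaled gene-conversion initiation rate per kb (>= 0).
    lam
        Mean conversion tract length in kb; must be positive whenever
        ``gamma > 0``.  The pair (gamma=0, any lam) and (lam=0, any gamma)
        give identical likelihoods — the model is not identifiable at the
        no-conversion boundary.
    theta_hat
        Per-site copying-mutation parameter (> 0).
    """

    rho: float
    gamma: float
    lam: float
    theta_hat: float

    def __post_init__(self) -> None:
        for name in ("rho", "gamma", "lam", "theta_hat"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.rho < 0 or self.gamma < 0:
            raise ValueError("rates must be non-negative")
        if self.gamma > 0 and self.lam <= 0:
            raise ValueError("lam must be positive when gamma > 0")
        if self.theta_hat <= 0:
            raise ValueError("theta_hat must be positive")


@dataclass(frozen=True)
class TransitionContext:
    """Panel size ``k`` and inter-SNP distance ``d`` (kb) for one step."""

    k: int
    d: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.d < 0:
            raise ValueError("d must be >= 0")


def estimate_theta(n: int) -> float:
    """Per-site mutation parameter of the PAC copying model.

    Returns ``1 / sum_{i=1}^{n-1} 1/i`` for a sample of ``n`` haplotypes —
    the Watterson-style plug-in used by the original PAC emissions.
    """
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    return 1.0 / sum(1.0 / i for i in range(1, n))


def crossover_transition(
    ctx: TransitionContext,
    params: ModelParams,
    from_x: int,
    to_x: int,
    g_next: int | None,
) -> float:
    """P(X_{j+1} = to_x | X_j = from_x, G_{j+1} = g_next).

    Inside a tract (``g_next`` not empty) the crossover chain is frozen.
    Outside, it jumps to a uniform donor at Poisson rate ``rho/k`` per kb.
    """
    k = ctx.k
    if not (1 <= from_x <= k and 1 <= to_x <= k):
        raise ValueError("donor indices must lie in 1..k")
    if g_next is not EMPTY:
        return 1.0 if to_x == from_x else 0.0
    p = math.exp(-params.rho * ctx.d / k)
    stay = p + (1.0 - p) / k
    return stay if to_x == from_x else (1.0 - p) / k


def conversion_transition(
    ctx: TransitionContext,
    params: ModelParams,
    from_g: int | None,
    to_g: int | None,
) -> float:
    """P(G_{j+1} = to_g | G_j = from_g) over a distance ``d``.

    Competing-risks parameterisation: with ``c = 1 - exp(-gamma*d/k)`` the
    probability a newly initiated tract covers the next site and
    ``e = 1 - exp(-d/lam)`` the probability an ongoing tract has ended, an
    ongoing tract survives unrenewed with ``(1-c)(1-e)``, ends with
    ``(1-c)e``, and is superseded by a fresh tract (overlap) with mass
    ``c/k`` per donor.  Rows sum to one exactly.
    """
    k = ctx.k
    gamma, lam, d = params.gamma, params.lam, ctx.d
    if gamma > 0 and lam <= 0:
        raise ValueError("lam must be positive when gamma > 0")
    c = 1.0 - math.exp(-gamma * d / k) if gamma > 0 else 0.0
    e = 1.0 - math.exp(-d / lam) if (gamma > 0 and lam > 0) else 0.0
    if from_g is EMPTY:
        if to_g is EMPTY:
            return 1.0 - c
        return c / k
    if to_g is EMPTY:
        return (1.0 - c) * e
    p = c / k
    if to_g == from_g:
        p += (1.0 - c) * (1.0 - e)
    return p


def initial_state_probs(k: int, params: ModelParams) -> np.ndarray:
    """Initial joint distribution as a ``(k, k+1)`` array.

    Row index is the crossover donor ``x`` (0-based); column 0 is the empty
    conversion state, column ``g`` (1-based) a conversion donor.  ``X_1``
    is uniform; ``G_1`` is empty with probability ``1/(1 + gamma*lam/k)``
    — the stationary balance of tract initiation (rate ``gamma/k``) and
    termination (rate ``1/lam``) — else uniform over donors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if params.gamma > 0:
        w = params.gamma * params.lam / k
        p_empty = 1.0 / (1.0 + w)
    else:
        p_empty = 1.0
    out = np.empty((k, k + 1))
    out[:, 0] = p_empty / k
    out[:, 1:] = (1.0 - p_empty) / (k * k)
    return out


def emission_prob(
    allele_next: int, donor_allele: int, k: int, theta_hat: float
) -> float:
    """Mosaic-copying emission: copy faithfully with probability
    ``k/(k+theta_hat)``, else emit a uniform allele."""
    if allele_next not in (0, 1) or donor_allele not in (0, 1):
        raise ValueError("alleles must be 0 or 1")
    base = 0.5 * theta_hat / (k + theta_hat)
    if allele_next == donor_allele:
        return k / (k + theta_hat) + base
    return base


def _validate_inputs(
    target: np.ndarray, panel: np.ndarray, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    target = np.ascontiguousarray(target, dtype=np.int8)
    panel = np.ascontiguousarray(panel, dtype=np.int8)
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    if panel.ndim != 2 or panel.shape[0] < 1:
        raise ValueError("panel must be a non-empty 2-D matrix")
    S = target.shape[0]
    if S == 0:
        raise ValueError("need at least one site")
    if panel.shape[1] != S or positions.shape[0] != S:
        raise ValueError("target, panel and positions lengths disagree")
    return target, panel, positions


def conditional_log_prob(
    target: np.ndarray,
    panel: np.ndarray,
    positions: np.ndarray,
    params: ModelParams,
) -> float:
    """log pi_hat(target | panel, rho, gamma, lam) by the forward
    algorithm over the joint (crossover, conversion) state space.

    Probabilities are renormalised at every site and the log accumulated
    from the scaling constants, so the value is finite for all valid
    inputs.
    """
    target, panel, positions = _validate_inputs(target, panel, positions)
    return float(
        forward_joint(
            target,
            panel,
            positions,
            float(params.rho),
            float(params.gamma),
            float(params.lam),
            float(params.theta_hat),
        )
    )


def conditional_log_prob_crossover_only(
    target: np.ndarray,
    panel: np.ndarray,
    positions: np.ndarray,
    rho: float,
    theta_hat: float,
) -> float:
    """log pi_hat under the crossover-only copying model (the original
    PAC conditional); equals :func:`conditional_log_prob` at gamma = 0."""
    target, panel, positions = _validate_inputs(target, panel, positions)
    if rho < 0 or not math.isfinite(rho):
        raise ValueError("rho must be finite and non-negative")
    return float(
        forward_crossover_only(target, panel, positions, float(rho), float(theta_hat))
    )
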