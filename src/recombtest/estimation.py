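"""MAP / ML point estimation of (rho, gamma, lam) by Nelder-Mead.

All searches run in log10-transformed coordinates inside finite box
bounds (rates 1e-4..1e3 per kb, tract length 1e-3..1e2 kb), with a small
number of deterministic starts.  Boundary hits are reported, not raised:
a gamma estimate at the lower box edge is the optimizer's way of saying
"no conversion signal" and is mapped to 0 in summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .copying_hmm import ModelParams, estimate_theta
from .data_io import HaplotypeMatrix
from .pac_likelihood import OrderingPolicy, log_posterior, pac_log_likelihood

__all__ = ["FitOptions", "FitResult", "fit_full", "fit_null_crossover", "fit_null_conversion"]

_RATE_BOUNDS = (-4.0, 3.0)  # log10 rho, log10 gamma
_LAM_BOUNDS = (-3.0, 2.0)  # log10 lam
_FULL_STARTS = (
    (0.0, 0.0, -0.5),  # rho=1, gamma=1, lam at the prior median
    (-1.0, 0.0, -0.5),
    (0.0, -1.0, -0.5),
)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    ``xatol`` and ``fatol`` are the Nelder-Mead simplex-size tolerance in
    log10 coordinates and the objective tolerance; ``maxfev`` caps the
    objective evaluations per start.  ``fast()`` returns the leaner preset
    used for bootstrap replicates, where thousands of fits are needed and
    a single start with a looser tolerance suffices.
    """

    n_starts: int = 3
    maxfev: int = 500
    xatol: float = 1e-4
    fatol: float = 1e-5

    @staticmethod
    def fast() -> "FitOptions":
        return FitOptions(n_starts=1, maxfev=200, xatol=5e-3, fatol=1e-4)


@dataclass
class FitResult:
    """Outcome of one maximization.

    ``params`` holds the raw estimates (possibly at a box bound);
    ``params_summary`` maps a gamma at the lower bound to exactly 0 for
    reporting.  ``objective`` is the attained log-posterior (or
    log-likelihood for the crossover-only null).
    """

    params: ModelParams
    objective: float
    converged: bool
    n_eval: int
    starts: list[dict] = field(default_factory=list)
    at_bounds: tuple[bool, ...] = ()

    @property
    def params_summary(self) -> ModelParams:
        p = self.params
        if p.gamma > 0 and math.log10(p.gamma) <= _RATE_BOUNDS[0] + 1e-9:
            return replace(p, gamma=0.0, lam=0.0)
        return p

    def __repr__(self) -> str:  # keep optimizer traces out of the default repr
        p = self.params
        return (
            f"FitResult(rho={p.rho:.4g}, gamma={p.gamma:.4g}, lam={p.lam:.4g}, "
            f"objective={self.objective:.4f}, converged={self.converged}, "
            f"n_eval={self.n_eval})"
        )


def _run_starts(objective, starts, bounds, options: FitOptions):
    best = None
    records = []
    n_eval = 0
    any_converged = False
    for z0 in starts[: options.n_starts]:
        res = minimize(
            objective,
            np.asarray(z0, dtype=float),
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "xatol": options.xatol,
                "fatol": options.fatol,
                "maxfev": options.maxfev,
                "adaptive": False,
            },
        )
        n_eval += res.nfev
        records.append(
            {"start": tuple(z0), "z": tuple(res.x), "neg_obj": float(res.fun),
             "converged": bool(res.success), "nfev": int(res.nfev)}
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best, records, n_eval, any_converged


def fit_full(
    data: HaplotypeMatrix,
    policy: OrderingPolicy = OrderingPolicy(),
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Maximize the posterior over (rho, gamma, lam).

    Runs Nelder-Mead from up to three deterministic starts in log10
    coordinates and returns the best; never raises on non-convergence
    (the ``converged`` flag records it).
    """
    _check_data(data)
    theta = estimate_theta(data.n)

    def neg(z: np.ndarray) -> float:
        p = ModelParams(
            rho=10.0 ** z[0], gamma=10.0 ** z[1], lam=10.0 ** z[2], theta_hat=theta
        )
        return -log_posterior(data, p, policy)

    bounds = [_RATE_BOUNDS, _RATE_BOUNDS, _LAM_BOUNDS]
    best, records, n_eval, converged = _run_starts(neg, _FULL_STARTS, bounds, options)
    z = best.x
    params = ModelParams(
        rho=10.0 ** z[0], gamma=10.0 ** z[1], lam=10.0 ** z[2], theta_hat=theta
    )
    at_bounds = tuple(
        z[i] <= bounds[i][0] + 1e-9 or z[i] >= bounds[i][1] - 1e-9 for i in range(3)
    )
    return FitResult(params, -float(best.fun), converged, n_eval, records, at_bounds)


def fit_null_crossover(
    data: HaplotypeMatrix,
    policy: OrderingPolicy = OrderingPolicy(),
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Maximize the crossover-only PAC likelihood over rho (gamma=lam=0)."""
    _check_data(data)
    theta = estimate_theta(data.n)

    def neg(z: np.ndarray) -> float:
        p = ModelParams(rho=10.0 ** z[0], gamma=0.0, lam=0.0, theta_hat=theta)
        return -pac_log_likelihood(data, p, policy, crossover_only=True)

    starts = [(-1.0,), (0.0,), (1.0,)]
    best, records, n_eval, converged = _run_starts(neg, starts, [_RATE_BOUNDS], options)
    z0_low = _RATE_BOUNDS[0]
    # parsimony tie-break: data with no recombination signal (e.g. monomorphic
    # haplotypes) leave the likelihood flat in rho; report the lower bound then
    low_obj = neg(np.array([z0_low]))
    n_eval += 1
    if low_obj <= best.fun + options.fatol:
        z_hat, obj = z0_low, -float(low_obj)
        converged = True
    else:
        z_hat, obj = float(best.x[0]), -float(best.fun)
    params = ModelParams(rho=10.0 ** z_hat, gamma=0.0, lam=0.0, theta_hat=theta)
    at_bounds = (
        z_hat <= _RATE_BOUNDS[0] + 1e-9 or z_hat >= _RATE_BOUNDS[1] - 1e-9,
    )
    return FitResult(params, obj, converged, n_eval, records, at_bounds)


def fit_null_conversion(
    data: HaplotypeMatrix,
    policy: OrderingPolicy = OrderingPolicy(),
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Maximize the posterior over (gamma, lam) with rho fixed at 0."""
    _check_data(data)
    theta = estimate_theta(data.n)

    def neg(z: np.ndarray) -> float:
        p = ModelParams(
            rho=0.0, gamma=10.0 ** z[0], lam=10.0 ** z[1], theta_hat=theta
        )
        return -log_posterior(data, p, policy)

    starts = [(0.0, -0.5), (-1.0, -0.5), (1.0, -0.5)]
    bounds = [_RATE_BOUNDS, _LAM_BOUNDS]
    best, records, n_eval, converged = _run_starts(neg, starts, bounds, options)
    z = best.x
    params = ModelParams(
        rho=0.0, gamma=10.0 ** z[0], lam=10.0 ** z[1], theta_hat=theta
    )
    at_bounds = (
        z[0] <= _RATE_BOUNDS[0] + 1e-9 or z[0] >= _RATE_BOUNDS[1] - 1e-9,
        z[1] <= _LAM_BOUNDS[0] + 1e-9 or z[1] >= _LAM_BOUNDS[1] - 1e-9,
    )
    return FitResult(params, -float(best.fun), converged, n_eval, records, at_bounds)


def _check_data(data: HaplotypeMatrix) -> None:
    if data.n < 2:
        raise ValueError("need at least two haplotypes")
    if data.n_sites < 2:
        raise ValueError("need at least two segregating sites")
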