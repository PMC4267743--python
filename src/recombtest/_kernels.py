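"""Numba forward-recursion kernels.

The joint kernel exploits the structure of the interleaved transition:
the conversion step needs only the per-row totals of the forward mass and
the crossover step only the column-0 total, so one site costs
O(k * (k + 1)) rather than O((k * (k + 1))^2).  Forward mass is
renormalised at every site (scaled forward algorithm); nothing is
truncated to zero before the log.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["forward_joint", "forward_crossover_only"]


@njit(cache=True)
def forward_joint(target, panel, positions, rho, gamma, lam, theta):
    k, S = panel.shape
    f = np.empty((k, k + 1))
    m = np.empty((k, k + 1))
    if gamma > 0.0:
        p_empty = 1.0 / (1.0 + gamma * lam / k)
    else:
        p_empty = 1.0
    em_match = k / (k + theta) + 0.5 * theta / (k + theta)
    em_mis = 0.5 * theta / (k + theta)

    t0 = target[0]
    tot = 0.0
    for x in range(k):
        ex = em_match if panel[x, 0] == t0 else em_mis
        f[x, 0] = (p_empty / k) * ex
        tot += f[x, 0]
        pg = (1.0 - p_empty) / (k * k)
        for g in range(k):
            eg = em_match if panel[g, 0] == t0 else em_mis
            f[x, g + 1] = pg * eg
            tot += f[x, g + 1]
    ll = math.log(tot)
    for x in range(k):
        for g in range(k + 1):
            f[x, g] /= tot

    for j in range(1, S):
        d = positions[j] - positions[j - 1]
        c = 1.0 - math.exp(-gamma * d / k) if gamma > 0.0 else 0.0
        e = 1.0 - math.exp(-d / lam) if (gamma > 0.0 and lam > 0.0) else 0.0
        p = math.exp(-rho * d / k)
        # conversion-chain step: f[x, .] -> m[x, .]
        for x in range(k):
            row_sum = 0.0
            for g in range(k + 1):
                row_sum += f[x, g]
            in_tract = row_sum - f[x, 0]
            m[x, 0] = (1.0 - c) * (f[x, 0] + e * in_tract)
            fresh = (c / k) * row_sum
            keep = (1.0 - c) * (1.0 - e)
            for b in range(1, k + 1):
                m[x, b] = fresh + keep * f[x, b]
        # crossover-chain step (identity when the next site is in a tract)
        col0 = 0.0
        for x in range(k):
            col0 += m[x, 0]
        tj = target[j]
        tot = 0.0
        for x in range(k):
            ex = em_match if panel[x, j] == tj else em_mis
            v = (p * m[x, 0] + (1.0 - p) / k * col0) * ex
            f[x, 0] = v
            tot += v
            for b in range(1, k + 1):
                eb = em_match if panel[b - 1, j] == tj else em_mis
                v = m[x, b] * eb
                f[x, b] = v
                tot += v
        ll += math.log(tot)
        for x in range(k):
            for g in range(k + 1):
                f[x, g] /= tot
    return ll


@njit(cache=True)
def forward_crossover_only(target, panel, positions, rho, theta):
    k, S = panel.shape
    f = np.empty(k)
    em_match = k / (k + theta) + 0.5 * theta / (k + theta)
    em_mis = 0.5 * theta / (k + theta)

    t0 = target[0]
    tot = 0.0
    for x in range(k):
        ex = em_match if panel[x, 0] == t0 else em_mis
        f[x] = ex / k
        tot += f[x]
    ll = math.log(tot)
    for x in range(k):
        f[x] /= tot

    for j in range(1, S):
        d = positions[j] - positions[j - 1]
        p = math.exp(-rho * d / k)
        total = 0.0
        for x in range(k):
            total += f[x]
        tj = target[j]
        tot = 0.0
        for x in range(k):
            ex = em_match if panel[x, j] == tj else em_mis
            v = (p * f[x] + (1.0 - p) / k * total) * ex
            f[x] = v
            tot += v
        ll += math.log(tot)
        for x in range(k):
            f[x] /= tot
    return ll
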