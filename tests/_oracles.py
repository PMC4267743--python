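"""Independent brute-force oracles for the copying HMM.

These enumerate every hidden path through the joint (crossover,
conversion) state space using the scalar transition / emission functions,
so they share no code with the forward-recursion kernels they check.
Only usable for k <= 3, S <= 4 or so.
"""

import itertools
import math

from recombtest.copying_hmm import (
    EMPTY,
    TransitionContext,
    conversion_transition,
    crossover_transition,
    emission_prob,
    initial_state_probs,
)


def enumerate_log_prob(target, panel, positions, params):
    """log pi_hat by summing the probability of every hidden path."""
    k, S = panel.shape
    states = [
        (x, g) for x in range(1, k + 1) for g in [EMPTY] + list(range(1, k + 1))
    ]
    init = initial_state_probs(k, params)
    total = 0.0
    for path in itertools.product(states, repeat=S):
        x0, g0 = path[0]
        p = init[x0 - 1, 0 if g0 is EMPTY else g0]
        donor = (g0 if g0 is not EMPTY else x0) - 1
        p *= emission_prob(
            int(target[0]), int(panel[donor, 0]), k, params.theta_hat
        )
        for j in range(1, S):
            if p == 0.0:
                break
            x1, g1 = path[j]
            ctx = TransitionContext(k=k, d=float(positions[j] - positions[j - 1]))
            p *= conversion_transition(ctx, params, path[j - 1][1], g1)
            p *= crossover_transition(ctx, params, path[j - 1][0], x1, g1)
            donor = (g1 if g1 is not EMPTY else x1) - 1
            p *= emission_prob(
                int(target[j]), int(panel[donor, j]), k, params.theta_hat
            )
        total += p
    return math.log(total)


def enumerate_log_prob_crossover_only(target, panel, positions, rho, theta_hat):
    """Crossover-only oracle: paths over donor indices only."""
    k, S = panel.shape
    total = 0.0
    for path in itertools.product(range(1, k + 1), repeat=S):
        p = 1.0 / k
        p *= emission_prob(
            int(target[0]), int(panel[path[0] - 1, 0]), k, theta_hat
        )
        for j in range(1, S):
            d = float(positions[j] - positions[j - 1])
            stay = math.exp(-rho * d / k)
            prob = (1.0 - stay) / k
            if path[j] == path[j - 1]:
                prob += stay
            p *= prob
            p *= emission_prob(
                int(target[j]), int(panel[path[j] - 1, j]), k, theta_hat
            )
        total += p
    return math.log(total)
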