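"""Compiled first-passage kernels shared by the simulator and the fit objective."""

import numpy as np
from numba import njit


@njit(cache=True)
def first_passage(noise, mu_dt, auto_inc, signed_zetas, bound):
    """Euler first-passage times for a batch of accumulator trials.

    Parameters
    ----------
    noise : (n, n_steps) float64
        Pre-scaled diffusion increments (sigma * sqrt(dt) * N(0, 1)).
    mu_dt : float
        Controlled-drift increment per step (mu_c * dt).
    auto_inc : (n_steps,) float64
        Unit-amplitude automatic-activation increments per step.
    signed_zetas : (n,) float64
        Per-trial automatic amplitude including the congruency sign
        (+zeta congruent, -zeta incongruent).
    bound : float
        Absorbing boundary; accumulation starts at 0, absorbs at +-bound.

    Returns
    -------
    steps, correct, absorbed : int64/bool/bool arrays of length n.
        Unabsorbed trials get steps = n_steps, correct = False.
    """
    n, n_steps = noise.shape
    steps = np.empty(n, np.int64)
    correct = np.empty(n, np.bool_)
    absorbed = np.empty(n, np.bool_)
    for i in range(n):
        x = 0.0
        sz = signed_zetas[i]
        k_hit = n_steps
        hit = False
        c = False
        for k in range(n_steps):
            x += mu_dt + sz * auto_inc[k] + noise[i, k]
            if x >= bound:
                k_hit = k + 1
                hit = True
                c = True
                break
            elif x <= -bound:
                k_hit = k + 1
                hit = True
                c = False
                break
        steps[i] = k_hit
        correct[i] = c
        absorbed[i] = hit
    return steps, correct, absorbed
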