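"""Numba-compiled inner loop of the stochastic engine.

The kernel implements exactly the same elementary-step law as
:func:`damseg.engine.step`, consuming draws from the same
``numpy.random.Generator`` stream in the same order (selection, death,
divider, mutation, placement), so a trajectory produced here is
bit-identical to one produced by repeated Python-level steps with the same
seed. Keeping the loop in compiled code makes collapse-time experiments
(10^6-10^8 elementary steps) practical.

First-passage events (loss of the initial-level class, entry into the
all-damage-one state) are tracked at elementary-step resolution through
O(1) class counters; both events are absorbing, so the first step at which
a counter hits its target is exact. The loop still runs to the end of the
current time unit before stopping, so per-unit recording by the caller
stays aligned.
"""

from __future__ import annotations

import numba
import numpy as np

#: stop_mode values understood by :func:`advance_units`.
STOP_NONE = 0       # run all units (still halts in the absorbing state)
STOP_F0_ZERO = 1    # halt once no cell sits exactly at the initial level


@numba.njit(cache=True)
def advance_units(
    damages: np.ndarray,
    increments: np.ndarray,
    rng,
    n_units: int,
    p: float,
    delta: float,
    symmetric: bool,
    ring: bool,
    epsilon: float,
    stop_mode: int,
):
    """Advance the population by up to ``n_units`` time units in place.

    One time unit is N elementary steps. Returns
    ``(steps_done, first_f0_zero_step, first_all_one_step)`` with the
    first-passage entries counted in elementary steps from the start of
    this call (1-based; -1 if the event was not observed).
    """
    n = damages.shape[0]
    n_f0 = 0
    n_one = 0
    for c in range(n):
        if damages[c] == epsilon:
            n_f0 += 1
        if damages[c] == 1.0:
            n_one += 1
    first_f0_zero = np.int64(-1)
    first_all_one = np.int64(-1)
    steps_done = np.int64(0)
    for _u in range(n_units):
        for _ in range(n):
            steps_done += 1
            i = rng.integers(0, n)
            if rng.random() < damages[i]:
                # the apoptotic cell is removed; a neighbour divides
                if ring:
                    if rng.random() < 0.5:
                        j = (i - 1) % n
                    else:
                        j = (i + 1) % n
                else:
                    j = rng.integers(0, n - 1)
                    if j >= i:
                        j += 1
                mutated = rng.random() < p
                dj = damages[j]
                cj = increments[j]
                if mutated:
                    if symmetric:
                        d_hi = min(dj + 0.5 * delta, 1.0)
                        d_lo = d_hi
                        c_hi = cj + 1
                        c_lo = cj + 1
                    else:
                        d_hi = min(dj + delta, 1.0)
                        d_lo = dj
                        c_hi = cj + 1
                        c_lo = cj
                else:
                    d_hi = dj
                    d_lo = dj
                    c_hi = cj
                    c_lo = cj
                for slot in (i, j):
                    if damages[slot] == epsilon:
                        n_f0 -= 1
                    if damages[slot] == 1.0:
                        n_one -= 1
                if rng.random() < 0.5:
                    damages[i] = d_hi
                    increments[i] = c_hi
                    damages[j] = d_lo
                    increments[j] = c_lo
                else:
                    damages[i] = d_lo
                    increments[i] = c_lo
                    damages[j] = d_hi
                    increments[j] = c_hi
                for slot in (i, j):
                    if damages[slot] == epsilon:
                        n_f0 += 1
                    if damages[slot] == 1.0:
                        n_one += 1
                if first_f0_zero < 0 and n_f0 == 0:
                    first_f0_zero = steps_done
                if first_all_one < 0 and n_one == n:
                    first_all_one = steps_done
        if first_all_one >= 0:
            break
        if stop_mode == STOP_F0_ZERO and first_f0_zero >= 0:
            break
    return steps_done, first_f0_zero, first_all_one
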