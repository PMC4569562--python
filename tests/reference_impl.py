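"""Naive per-element reference stepper, used as an oracle.

Implements the collapse-driven step with plain Python floats, lists and
scalar loops — no vectorised shortcuts — while consuming the random
stream through the same generator calls as the optimised stepper (one
uniform double per victim draw).  For small communities (N <= 6, where
numpy reductions are sequential) the two implementations must agree
bit for bit.
"""

import numpy as np


def reference_run(
    N,
    gamma,
    n_steps,
    seed,
    victim_policy="uniform",  # "uniform" or "size_proportional" (KtW sigma=1)
    equalize_at_wave_start=False,
    wave_threshold=None,
    substantial_threshold=1e-10,
):
    """Run the basic (or sigma=1 kill-the-winner) model naively.

    Returns (trajectory, events): trajectory[t] is the population list
    after step t (t = 0 is the initial state), events are tuples
    (step, victim, pre_size, is_boundary, rescale_factor).
    """
    if wave_threshold is None:
        wave_threshold = 1.0 - 1.0 / N
    rng = np.random.default_rng(seed)
    pops = [1.0 / N for _ in range(N)]
    trajectory = [list(pops)]
    events = []
    for t in range(1, n_steps + 1):
        u = rng.random()
        if victim_policy == "uniform":
            victim = min(int(u * N), N - 1)
        else:  # selection probability proportional to population size
            total = 0.0
            cum = []
            for p in pops:
                total += p
                cum.append(total)
            target = u * total
            victim = N - 1
            for i, c in enumerate(cum):
                if c > target:
                    victim = i
                    break
        pre = pops[victim]
        boundary = pre > wave_threshold
        pops[victim] = gamma
        total = 0.0
        for p in pops:
            total += p
        factor = 1.0 / total
        if equalize_at_wave_start and boundary:
            for i in range(N):
                pops[i] = 1.0 / N
        else:
            for i in range(N):
                pops[i] = pops[i] * factor
        trajectory.append(list(pops))
        events.append((t, victim, pre, boundary, factor))
    return trajectory, events
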