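"""Independently coded vanilla Whale Optimization, used as a reduction oracle.

This transcribes the classic WOA equations directly (encircle / explore /
spiral with the shrinking coefficient ``a``), consuming random draws in the
same per-whale order as the package optimizer so the two can share one
random stream.  It deliberately avoids calling any of the package's update
functions.
"""

import math

import numpy as np

from retikan.iwo import SearchSpace, chaotic_initialize


def vanilla_woa(objective, space: SearchSpace, population: int, tmax: int,
                a_schedule, b: float, seed: int):
    """Minimize with textbook WOA; returns (positions log, best history)."""
    rng = np.random.default_rng(seed)
    pop = chaotic_initialize(space, population, rng)
    evaluated = []
    for w in pop:
        w.fitness = objective(w.position)
        evaluated.append(w.position.copy())
    best = min(pop, key=lambda w: w.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    history = [best_fit]

    for t in range(1, tmax + 1):
        a = a_schedule(t)
        new_positions = []
        for w in pop:
            rand_pos = pop[int(rng.integers(population))].position
            p = rng.random()
            r1 = rng.random(len(space))
            r2 = rng.random(len(space))
            s = rng.uniform(-1.0, 1.0)
            avec = 2.0 * a * r1 - a
            cvec = 2.0 * r2
            if p < 0.5:
                if np.abs(avec).mean() >= 1.0:
                    new = rand_pos - avec * np.abs(cvec * rand_pos - w.position)
                else:
                    new = best_pos - avec * np.abs(cvec * best_pos - w.position)
            else:
                dist = np.abs(best_pos - w.position)
                new = best_pos + dist * math.exp(b * s) * math.cos(
                    2.0 * math.pi * s)
            new_positions.append(space.clip(new))
        for w, pos in zip(pop, new_positions):
            w.position = pos
            w.fitness = objective(pos)
            evaluated.append(pos.copy())
            if w.fitness < best_fit:
                best_fit = w.fitness
                best_pos = w.position.copy()
        history.append(best_fit)
    return evaluated, history
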