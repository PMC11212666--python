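"""Independent brute-force oracles used by the test suite.

Everything here is written with plain Python loops and scipy primitives,
deliberately independent of the vectorized implementations it checks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy.stats import multinomial


def brute_force_bray_curtis(c1: dict[str, int], c2: dict[str, int]) -> float:
    """Naive double-loop Bray-Curtis on two {species: count} maps."""
    shared = 0
    for s in set(c1) | set(c2):
        shared += min(c1.get(s, 0), c2.get(s, 0))
    j1 = sum(c1.values())
    j2 = sum(c2.values())
    return 1.0 - 2.0 * shared / (j1 + j2)


def brute_force_rao(traits: list[float], counts: list[int]) -> float:
    """Abundance-weighted mean absolute pairwise trait difference."""
    total = sum(counts)
    out = 0.0
    for ti, ni in zip(traits, counts):
        for tj, nj in zip(traits, counts):
            out += (ni / total) * (nj / total) * abs(ti - tj)
    return out


def brute_force_competition_load(
    focal_trait: float,
    traits: list[float],
    counts: list[int],
    sigma_comp: float,
    focal_index: int | None = None,
) -> float:
    """Pairwise sum over individuals of the Gaussian overlap kernel.

    ``focal_index`` marks the focal individual's own species, one
    individual of which is excluded from the load.
    """
    individuals = []
    for i, (t, n) in enumerate(zip(traits, counts)):
        individuals.extend([(i, t)] * n)
    if focal_index is not None:
        for k, (i, _) in enumerate(individuals):
            if i == focal_index:
                del individuals[k]
                break
    load = 0.0
    for _, t in individuals:
        load += math.exp(-((focal_trait - t) ** 2) / (2.0 * sigma_comp**2))
    return load / len(individuals)


def _death_vector_probs(
    counts: tuple[int, ...], weights: tuple[float, ...], K: int
) -> dict[tuple[int, ...], float]:
    """Distribution of per-species death counts under successive weighted
    sampling without replacement of K individuals."""
    out: dict[tuple[int, ...], float] = {}

    def recurse(remaining: tuple[int, ...], deaths: tuple[int, ...], prob: float, k: int):
        if k == 0:
            out[deaths] = out.get(deaths, 0.0) + prob
            return
        z = sum(c * w for c, w in zip(remaining, weights))
        for s, (c, w) in enumerate(zip(remaining, weights)):
            if c == 0:
                continue
            p = c * w / z
            rem = list(remaining)
            rem[s] -= 1
            d = list(deaths)
            d[s] += 1
            recurse(tuple(rem), tuple(d), prob * p, k - 1)

    recurse(counts, tuple(0 for _ in counts), 1.0, K)
    return out


def enumerate_step_distribution(
    counts: tuple[int, ...],
    traits: tuple[float, ...],
    pool_ab: tuple[float, ...],
    env: float,
    sigma_env: float,
    sigma_comp: float,
    comp_strength: float,
    death_fraction: float,
    m: float,
    death_floor: float,
    recruit_weighting: str = "fitness",
) -> dict[tuple[int, ...], float]:
    """Exact one-step transition distribution of the lottery update.

    Enumerates every death multiset (successive weighted sampling without
    replacement) and, for each, sums over the number of immigrants
    (binomial in K) and the two multinomial recruit draws taken at the
    post-death state.  Fitness follows the same model definition computed
    with scalar math here.
    """
    S = len(counts)
    J = sum(counts)
    K = round(death_fraction * J)

    # species fitness against the pre-death community, focal excluded
    fit = []
    for s in range(S):
        f_env = math.exp(-((traits[s] - env) ** 2) / (2.0 * sigma_env**2))
        if comp_strength > 0:
            tot = 0.0
            for t2 in range(S):
                tot += counts[t2] * math.exp(
                    -((traits[s] - traits[t2]) ** 2) / (2.0 * sigma_comp**2)
                )
            if counts[s] > 0:
                load = (tot - 1.0) / (J - 1)
            else:
                load = tot / J
            fit.append(f_env * math.exp(-comp_strength * load))
        else:
            fit.append(f_env)
    fmax = max(f for f, c in zip(fit, counts) if c > 0)
    weights = tuple(1.0 - f / fmax + death_floor for f in fit)

    deaths = _death_vector_probs(tuple(counts), weights, K)

    if recruit_weighting in ("fitness", "immigration"):
        wp = [q * f for q, f in zip(pool_ab, fit)]
    else:
        wp = list(pool_ab)
    zp = sum(wp)
    pool_p = [w / zp for w in wp]

    out: dict[tuple[int, ...], float] = {}
    for d, pd_ in deaths.items():
        surv = tuple(c - dd for c, dd in zip(counts, d))
        if recruit_weighting == "fitness":
            wl = [c * f for c, f in zip(surv, fit)]
        else:
            wl = [float(c) for c in surv]
        zl = sum(wl)
        local_p = [w / zl for w in wl]
        # each recruit is independently an immigrant with probability m
        recruit_p = [m * pp + (1 - m) * lp for pp, lp in zip(pool_p, local_p)]
        for rec in product(range(K + 1), repeat=S):
            if sum(rec) != K:
                continue
            pr = multinomial.pmf(rec, n=K, p=recruit_p)
            if pr <= 0:
                continue
            final = tuple(s + r for s, r in zip(surv, rec))
            out[final] = out.get(final, 0.0) + pd_ * pr
    return out
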