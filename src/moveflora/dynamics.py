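"""The per-generation lottery update.

Each generation a fixed expected fraction of the community dies, with
individual death probabilities weighted against relative fitness, and every
vacancy is refilled immediately — from surviving residents or, with
probability ``m``, by an immigrant from the environmental species pool.
Recruitment weights are abundance-based, optionally multiplied by fitness
in the current environment on either branch (see ``recruit_weighting``).
Community size ``J`` is conserved exactly at every step.

Death weights are ``1 - f/max(f) + eps`` with a small floor ``eps`` so that
even a perfectly adapted species retains a nonzero death hazard; this keeps
ecological drift alive and gives the exact neutral lottery in the
equal-fitness limit.  Deaths are drawn without replacement via an
exponential race (each individual draws Exp(1)/weight; the smallest K
values die), which is distributionally identical to successive weighted
draws without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pools import Community, SpeciesPool
from .selection import SelectionParams, species_fitness

__all__ = ["DynamicsParams", "select_deaths", "fill_vacancies", "step"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DynamicsParams:
    """Turnover and immigration parameters.

    death_fraction
        Expected fraction of J replaced per generation (K = round(dJ)).
    immigration_rate
        Probability m that a vacancy is filled from the pool rather than
        from surviving residents.
    death_floor
        Floor eps added to every death weight.
    pool_weighting
        'abundance' weights the immigration branch by pool relative
        abundance; 'uniform' draws immigrant species uniformly.
    recruit_weighting
        'fitness' (default): recruitment weights (local and immigrant) are
        multiplied by individual fitness in the current environment, so
        filtering also acts at establishment.  'immigration': only the
        immigration branch is fitness-filtered (establishing from outside
        the host is selective; local reproduction is a plain lottery).
        'neutral': replacement is a plain lottery on both branches —
        local recruits proportional to survivor counts, immigrants
        proportional to the pool weighting — and selection acts through
        mortality alone.
    seed
        Default RNG seed for runs driven by these parameters.
    """

    death_fraction: float = 0.10
    immigration_rate: float = 0.05
    death_floor: float = 0.05
    pool_weighting: str = "abundance"
    recruit_weighting: str = "fitness"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.death_fraction <= 1.0):
            raise ValueError(
                f"death_fraction must be in (0, 1], got {self.death_fraction}"
            )
        if not (0.0 <= self.immigration_rate <= 1.0):
            raise ValueError(
                f"immigration_rate must be in [0, 1], got {self.immigration_rate}"
            )
        if self.death_floor <= 0:
            raise ValueError(f"death_floor must be > 0, got {self.death_floor}")
        if self.pool_weighting not in ("abundance", "uniform"):
            raise ValueError(
                f"pool_weighting must be 'abundance' or 'uniform', "
                f"got {self.pool_weighting!r}"
            )
        if self.recruit_weighting not in ("neutral", "fitness", "immigration"):
            raise ValueError(
                "recruit_weighting must be 'fitness', 'immigration' or "
                f"'neutral', got {self.recruit_weighting!r}"
            )


def _death_weights(fitnesses: np.ndarray, floor: float) -> np.ndarray:
    fmax = fitnesses.max()
    if fmax <= 0:
        raise ValueError("fitnesses must be strictly positive")
    return 1.0 - fitnesses / fmax + floor


def _draw_deaths(
    counts: np.ndarray, weights: np.ndarray, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-species death counts: K weighted draws without replacement.

    Exponential race over individuals: individual i of species s draws
    Exp(1)/w_s and the K smallest keys die.
    """
    J = int(counts.sum())
    present = np.flatnonzero(counts > 0)
    owner = np.repeat(present, counts[present])
    keys = rng.exponential(size=J) / weights[owner]
    dead = owner[np.argpartition(keys, K - 1)[:K]] if K < J else owner
    deaths = np.zeros_like(counts)
    np.add.at(deaths, dead, 1)
    return deaths


def select_deaths(
    community: Community,
    fitnesses: np.ndarray,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> tuple[Community, np.ndarray]:
    """Remove K = round(death_fraction * J) individuals, fitness-weighted.

    ``fitnesses`` is index-aligned with the community table and must be
    strictly positive for every present species.  Individuals within a
    species are exchangeable, so the removed individuals are reported as a
    per-species death-count vector.  Returns (community after deaths,
    deaths per species).
    """
    J = community.size
    K = int(round(params.death_fraction * J))
    if K >= J:
        raise ValueError(
            f"death count K={K} would extinguish the whole community (J={J})"
        )
    fitnesses = np.asarray(fitnesses, dtype=float)
    present = community.counts > 0
    if (fitnesses[present] <= 0).any():
        raise ValueError("fitnesses must be strictly positive for present species")
    if K == 0:
        return community.copy(), np.zeros_like(community.counts)
    fmax = fitnesses[present].max()
    weights = 1.0 - fitnesses / fmax + params.death_floor
    deaths = _draw_deaths(community.counts, weights, K, rng)
    survived = Community(community.ids, community.traits, community.counts - deaths)
    return survived, deaths


def _normalized(weights: np.ndarray, support: np.ndarray, what: str) -> np.ndarray:
    """Normalize recruitment weights, falling back to uniform over the support."""
    total = weights.sum()
    if not np.isfinite(total) or total <= 0.0:
        logger.warning(
            "all %s recruitment weights are numerically zero; "
            "falling back to a uniform draw",
            what,
        )
        out = np.zeros_like(weights)
        out[support] = 1.0 / support.sum()
        return out
    return weights / total


def _align_pool(community: Community, pool: SpeciesPool) -> np.ndarray:
    """Pool relative abundance aligned to the community's species table."""
    index = {sid: i for i, sid in enumerate(community.ids)}
    aligned = np.zeros(len(community.ids))
    for sid, ab in zip(pool.ids, pool.rel_abundance):
        if sid not in index:
            raise ValueError(
                f"pool species {sid!r} is missing from the community table; "
                "align the community to the pool first (initialize_community "
                "keeps all pool species at count >= 0)"
            )
        aligned[index[sid]] = ab
    return aligned


def fill_vacancies(
    community: Community,
    pool: SpeciesPool,
    env: float,
    sel_params: SelectionParams,
    dyn_params: DynamicsParams,
    K: int,
    rng: np.random.Generator,
    fitnesses: np.ndarray | None = None,
) -> Community:
    """Fill K vacancies by local recruitment or pool immigration.

    Each vacancy is filled independently: with probability m the recruit is
    an immigrant drawn from the pool (weighted by pool relative abundance
    under the default pool weighting), otherwise a local recruit drawn
    from survivors with weight proportional to survivor count.  Under
    ``recruit_weighting='fitness'`` both weight vectors are additionally
    multiplied by individual fitness in the current environment, so
    filtering also acts at establishment.  Species absent from the
    community can only enter through the pool branch.

    ``fitnesses``, if given, must be index-aligned with the community table
    (the engine passes the per-generation species fitness cache); otherwise
    fitness is computed here against the post-death community.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if K == 0:
        return community.copy()
    pool_ab = _align_pool(community, pool)
    mode = dyn_params.recruit_weighting
    if mode != "neutral" and fitnesses is None:
        member = community.counts > 0
        fitnesses = species_fitness(
            community.traits, env, community, sel_params, member_mask=member
        )
    fit = np.asarray(fitnesses, dtype=float) if mode != "neutral" else None
    pool_fit = fit if mode in ("fitness", "immigration") else 1.0
    local_fit = fit if mode == "fitness" else 1.0

    n_immigrants = rng.binomial(K, dyn_params.immigration_rate)
    n_local = K - n_immigrants
    counts = community.counts.copy()
    if n_immigrants > 0:
        if dyn_params.pool_weighting == "abundance":
            w_pool = pool_ab * pool_fit
        else:
            w_pool = (pool_ab > 0) * pool_fit
        w_pool = np.where(pool_ab > 0, w_pool, 0.0)
        counts += rng.multinomial(
            n_immigrants, _normalized(w_pool, pool_ab > 0, "pool")
        )
    if n_local > 0:
        w_local = community.counts * local_fit
        counts += rng.multinomial(
            n_local, _normalized(w_local, community.counts > 0, "local")
        )
    return Community(community.ids, community.traits, counts)


def step(
    community: Community,
    pool: SpeciesPool,
    env: float,
    sel_params: SelectionParams,
    dyn_params: DynamicsParams,
    rng: np.random.Generator,
) -> Community:
    """One full lottery generation: fitness-weighted deaths, then refill.

    Fitness is computed once per species against the pre-death community
    and reused for both death and recruitment weights.  J is conserved
    exactly.
    """
    member = community.counts > 0
    fitnesses = species_fitness(
        community.traits, env, community, sel_params, member_mask=member
    )
    survived, deaths = select_deaths(community, fitnesses, dyn_params, rng)
    K = int(deaths.sum())
    return fill_vacancies(
        survived, pool, env, sel_params, dyn_params, K, rng, fitnesses=fitnesses
    )
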