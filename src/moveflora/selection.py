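"""Fitness on a univariate niche axis.

Both the environment and every species' niche optimum live on the same
[0, 1] axis, interpreted as the first principal component of all selective
pressures acting on the microbiota (host-imposed and abiotic together).
Individual fitness has two parts:

* **environmental filtering** — a Gaussian function of the distance between
  a species' trait and the current environmental optimum,
  ``exp(-(trait - env)^2 / (2 sigma_env^2))``;
* **limiting similarity** — a multiplicative penalty ``exp(-c * load)``
  where ``load`` is the abundance-weighted mean Gaussian trait overlap with
  the other individuals in the community (the competition kernel has its
  own width ``sigma_comp``).

With ``comp_strength = 0`` fitness reduces exactly to the environmental
filter.  All conspecifics share one trait, so fitness is a species-level
quantity within a generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pools import Community

__all__ = [
    "SelectionParams",
    "env_fitness",
    "competition_load",
    "individual_fitness",
    "species_fitness",
]


@dataclass(frozen=True)
class SelectionParams:
    """Widths and weights of the two selection components.

    sigma_env
        Width of the Gaussian environmental filter on the trait axis.
    sigma_comp
        Width of the Gaussian competition (trait-overlap) kernel.
    comp_strength
        Weight of the competition load in the multiplicative penalty;
        0 disables limiting similarity entirely.
    """

    sigma_env: float = 0.05
    sigma_comp: float = 0.1
    comp_strength: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_env <= 0:
            raise ValueError(f"sigma_env must be > 0, got {self.sigma_env}")
        if self.sigma_comp <= 0:
            raise ValueError(f"sigma_comp must be > 0, got {self.sigma_comp}")
        if self.comp_strength < 0:
            raise ValueError(f"comp_strength must be >= 0, got {self.comp_strength}")


def env_fitness(trait, env: float, sigma_env: float = 0.05):
    """Gaussian environmental filter, in (0, 1].

    Equals 1 exactly when ``trait == env`` and decays with the squared
    trait-environment distance.  Accepts scalar or array ``trait``.
    """
    if sigma_env <= 0:
        raise ValueError(f"sigma_env must be > 0, got {sigma_env}")
    trait = np.asarray(trait, dtype=float)
    out = np.exp(-((trait - env) ** 2) / (2.0 * sigma_env**2))
    return float(out) if out.ndim == 0 else out


def _overlap_totals(
    traits, community: Community, sigma_comp: float
) -> np.ndarray:
    """Sum over community individuals of the Gaussian overlap with ``traits``."""
    t = np.asarray(traits, dtype=float)[:, None]
    present = community.counts > 0
    ct = community.traits[present][None, :]
    k = np.exp(-((t - ct) ** 2) / (2.0 * sigma_comp**2))
    return k @ community.counts[present]


def competition_load(
    trait: float,
    community: Community,
    sigma_comp: float = 0.1,
    focal_species_id: str | None = None,
) -> float:
    """Abundance-weighted mean trait overlap with the rest of the community.

    The load of a focal individual is the mean Gaussian kernel value
    between its trait and every *other* individual's trait, so it lies in
    [0, 1] and equals 1 when every individual shares one trait.  If the
    focal individual is itself a community member, pass its species id via
    ``focal_species_id`` so it is excluded from its own load; recruits
    arriving from outside are evaluated against all ``J`` residents.
    """
    if sigma_comp <= 0:
        raise ValueError(f"sigma_comp must be > 0, got {sigma_comp}")
    J = community.size
    if J < 1:
        raise ValueError("community must be nonempty")
    total = float(_overlap_totals([trait], community, sigma_comp)[0])
    if focal_species_id is not None:
        idx = np.flatnonzero(community.ids == focal_species_id)
        if idx.size and community.counts[idx[0]] > 0:
            if J == 1:
                return 0.0
            # remove the focal's self-overlap (kernel at distance 0 is 1)
            return (total - 1.0) / (J - 1)
    return total / J


def individual_fitness(
    trait: float,
    env: float,
    community: Community,
    params: SelectionParams,
    focal_species_id: str | None = None,
) -> float:
    """Fitness of one individual: environmental filter times competition penalty."""
    f_env = env_fitness(trait, env, params.sigma_env)
    if params.comp_strength == 0:
        return float(f_env)
    load = competition_load(trait, community, params.sigma_comp, focal_species_id)
    return float(f_env * np.exp(-params.comp_strength * load))


def species_fitness(
    traits: np.ndarray,
    env: float,
    community: Community,
    params: SelectionParams,
    member_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized fitness for many candidate traits against one community.

    ``member_mask`` marks traits whose species is a current community member
    (index-aligned with ``traits`` *and* the community table); members have
    one individual (themselves) excluded from their own competition load.
    Used by the dynamics engine, which computes fitness once per species per
    generation and reuses it for death and recruitment weights.
    """
    f_env = env_fitness(traits, env, params.sigma_env)
    if params.comp_strength == 0:
        return np.asarray(f_env, dtype=float)
    J = community.size
    totals = _overlap_totals(traits, community, params.sigma_comp)
    load = totals / J
    if member_mask is not None and J > 1:
        member = member_mask & (community.counts > 0)
        load = np.where(member, (totals - 1.0) / (J - 1), load)
    return f_env * np.exp(-params.comp_strength * load)
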