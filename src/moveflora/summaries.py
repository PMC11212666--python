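"""Community summary statistics and phase-level diagnostics.

Per generation the simulator tracks species richness, Bray-Curtis
dissimilarity to the initial (generation-0) community, functional
diversity, the abundance-weighted mean trait, and consecutive-generation
Bray-Curtis turnover.  Functional diversity is Rao's quadratic entropy
with the absolute trait difference as the distance — the abundance-weighted
mean pairwise trait distance on the univariate niche axis.

Phase-level diagnostics aggregate these series by migration cycle and
phase label and compute an *acclimation index*: the ratio of mean
per-generation turnover in the first migration cycles to that in the last
cycles.  An index above 1 means early cycles were more turbulent than late
ones — the transition from an acclimation phase to an equilibrated,
movement-adjusted microbiota.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pools import Community
from .scenarios import EnvironmentSchedule

__all__ = [
    "richness",
    "bray_curtis",
    "functional_diversity",
    "mean_trait",
    "classify_abundant",
    "phase_metrics",
    "acclimation_index",
    "PhaseMetrics",
    "ABUNDANT_THRESHOLD",
]

# abundant taxa: mean relative abundance strictly greater than 0.1%
ABUNDANT_THRESHOLD = 0.001


def richness(community: Community) -> int:
    """Number of species with count > 0."""
    return community.richness


def bray_curtis(c1: Community, c2: Community) -> float:
    """Bray-Curtis dissimilarity between two communities on raw counts.

    ``1 - 2 * sum_s min(n1_s, n2_s) / (J1 + J2)`` over the union of
    species; 0 for identical count vectors, 1 for disjoint species sets.
    """
    if c1.size < 1 or c2.size < 1:
        raise ValueError("both communities must be nonempty")
    n1 = {sid: int(n) for sid, n in zip(c1.ids, c1.counts) if n > 0}
    n2 = {sid: int(n) for sid, n in zip(c2.ids, c2.counts) if n > 0}
    shared = sum(min(n1[s], n2[s]) for s in n1.keys() & n2.keys())
    return 1.0 - 2.0 * shared / (c1.size + c2.size)


def _bray_curtis_aligned(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis on index-aligned count vectors (engine fast path)."""
    return 1.0 - 2.0 * np.minimum(x, y).sum() / (x.sum() + y.sum())


def functional_diversity(community: Community) -> float:
    """Rao's quadratic entropy on the trait axis.

    ``sum_s sum_t p_s p_t |trait_s - trait_t|`` over present species —
    zero for a monodominant community, and invariant to species labels.
    Computed via the sorted-trait identity
    ``2 * sum_k (t_(k+1) - t_(k)) F_k (1 - F_k)`` where ``F`` is the
    cumulative abundance in trait order.
    """
    present = community.counts > 0
    p = community.counts[present] / community.size
    t = community.traits[present]
    if len(t) <= 1:
        return 0.0
    order = np.argsort(t)
    t, p = t[order], p[order]
    cum = np.cumsum(p)[:-1]
    return float(2.0 * np.sum(np.diff(t) * cum * (1.0 - cum)))


def mean_trait(community: Community) -> float:
    """Abundance-weighted mean trait of the community."""
    return float(community.counts @ community.traits / community.size)


def classify_abundant(
    communities: Sequence[Community], threshold: float = ABUNDANT_THRESHOLD
) -> pd.DataFrame:
    """Partition species into abundant vs rare taxa across a run.

    A species is *abundant* when its mean relative abundance across all
    generations is strictly greater than ``threshold`` (default 0.1%);
    every other species ever observed is *rare*.  Returns a table with
    columns ``species_id, mean_rel_abundance, abundant``.
    """
    if len(communities) == 0:
        raise ValueError("need at least one generation of communities")
    sums: dict[str, float] = {}
    n = len(communities)
    for com in communities:
        p = com.counts / com.size
        for sid, rel in zip(com.ids, p):
            if rel > 0:
                sums[sid] = sums.get(sid, 0.0) + float(rel)
    ids = sorted(sums)
    means = np.array([sums[s] / n for s in ids])
    return pd.DataFrame(
        {
            "species_id": ids,
            "mean_rel_abundance": means,
            "abundant": means > threshold,
        }
    )


@dataclass
class PhaseMetrics:
    """Per-cycle, per-phase aggregate table plus the acclimation index."""

    table: pd.DataFrame
    acclimation_index: float


def acclimation_index(
    summary: pd.DataFrame, schedule: EnvironmentSchedule, k: int = 2
) -> float:
    """Ratio of mean turnover in the first k cycles to the last k cycles.

    Values above 1 indicate elevated early-cycle turnover (acclimation)
    relative to late cycles (equilibration).  NaN, with a warning, when the
    late-cycle turnover is zero (e.g. a constant community).
    """
    if len(summary) != len(schedule):
        raise ValueError("summary and schedule lengths differ")
    cycles = schedule.cycle
    turnover = np.asarray(summary["turnover"], dtype=float)
    labels = np.unique(cycles[cycles > 0])
    if len(labels) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} cycles for an acclimation index with k={k}, "
            f"got {len(labels)}"
        )
    early = np.isin(cycles, labels[:k])
    late = np.isin(cycles, labels[-k:])
    early_mean = np.nanmean(turnover[early])
    late_mean = np.nanmean(turnover[late])
    if late_mean == 0.0:
        warnings.warn(
            "late-cycle turnover is zero; acclimation index undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(early_mean / late_mean)


def phase_metrics(
    summary: pd.DataFrame, schedule: EnvironmentSchedule, k: int = 2
) -> PhaseMetrics:
    """Aggregate summary statistics by migration cycle and phase.

    ``summary`` is a per-generation table as produced by
    :func:`moveflora.simulate.run_simulation` (columns ``richness``,
    ``bray_curtis_to_initial``, ``functional_diversity``, ``mean_trait``,
    ``turnover``).  Returns mean values per (cycle, phase) plus the
    acclimation index over the run.
    """
    if len(summary) != len(schedule):
        raise ValueError(
            f"summary ({len(summary)} rows) and schedule ({len(schedule)} "
            "generations) lengths differ"
        )
    df = summary.copy()
    df["cycle"] = schedule.cycle
    df["phase"] = schedule.phase
    stats = ["richness", "bray_curtis_to_initial", "functional_diversity",
             "mean_trait", "turnover"]
    table = (
        df.groupby(["cycle", "phase"], sort=True)[stats]
        .mean()
        .reset_index()
    )
    cycles = np.unique(schedule.cycle[schedule.cycle > 0])
    if len(cycles) >= 2 * k:
        idx = acclimation_index(summary, schedule, k=k)
    else:
        idx = float("nan")
    return PhaseMetrics(table=table, acclimation_index=idx)
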