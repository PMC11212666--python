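"""Per-generation environment schedules for host movement scenarios.

The host's environment is a single scalar optimum on the [0, 1] niche axis.
A simulated host either makes a one-off relocation (*irregular* movement:
origin -> movement corridor -> destination, then residency) or cycles
repeatedly between origin and destination through the movement corridor
(*regular* movement, e.g. seasonal migration).

Selection optima default to the origin at 0.3 and the destination at 0.4
(relatively similar habitats, e.g. two coastal regions) with the movement
corridor at 0.7 (e.g. the open ocean between them).  Transitions are
gradual: the first and last 10% of each movement leg ramp linearly between
the bounding optima and the corridor value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "EnvironmentSchedule",
    "make_irregular_schedule",
    "make_regular_schedule",
    "make_schedule",
]

PHASES = (
    "origin",
    "movement",
    "destination",
    "residency_origin",
    "residency_destination",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Movement-scenario geometry.

    movement_type
        'irregular' (one-off dispersal) or 'regular' (cyclical migration).
    env_origin, env_destination, env_movement
        Selection optima of the three environments on the [0, 1] axis.
    ramp_fraction
        Fraction of each movement leg spent ramping linearly into and out
        of the corridor optimum (applied to both ends).
    gens_burnin, gens_movement, gens_residency
        Generations spent in the pre-movement origin, each movement leg,
        and each residency block.
    n_cycles
        Number of out-and-back migration cycles (regular only).
    """

    movement_type: str = "irregular"
    env_origin: float = 0.3
    env_destination: float = 0.4
    env_movement: float = 0.7
    ramp_fraction: float = 0.10
    gens_burnin: int = 200
    gens_movement: int = 100
    gens_residency: int = 100
    n_cycles: int = 10

    def __post_init__(self) -> None:
        problems = []
        if self.movement_type not in ("regular", "irregular"):
            problems.append(f"movement_type must be regular|irregular, got {self.movement_type!r}")
        for name in ("env_origin", "env_destination", "env_movement"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.ramp_fraction < 0.5):
            problems.append(f"ramp_fraction must lie in (0, 0.5), got {self.ramp_fraction}")
        for name in ("gens_burnin", "gens_movement", "gens_residency"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_cycles < 1:
            problems.append(f"n_cycles must be >= 1, got {self.n_cycles}")
        if problems:
            raise ValueError("invalid scenario config: " + "; ".join(problems))


@dataclass
class EnvironmentSchedule:
    """Environmental optimum, phase label, and cycle index per generation.

    ``cycle`` is 0 during burn-in and counts migration cycles from 1
    (for irregular scenarios everything after burn-in is cycle 1).
    Generations are 0-based internally and 1-based in exported tables.
    """

    env: np.ndarray
    phase: np.ndarray
    cycle: np.ndarray

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        self.cycle = np.asarray(self.cycle, dtype=int)
        if not (len(self.env) == len(self.phase) == len(self.cycle)):
            raise ValueError("env, phase and cycle must have equal length")
        unknown = set(self.phase) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.env)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(1, len(self) + 1),
                "phase": self.phase,
                "cycle": self.cycle,
                "env": self.env,
            }
        )

    def to_csv(self, path, delimiter: str = "\t") -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(["generation", "phase", "cycle", "env"])
            for g, (p, c, e) in enumerate(zip(self.phase, self.cycle, self.env), 1):
                writer.writerow([g, p, c, repr(float(e))])


def _movement_leg(start: float, corridor: float, end: float, gens: int, ramp_fraction: float) -> np.ndarray:
    """One movement leg: ramp start->corridor, plateau, ramp corridor->end.

    Ramps are endpoint-inclusive over the first and last
    ``round(ramp_fraction * gens)`` generations, which makes the reversed
    leg (end, corridor, start) the exact time-reverse of this one.
    """
    r = int(round(ramp_fraction * gens))
    env = np.full(gens, corridor, dtype=float)
    if r >= 1:
        env[:r] = np.linspace(start, corridor, r)
        env[gens - r:] = np.linspace(corridor, end, r)
    return env


def make_irregular_schedule(cfg: ScenarioConfig) -> EnvironmentSchedule:
    """Schedule for one-off dispersal: origin, movement corridor, destination.

    Burn-in at the origin optimum; one movement block whose first and last
    ``ramp_fraction`` of generations linearly interpolate origin->corridor
    and corridor->destination; then residency at the destination optimum.
    """
    if cfg.movement_type != "irregular":
        raise ValueError("cfg.movement_type must be 'irregular'")
    leg = _movement_leg(
        cfg.env_origin, cfg.env_movement, cfg.env_destination,
        cfg.gens_movement, cfg.ramp_fraction,
    )
    env = np.concatenate(
        [
            np.full(cfg.gens_burnin, cfg.env_origin),
            leg,
            np.full(cfg.gens_residency, cfg.env_destination),
        ]
    )
    phase = np.concatenate(
        [
            np.full(cfg.gens_burnin, "origin", dtype=object),
            np.full(cfg.gens_movement, "movement", dtype=object),
            np.full(cfg.gens_residency, "destination", dtype=object),
        ]
    )
    cycle = np.concatenate(
        [
            np.zeros(cfg.gens_burnin, dtype=int),
            np.ones(cfg.gens_movement + cfg.gens_residency, dtype=int),
        ]
    )
    return EnvironmentSchedule(env, phase, cycle)


def make_regular_schedule(cfg: ScenarioConfig) -> EnvironmentSchedule:
    """Schedule for cyclical migration between origin and destination.

    Burn-in at the origin, then ``n_cycles`` repeats of: outbound movement
    leg (origin -> corridor -> destination), residency at the destination,
    return leg (destination -> corridor -> origin), residency at the
    origin.  Each leg ramps exactly as in the irregular scenario.
    """
    if cfg.movement_type != "regular":
        raise ValueError("cfg.movement_type must be 'regular'")
    out_leg = _movement_leg(
        cfg.env_origin, cfg.env_movement, cfg.env_destination,
        cfg.gens_movement, cfg.ramp_fraction,
    )
    back_leg = _movement_leg(
        cfg.env_destination, cfg.env_movement, cfg.env_origin,
        cfg.gens_movement, cfg.ramp_fraction,
    )
    env_parts = [np.full(cfg.gens_burnin, cfg.env_origin)]
    phase_parts = [np.full(cfg.gens_burnin, "origin", dtype=object)]
    cycle_parts = [np.zeros(cfg.gens_burnin, dtype=int)]
    for c in range(1, cfg.n_cycles + 1):
        env_parts += [
            out_leg,
            np.full(cfg.gens_residency, cfg.env_destination),
            back_leg,
            np.full(cfg.gens_residency, cfg.env_origin),
        ]
        phase_parts += [
            np.full(cfg.gens_movement, "movement", dtype=object),
            np.full(cfg.gens_residency, "residency_destination", dtype=object),
            np.full(cfg.gens_movement, "movement", dtype=object),
            np.full(cfg.gens_residency, "residency_origin", dtype=object),
        ]
        cycle_parts.append(
            np.full(2 * (cfg.gens_movement + cfg.gens_residency), c, dtype=int)
        )
    return EnvironmentSchedule(
        np.concatenate(env_parts),
        np.concatenate(phase_parts),
        np.concatenate(cycle_parts),
    )


def make_schedule(cfg: ScenarioConfig) -> EnvironmentSchedule:
    """Dispatch on ``cfg.movement_type``."""
    if cfg.movement_type == "regular":
        return make_regular_schedule(cfg)
    return make_irregular_schedule(cfg)
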