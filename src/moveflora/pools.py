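"""Species pools and communities.

A *species pool* is the environmental source community from which a host
microbiota draws immigrants: a list of species, each with a relative
abundance and a position on a univariate niche axis (its "trait", the
environment in which it is fittest).  A *community* is the host microbiota
itself — an integer number of individuals per species, with a fixed total
size ``J`` that never changes over a simulation.

Pools may be read from delimited text files (columns
``species_id,abundance[,trait]``) or generated synthetically.  The synthetic
generator stands in for species lists derived from environmental water
samples: lognormal relative abundances (the canonical shape of microbial
species-abundance distributions) and uniform traits on [0, 1].  Pool
*richness* is the experimental knob — it encodes how much of the
environmental "microbial soup" the host surface is exposed to.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Species",
    "SpeciesPool",
    "Community",
    "build_synthetic_pool",
    "read_pool",
    "write_pool",
    "initialize_community",
]

_ABUNDANCE_TOL = 1e-9


class PoolFormatError(ValueError):
    """A pool table violates the expected format (rows are 1-based)."""


@dataclass(frozen=True)
class Species:
    """One microbial species: an opaque id and a niche trait in [0, 1]."""

    id: str
    trait: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.trait <= 1.0):
            raise ValueError(
                f"trait must lie in [0, 1], got {self.trait!r} for species {self.id!r}"
            )


def _validate_ids_traits(ids: np.ndarray, traits: np.ndarray) -> None:
    if ids.shape != traits.shape or ids.ndim != 1:
        raise ValueError("ids and traits must be 1-D arrays of equal length")
    if len(np.unique(ids)) != len(ids):
        seen: set[str] = set()
        for sid in ids:
            if sid in seen:
                raise ValueError(f"duplicate species id {sid!r}")
            seen.add(sid)
    if traits.size and (traits.min() < 0.0 or traits.max() > 1.0):
        bad = traits[(traits < 0.0) | (traits > 1.0)][0]
        raise ValueError(f"trait values must lie in [0, 1], got {bad}")


@dataclass
class SpeciesPool:
    """An environmental source community.

    Parameters
    ----------
    ids
        Unique species labels.
    traits
        Niche-axis position per species, each in [0, 1].
    rel_abundance
        Nonnegative weights; renormalized to sum to 1 on construction.
    """

    ids: np.ndarray
    traits: np.ndarray
    rel_abundance: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.traits = np.asarray(self.traits, dtype=float)
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        _validate_ids_traits(self.ids, self.traits)
        if self.rel_abundance.shape != self.ids.shape:
            raise ValueError("rel_abundance must match ids in length")
        if self.rel_abundance.size == 0:
            raise ValueError("pool must contain at least one species")
        if (self.rel_abundance < 0).any():
            raise ValueError("relative abundances must be >= 0")
        total = self.rel_abundance.sum()
        if total <= 0:
            raise ValueError("relative abundances must not all be zero")
        if abs(total - 1.0) > _ABUNDANCE_TOL:
            self.rel_abundance = self.rel_abundance / total

    @property
    def richness(self) -> int:
        return len(self.ids)

    @property
    def species(self) -> list[Species]:
        return [Species(str(i), float(t)) for i, t in zip(self.ids, self.traits)]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class Community:
    """A host microbiota: individual counts per species at one generation.

    Species with zero counts may be retained for alignment with a pool;
    they do not contribute to richness or any summary statistic.
    """

    ids: np.ndarray
    traits: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.traits = np.asarray(self.traits, dtype=float)
        self.counts = np.asarray(self.counts)
        _validate_ids_traits(self.ids, self.traits)
        if self.counts.shape != self.ids.shape:
            raise ValueError("counts must match ids in length")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if self.counts.sum() <= 0:
            raise ValueError("community must contain at least one individual")

    @property
    def size(self) -> int:
        """Total number of individuals J."""
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        return int((self.counts > 0).sum())

    def rel_abundance(self) -> np.ndarray:
        return self.counts / self.size

    def copy(self) -> "Community":
        return Community(self.ids.copy(), self.traits.copy(), self.counts.copy())


def build_synthetic_pool(
    richness: int,
    abundance_shape: float = 1.0,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "sp",
) -> SpeciesPool:
    """Generate a synthetic environmental species pool.

    Emulates a species list derived from an environmental water sample:
    relative abundances follow a lognormal species-abundance distribution
    with shape parameter ``abundance_shape`` (the lognormal sigma; larger
    values give more uneven pools) and traits are uniform on [0, 1].

    Deterministic given ``seed``.
    """
    if richness < 1:
        raise ValueError(f"richness must be >= 1, got {richness}")
    if abundance_shape <= 0:
        raise ValueError(f"abundance_shape must be > 0, got {abundance_shape}")
    rng = np.random.default_rng(seed)
    traits = rng.uniform(0.0, 1.0, size=richness)
    raw = rng.lognormal(mean=0.0, sigma=abundance_shape, size=richness)
    ids = np.array([f"{id_prefix}{i:05d}" for i in range(richness)], dtype=object)
    return SpeciesPool(ids=ids, traits=traits, rel_abundance=raw / raw.sum())


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_pool(path, seed: int | None = None) -> SpeciesPool:
    """Read a species pool from a delimited text file.

    The file must have a header with columns ``species_id`` and
    ``abundance``; a ``trait`` column is optional.  Comma or tab delimiting
    is sniffed from the header line.  Abundances are renormalized to sum
    to 1.  If the trait column is absent (or blank for some rows), traits
    are assigned uniformly at random only when ``seed`` is given; otherwise
    this is an error.  Row numbers in error messages are 1-based and count
    the header as row 1.
    """
    with open(path, "r", newline="") as fh:
        text = fh.read()
    first_line = text.splitlines()[0] if text else ""
    delim = _sniff_delimiter(first_line)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    fields = [f.strip() for f in (reader.fieldnames or [])]
    for required in ("species_id", "abundance"):
        if required not in fields:
            raise PoolFormatError(
                f"{path}: missing required column {required!r} (found {fields})"
            )
    has_trait = "trait" in fields

    ids: list[str] = []
    abundances: list[float] = []
    traits: list[float | None] = []
    seen: set[str] = set()
    for rownum, row in enumerate(reader, start=2):
        sid = (row.get("species_id") or "").strip()
        if not sid:
            raise PoolFormatError(f"{path}: row {rownum}: empty species_id")
        if sid in seen:
            raise PoolFormatError(f"{path}: row {rownum}: duplicate species_id {sid!r}")
        seen.add(sid)
        try:
            ab = float(row["abundance"])
        except (TypeError, ValueError):
            raise PoolFormatError(
                f"{path}: row {rownum}: abundance {row.get('abundance')!r} is not numeric"
            ) from None
        if ab < 0:
            raise PoolFormatError(f"{path}: row {rownum}: negative abundance {ab}")
        tr: float | None = None
        if has_trait:
            raw_tr = (row.get("trait") or "").strip()
            if raw_tr:
                try:
                    tr = float(raw_tr)
                except ValueError:
                    raise PoolFormatError(
                        f"{path}: row {rownum}: trait {raw_tr!r} is not numeric"
                    ) from None
                if not (0.0 <= tr <= 1.0):
                    raise PoolFormatError(
                        f"{path}: row {rownum}: trait {tr} outside [0, 1]"
                    )
        ids.append(sid)
        abundances.append(ab)
        traits.append(tr)

    if not ids:
        raise PoolFormatError(f"{path}: pool file contains no species rows")

    missing = [i for i, t in enumerate(traits) if t is None]
    if missing:
        if seed is None:
            raise PoolFormatError(
                f"{path}: {len(missing)} rows lack a trait value and no seed was "
                "supplied for random trait assignment"
            )
        rng = np.random.default_rng(seed)
        drawn = rng.uniform(0.0, 1.0, size=len(missing))
        for i, t in zip(missing, drawn):
            traits[i] = float(t)

    return SpeciesPool(
        ids=np.array(ids, dtype=object),
        traits=np.array([float(t) for t in traits]),
        rel_abundance=np.array(abundances, dtype=float),
    )


def write_pool(pool: SpeciesPool, path, delimiter: str = ",") -> None:
    """Write a pool as delimited text with columns species_id,abundance,trait."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["species_id", "abundance", "trait"])
        for sid, ab, tr in zip(pool.ids, pool.rel_abundance, pool.traits):
            writer.writerow([sid, repr(float(ab)), repr(float(tr))])


def initialize_community(
    pool: SpeciesPool, J: int, seed: int | np.random.Generator = 0
) -> Community:
    """Draw an initial community of ``J`` individuals from a pool.

    Individuals are drawn by multinomial sampling with probabilities equal
    to the pool's relative abundances; all pool species are retained in the
    community table (possibly at count zero) so that community and pool
    stay index-aligned.  Deterministic given ``seed``.
    """
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    if len(pool) == 0:
        raise ValueError("cannot initialize a community from an empty pool")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(J, pool.rel_abundance)
    return Community(ids=pool.ids.copy(), traits=pool.traits.copy(), counts=counts)
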