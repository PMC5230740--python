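"""Shared record types and the seed-splitting rule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry.base import BaseGeometry

#: introduction outcome statuses
STATUS_ESTABLISHED = 1
STATUS_BREEDING = 2
STATUS_UNSUCCESSFUL = 3
STATUS_DIED_OUT = 4
STATUS_EXTIRPATED = 5
STATUS_UNKNOWN = 6
VALID_STATUSES = frozenset(range(1, 7))
#: statuses with a known outcome, used for the dated analysis set
KNOWN_OUTCOME_STATUSES = frozenset(range(1, 6))

PROVENANCE_INTRODUCTION = "introduction"
PROVENANCE_NATURAL = "natural_colonisation"
PROVENANCE_CONSERVATION = "conservation_translocation"


@dataclass
class IntroductionRecord:
    """First record of one species in one country unit."""

    species_id: str
    family_id: str
    country_id: str
    year: int | None
    status: int
    provenance: str = PROVENANCE_INTRODUCTION


@dataclass
class CountryUnit:
    country_id: str
    name: str = ""
    is_former_british_colony: bool = False
    gdp_1900: float | None = None
    gdp_2000: float | None = None

    def __post_init__(self):
        for v in (self.gdp_1900, self.gdp_2000):
            if v is not None and v <= 0:
                raise ValueError("GDP values must be positive when present")


@dataclass
class RangeMap:
    """A species' geometry for one role, with the date of the mapped state.

    Either an explicit set of grid cell ids or a shapely geometry (in
    geographic lon/lat by default; ``crs='behrmann'`` marks already-projected
    coordinates in km).
    """

    species_id: str
    role: str  # native | introduction | established
    cells: frozenset[int] | None = None
    geometry: BaseGeometry | None = None
    date: int | None = None
    crs: str = "lonlat"

    def __post_init__(self):
        if self.role not in ("native", "introduction", "established"):
            raise ValueError(f"unknown range role {self.role!r}")
        if self.cells is None and self.geometry is None:
            raise ValueError("range must carry either cells or geometry")
        if self.cells is not None:
            self.cells = frozenset(int(c) for c in self.cells)


# stage indices for deriving independent sub-streams from the global seed
_STAGES = {
    "world": 0,
    "introductions": 1,
    "ranges": 2,
    "nulls": 3,
    "family": 4,
    "realm": 5,
    "moran": 6,
    "selection": 7,
    "ports": 8,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator: SeedSequence(seed, stage index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))
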