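"""Specimen records: a foliar profile plus the local growth factors.

Each observed tree ("specimen") carries the categorical features that
define its Humboldtian locus — clone, soil type, location — together
with age, the yield proxy DBH (stem diameter at breast height, cm), and
the 11-nutrient foliar profile.  The compositional views (closed
composition, clr coordinates) are derived lazily and cached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .composition import (
    ClrVector,
    Composition,
    NutrientProfile,
    clr_transform,
    close_composition,
)

__all__ = ["Specimen", "FactorSpec"]


@dataclass
class Specimen:
    id: str
    profile: NutrientProfile
    clone: str = ""
    soil_type: str = ""
    location: str = ""
    age_yr: float = 1.0
    dbh_cm: float = 1.0
    kappa: float = 1000.0
    _composition: Composition | None = field(default=None, repr=False, compare=False)
    _clr: ClrVector | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.age_yr <= 0:
            raise ValueError(f"specimen {self.id}: age must be positive")
        if self.dbh_cm <= 0:
            raise ValueError(f"specimen {self.id}: DBH must be positive")

    @property
    def composition(self) -> Composition:
        if self._composition is None:
            self._composition = close_composition(self.profile, kappa=self.kappa)
        return self._composition

    @property
    def clr(self) -> ClrVector:
        if self._clr is None:
            self._clr = clr_transform(self.composition)
        return self._clr

    def factor(self, name: str):
        """A factor value by field name (clone, soil_type, location, age_yr ...)."""
        return getattr(self, name)


@dataclass(frozen=True)
class FactorSpec:
    """Which features must match between a query and its candidate neighbors.

    ``exact`` lists categorical fields requiring equality; ``windows``
    maps numeric fields to half-width tolerances (e.g. ``{"age_yr": 0.1}``
    keeps candidates within +-0.1 year of the query).  An empty spec
    matches every candidate (no factor restriction).
    """

    exact: tuple[str, ...] = ("clone",)
    windows: Mapping[str, float] = field(default_factory=lambda: {"age_yr": 0.1})

    def __post_init__(self) -> None:
        for name, tol in self.windows.items():
            if tol < 0:
                raise ValueError(f"negative tolerance for {name}")

    def matches(self, query: Specimen, candidate: Specimen) -> bool:
        for name in self.exact:
            if query.factor(name) != candidate.factor(name):
                return False
        for name, tol in self.windows.items():
            if abs(float(query.factor(name)) - float(candidate.factor(name))) > tol:
                return False
        return True
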