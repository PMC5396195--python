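"""Domain types and unit conventions.

Units are fixed package-wide: residue concentrations in ng/g pollen (ppb),
honey bee LD50 values in µg/bee, application rates in kg product/ha, grid
coordinates and cell sizes in meters.  All unit conversion is confined to
:func:`pollenrisk.hazard.pct_of_ld50`; everything else works in these raw
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as _date
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "PesticideClass",
    "Route",
    "CompoundTox",
    "ResidueRecord",
    "SprayEvent",
    "PollenSample",
    "LandCoverClass",
    "LandCoverGrid",
    "ExposureParams",
    "RegulatoryThresholds",
    "round_half_up",
]


class PesticideClass(str, Enum):
    INSECTICIDE = "insecticide"
    FUNGICIDE = "fungicide"
    HERBICIDE = "herbicide"


class Route(str, Enum):
    """Exposure route; contact and oral LD50 values are distinct."""

    CONTACT = "contact"
    ORAL = "oral"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of reported tables).

    Python's built-in ``round`` rounds ties to even, which disagrees with
    hand-rounded published tables at exact .x5 values.
    """
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompoundTox:
    """One pesticide's identity, class, and route-specific honey bee LD50s.

    Missing LD50 values are ``None`` (never 0 or inf); downstream hazard
    operations must skip-and-flag the affected route.
    """

    name: str
    pclass: PesticideClass
    contact_ld50: Optional[float] = None
    oral_ld50: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")
        object.__setattr__(self, "pclass", PesticideClass(self.pclass))
        for route, v in (("contact", self.contact_ld50), ("oral", self.oral_ld50)):
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"{self.name}: {route} LD50 must be strictly positive, got {v!r}"
                )

    def ld50(self, route: Route | str) -> Optional[float]:
        route = Route(route)
        return self.contact_ld50 if route is Route.CONTACT else self.oral_ld50


@dataclass(frozen=True)
class ResidueRecord:
    """One compound's concentration in one site's pooled beebread.

    ``detected`` must equal ``concentration >= lod``; non-detects carry
    concentration 0.  Use :meth:`from_measurement` to apply the below-LOD
    coercion rule to raw laboratory values.
    """

    site_id: str
    compound: str
    concentration: float  # ng/g (ppb)
    lod: float  # ng/g (ppb)
    detected: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(
                f"{self.site_id}/{self.compound}: concentration must be finite "
                f"and >= 0, got {self.concentration!r}"
            )
        if not (math.isfinite(self.lod) and self.lod > 0):
            raise ValueError(f"{self.site_id}/{self.compound}: LOD must be > 0")
        if self.detected != (self.concentration >= self.lod):
            raise ValueError(
                f"{self.site_id}/{self.compound}: detected flag inconsistent with "
                f"concentration {self.concentration} vs LOD {self.lod}"
            )
        if not self.detected and self.concentration != 0:
            raise ValueError(
                f"{self.site_id}/{self.compound}: non-detect must carry "
                f"concentration 0"
            )

    @classmethod
    def from_measurement(
        cls, site_id: str, compound: str, concentration: float, lod: float
    ) -> "ResidueRecord":
        """Build a record from a raw measurement, coercing below-LOD to 0."""
        if concentration < 0:
            raise ValueError(
                f"{site_id}/{compound}: negative concentration {concentration}"
            )
        detected = concentration >= lod
        return cls(site_id, compound, concentration if detected else 0.0, lod, detected)


@dataclass(frozen=True)
class SprayEvent:
    """One pesticide application at one site (the use-index numerator).

    ``during_bloom`` is an explicit flag, never inferred from the date:
    bloom windows differ between sites.
    """

    site_id: str
    compound: str
    date: _date
    pct_ai: float  # percent active ingredient, 0-100 scale
    app_rate: float  # kg product per hectare
    during_bloom: bool

    def __post_init__(self) -> None:
        if not (0 < self.pct_ai <= 100):
            raise ValueError(
                f"{self.site_id}/{self.compound}: pct_ai must be in (0, 100], "
                f"got {self.pct_ai!r}"
            )
        if not (math.isfinite(self.app_rate) and self.app_rate > 0):
            raise ValueError(
                f"{self.site_id}/{self.compound}: app_rate must be > 0"
            )


@dataclass(frozen=True)
class PollenSample:
    """Morphotype grain counts for one site's pooled beebread slide."""

    site_id: str
    counts: Mapping[str, int]
    total_counted: int

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        object.__setattr__(self, "counts", counts)
        if any(c < 0 or c != int(c) for c in counts.values()):
            raise ValueError(f"{self.site_id}: counts must be non-negative integers")
        if sum(counts.values()) != self.total_counted:
            raise ValueError(
                f"{self.site_id}: counts sum to {sum(counts.values())}, "
                f"declared total_counted {self.total_counted}"
            )

    @classmethod
    def from_counts(cls, site_id: str, counts: Mapping[str, int]) -> "PollenSample":
        return cls(site_id, dict(counts), int(sum(counts.values())))


@dataclass(frozen=True)
class LandCoverClass:
    name: str
    group: str  # one of {"natural", "agricultural", "apple", "other"}

    def __post_init__(self) -> None:
        if self.group not in {"natural", "agricultural", "apple", "other"}:
            raise ValueError(f"unknown land-cover group {self.group!r}")


@dataclass
class LandCoverGrid:
    """Categorical raster with integer class codes on a square-cell grid.

    ``codes`` is a 2-D int array stored with the FIRST row at the TOP of the
    map (ESRI ASCII convention); ``xll``/``yll`` locate the lower-left corner
    in meters.  Every code present in the grid (other than ``nodata``) must
    have an entry in ``class_map``.
    """

    codes: np.ndarray
    cell_size: float  # meters
    xll: float
    yll: float
    class_map: Mapping[int, LandCoverClass]
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2:
            raise ValueError("grid codes must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        present = set(np.unique(self.codes).tolist()) - {self.nodata}
        unknown = sorted(present - set(self.class_map))
        if unknown:
            raise ValueError(f"grid contains unmapped class codes: {unknown}")

    @property
    def nrows(self) -> int:
        return self.codes.shape[0]

    @property
    def ncols(self) -> int:
        return self.codes.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of a cell center; row 0 is the top row."""
        x = self.xll + (col + 0.5) * self.cell_size
        y = self.yll + (self.nrows - 1 - row + 0.5) * self.cell_size
        return x, y


@dataclass(frozen=True)
class ExposureParams:
    """Assumptions converting a raw hazard quotient to percent of LD50.

    Defaults: a 100 mg adult bee contacting a body-weight equivalent of
    pollen (acute contact), and chronic oral ingestion of 9.4 mg pollen/day
    over a 10-day crop bloom period.
    """

    bee_mass_mg: float = 100.0
    contact_mass_mg: float = 100.0
    oral_rate_mg_per_day: float = 9.4
    duration_days: float = 10.0

    def __post_init__(self) -> None:
        for name in ("bee_mass_mg", "contact_mass_mg", "oral_rate_mg_per_day", "duration_days"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class RegulatoryThresholds:
    """Regulatory exposure/toxicity levels of concern, as fractions of LD50.

    EPA Tier 1 acute-contact risk quotient 0.4; EFSA acute-contact ETR 0.2;
    EFSA chronic-oral (10-day) ETR 0.03.
    """

    epa_acute_contact_rq: float = 0.4
    efsa_acute_contact_etr: float = 0.2
    efsa_chronic_oral_etr: float = 0.03

    def __post_init__(self) -> None:
        for name in ("epa_acute_contact_rq", "efsa_acute_contact_etr", "efsa_chronic_oral_etr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
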