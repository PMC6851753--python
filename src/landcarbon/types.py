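"""Core in-memory containers shared by every stage of the simulation.

The landscape is a regular grid of square cells, each carrying categorical
state (ecoregion, county, ownership, land-use/land-cover class) and the
continuous per-cell state the annual loop updates (age, time-since-transition,
spatial multipliers).  Climate is held per ecoregion as monthly series plus
annual aggregates and an atmospheric CO2 trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

#: Canonical land-use / land-cover classes.
STATE_CLASSES: tuple[str, ...] = (
    "water",
    "wetland",
    "snow_ice",
    "barren",
    "forest",
    "grassland",
    "shrubland",
    "annual_crop",
    "perennial_crop",
    "developed",
    "transportation",
)

CLASS_CODE: dict[str, int] = {name: i for i, name in enumerate(STATE_CLASSES)}

#: Classes for which stand age and time-since-transition are tracked.
AGE_TRACKED_CLASSES: frozenset[str] = frozenset(
    {"forest", "grassland", "shrubland", "annual_crop", "perennial_crop"}
)

#: Classes whose carbon counts toward total ecosystem carbon (TEC).  Carbon in
#: cells converted to any other class is frozen in the "transferred" pool.
ECOSYSTEM_CLASSES: frozenset[str] = frozenset(
    {"forest", "grassland", "shrubland", "annual_crop", "perennial_crop"}
)

#: Classes a wildfire can burn through.
BURNABLE_CLASSES: frozenset[str] = frozenset({"forest", "grassland", "shrubland"})

OWNERSHIPS: tuple[str, ...] = ("federal", "nonfederal", "private")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ContractError(RuntimeError):
    """Raised when an internal contract (eligibility, mass balance) is broken."""


def class_codes(names: Iterable[str]) -> np.ndarray:
    return np.array([CLASS_CODE[n] for n in names], dtype=np.int64)


@dataclass
class LandscapeGrid:
    """A regular grid of simulation cells (struct-of-arrays layout).

    All per-cell arrays are indexed by ``cell_id`` = ``row * n_cols + col``.
    ``state_class`` stores integer codes into :data:`STATE_CLASSES`.
    """

    n_rows: int
    n_cols: int
    cell_area: float  # km^2 per cell
    ecoregion: np.ndarray  # int
    county: np.ndarray  # int
    ownership: np.ndarray  # int codes into OWNERSHIPS
    state_class: np.ndarray  # int codes into STATE_CLASSES
    age: np.ndarray  # years, int
    tst: np.ndarray  # years since last transition, int
    protected: np.ndarray  # bool
    npp_multiplier: np.ndarray  # dimensionless, mean 1 per (ecoregion, class)
    fire_rel_prob: np.ndarray  # dimensionless >= 0
    drought_rel_prob: np.ndarray  # dimensionless >= 0

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def ecoregions(self) -> np.ndarray:
        return np.unique(self.ecoregion)

    @property
    def counties(self) -> np.ndarray:
        return np.unique(self.county)

    def class_mask(self, *names: str) -> np.ndarray:
        codes = class_codes(names)
        return np.isin(self.state_class, codes)

    def class_names(self) -> np.ndarray:
        return np.asarray(STATE_CLASSES, dtype=object)[self.state_class]

    def age_tracked_mask(self) -> np.ndarray:
        return self.class_mask(*sorted(AGE_TRACKED_CLASSES))

    def neighbors8(self, cell_id: int) -> np.ndarray:
        """Cell ids of the 8-connected neighbours of ``cell_id``."""
        r, c = divmod(int(cell_id), self.n_cols)
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                    out.append(rr * self.n_cols + cc)
        return np.asarray(out, dtype=np.int64)

    def copy(self) -> "LandscapeGrid":
        return replace(
            self,
            ecoregion=self.ecoregion.copy(),
            county=self.county.copy(),
            ownership=self.ownership.copy(),
            state_class=self.state_class.copy(),
            age=self.age.copy(),
            tst=self.tst.copy(),
            protected=self.protected.copy(),
            npp_multiplier=self.npp_multiplier.copy(),
            fire_rel_prob=self.fire_rel_prob.copy(),
            drought_rel_prob=self.drought_rel_prob.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "row": np.arange(self.n_cells) // self.n_cols,
                "col": np.arange(self.n_cells) % self.n_cols,
                "ecoregion": self.ecoregion,
                "county": self.county,
                "ownership": np.asarray(OWNERSHIPS, dtype=object)[self.ownership],
                "state_class": self.class_names(),
                "age": self.age,
                "tst": self.tst,
                "cell_area": self.cell_area,
                "protected": self.protected,
                "npp_multiplier": self.npp_multiplier,
                "fire_rel_prob": self.fire_rel_prob,
                "drought_rel_prob": self.drought_rel_prob,
            }
        )


@dataclass
class ClimateSeries:
    """Monthly climate per ecoregion plus an annual CO2 trajectory.

    ``monthly_temp``/``monthly_precip`` have shape ``(n_regions, n_years, 12)``;
    annual aggregates are derived (mean for temperature, sum for
    precipitation).  ``ca`` is the atmospheric CO2 concentration (ppm) for one
    forcing pathway, indexed like ``years``.
    """

    regions: np.ndarray  # ecoregion ids
    years: np.ndarray  # calendar years
    monthly_temp: np.ndarray  # degC, (n_regions, n_years, 12)
    monthly_precip: np.ndarray  # mm,   (n_regions, n_years, 12)
    ca: np.ndarray  # ppm, (n_years,)
    ca_baseline: float  # ppm at the simulation start year
    pathway: str = "low"
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.monthly_precip.min() < 0:
            raise ValidationError("precipitation must be non-negative")

    @property
    def annual_temp(self) -> np.ndarray:
        """Mean annual temperature, shape (n_regions, n_years)."""
        return self.monthly_temp.mean(axis=2)

    @property
    def annual_precip(self) -> np.ndarray:
        """Annual precipitation total, shape (n_regions, n_years)."""
        return self.monthly_precip.sum(axis=2)

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise ValidationError(f"year {year} outside climate series")
        return int(idx[0])

    def region_index(self, region: int) -> int:
        idx = np.flatnonzero(self.regions == region)
        if idx.size == 0:
            raise ValidationError(f"unknown ecoregion {region}")
        return int(idx[0])

    def ca_at(self, year: int) -> float:
        return float(self.ca[self.year_index(year)])
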