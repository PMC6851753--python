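"""Climate-driven disturbance submodels: wildfire events and drought mortality.

Wildfire is simulated as discrete events per ecoregion-year: events are drawn
until the cumulative burned area reaches an exogenous annual burn-area target,
with event origins weighted by a relative-probability layer, sizes drawn from
an empirical size distribution, spread by greedy annexation of the
highest-weight 8-connected neighbour, and per-cell severity drawn from an
empirical severity-class distribution.

Drought-induced tree mortality is driven by a 60-month Standardized
Precipitation-Evapotranspiration Index (SPEI): the climatic balance P - PET
(PET by Thornthwaite's temperature-only method) is summed over a rolling
60-month window and standardized against a calibration period.  A binomial
GLM (logit link) per mortality-severity class maps SPEI to an expected
mortality fraction; annual mortality area is then drawn from a Gaussian with
a 50% standard deviation, truncated to [0, eligible area].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import truncnorm

from .types import (
    BURNABLE_CLASSES,
    ContractError,
    LandscapeGrid,
    ValidationError,
    class_codes,
)

__all__ = [
    "FireRegime",
    "FireEvent",
    "DroughtModel",
    "thornthwaite_pet",
    "compute_spei",
    "fit_drought_glm",
    "sample_mortality_area",
    "simulate_fire_year",
]

MORTALITY_CLASSES = ("low", "medium", "high")
_DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class FireRegime:
    """Per-ecoregion fire regime: burn-area targets and event distributions."""

    ecoregion: int
    annual_target_area: dict[int, float]  # km^2 by simulation year
    size_distribution: np.ndarray  # empirical event sizes, km^2 (> 0)
    severity_distribution: dict[str, float]  # proportions over low/medium/high
    rel_prob_field: str = "fire_rel_prob"

    def __post_init__(self) -> None:
        self.size_distribution = np.asarray(self.size_distribution, dtype=float)
        if self.size_distribution.size and self.size_distribution.min() <= 0:
            raise ValidationError("fire sizes must be > 0")
        tot = sum(self.severity_distribution.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValidationError(f"severity proportions sum to {tot}, not 1")


@dataclass
class FireEvent:
    year: int
    ecoregion: int
    origin_cell: int
    burned_cells: np.ndarray
    severity: dict[int, str]  # per burned cell


@dataclass
class DroughtModel:
    """SPEI-to-mortality model: one logit-scale (intercept, slope) per class."""

    glm_coeffs: dict[str, tuple[float, float]]
    spei_window: int = 60
    area_sd_fraction: float = 0.5
    class_labels: tuple[str, ...] = MORTALITY_CLASSES

    def predicted_fraction(self, spei: float) -> dict[str, float]:
        return {
            cls: float(expit(b0 + b1 * spei)) for cls, (b0, b1) in self.glm_coeffs.items()
        }


def _daylight_hours(latitude: float) -> np.ndarray:
    """Mean daylight hours per calendar month at a latitude (degrees)."""
    lat = np.deg2rad(latitude)
    # solar declination at mid-month (day-of-year approximation)
    doy = np.cumsum(_DAYS_IN_MONTH) - _DAYS_IN_MONTH / 2
    decl = 0.409 * np.sin(2 * np.pi * doy / 365.25 - 1.39)
    x = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    sunset_angle = np.arccos(x)
    return 24.0 / np.pi * sunset_angle


def thornthwaite_pet(monthly_temp: np.ndarray, latitude: float = 37.0) -> np.ndarray:
    """Potential evapotranspiration (mm/month) by Thornthwaite's method.

    ``monthly_temp`` is a flat monthly series starting in January; each
    calendar year uses its own annual heat index.  Months at or below 0 degC
    contribute zero PET.
    """
    t = np.asarray(monthly_temp, dtype=float)
    if t.size % 12 != 0:
        raise ValidationError("monthly series must cover whole years (multiple of 12)")
    n_years = t.size // 12
    tm = t.reshape(n_years, 12)
    tpos = np.maximum(tm, 0.0)
    heat_index = ((tpos / 5.0) ** 1.514).sum(axis=1)  # annual heat index I
    heat_index = np.maximum(heat_index, 1e-6)
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    daylight = _daylight_hours(latitude)
    corr = (daylight / 12.0) * (_DAYS_IN_MONTH / 30.0)
    pet = 16.0 * (10.0 * tpos / heat_index[:, None]) ** a[:, None] * corr[None, :]
    pet[tm <= 0] = 0.0
    return pet.reshape(-1)


def compute_spei(
    monthly_precip: np.ndarray,
    monthly_temp: np.ndarray,
    latitude: float = 37.0,
    window: int = 60,
    calibration: slice | None = None,
) -> np.ndarray:
    """Rolling-window SPEI from flat monthly precipitation/temperature series.

    The climatic balance D = P - PET is summed over a trailing ``window``
    months and standardized to zero mean, unit variance over the calibration
    months (all valid months by default).  The first ``window - 1`` entries
    are NaN.
    """
    p = np.asarray(monthly_precip, dtype=float)
    t = np.asarray(monthly_temp, dtype=float)
    if p.shape != t.shape:
        raise ValidationError("precip and temp series must have equal length")
    if window <= 0:
        raise ValidationError("window must be positive")
    if p.size < window:
        raise ValidationError(f"series length {p.size} shorter than window {window}")
    d = p - thornthwaite_pet(t, latitude)
    csum = np.concatenate([[0.0], np.cumsum(d)])
    rolled = csum[window:] - csum[:-window]
    out = np.full(p.size, np.nan)
    out[window - 1 :] = rolled
    valid = out[window - 1 :]
    calib = valid if calibration is None else out[calibration][~np.isnan(out[calibration])]
    mu, sd = calib.mean(), calib.std(ddof=0)
    if sd == 0:
        raise ValidationError("climatic balance has zero variance; SPEI undefined")
    out[window - 1 :] = (valid - mu) / sd
    return out


def annual_spei(spei_monthly: np.ndarray, years: np.ndarray) -> pd.Series:
    """December SPEI value per calendar year (the annual drought tracker)."""
    n_years = spei_monthly.size // 12
    vals = spei_monthly.reshape(n_years, 12)[:, -1]
    return pd.Series(vals, index=np.asarray(years)[:n_years])


def fit_drought_glm(
    spei: np.ndarray,
    mortality_fraction: np.ndarray,
    weights: np.ndarray | None = None,
    cap: float = 25.0,
) -> tuple[float, float]:
    """Fit logit(mortality fraction) ~ SPEI by binomial maximum likelihood.

    Returns ``(intercept, slope)``.  Under (quasi-)perfect separation the
    coefficients are capped at ``|cap|`` with a warning rather than diverging.
    """
    spei = np.asarray(spei, dtype=float)
    y = np.asarray(mortality_fraction, dtype=float)
    if np.unique(spei).size < 3:
        raise ValidationError("need >= 3 distinct SPEI values to fit the GLM")
    exog = sm.add_constant(spei)
    kwargs = {"var_weights": np.asarray(weights, dtype=float)} if weights is not None else {}
    model = sm.GLM(y, exog, family=sm.families.Binomial(), **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(tol=1e-8)
            b0, b1 = float(res.params[0]), float(res.params[1])
        except Exception:  # perfect separation and kin
            b0, b1 = np.nan, np.nan
    if not np.isfinite(b0) or not np.isfinite(b1) or max(abs(b0), abs(b1)) > cap:
        warnings.warn("possible separation in drought GLM; coefficients capped", stacklevel=2)
        b0 = float(np.clip(np.nan_to_num(b0, nan=0.0), -cap, cap))
        b1 = float(np.clip(np.nan_to_num(b1, nan=0.0), -cap, cap))
    return b0, b1


def sample_mortality_area(
    model: DroughtModel,
    spei: float,
    eligible_area: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw annual mortality area (km^2) per severity class.

    The mean is the GLM-predicted fraction times the eligible area; the draw
    is Gaussian with standard deviation 50% of the mean, truncated to
    [0, eligible_area].
    """
    if eligible_area < 0:
        raise ValidationError("eligible_area must be >= 0")
    out: dict[str, float] = {}
    for cls, frac in model.predicted_fraction(spei).items():
        mean = frac * eligible_area
        if mean <= 0 or eligible_area <= 0:
            out[cls] = 0.0
            continue
        sd = model.area_sd_fraction * mean
        a, b = (0.0 - mean) / sd, (eligible_area - mean) / sd
        out[cls] = float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    return out


def _spread_fire(
    grid: LandscapeGrid,
    origin: int,
    size_km2: float,
    burnable: np.ndarray,
    burned_global: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow an event from ``origin`` by annexing the highest-weight neighbour."""
    n_target_cells = max(int(np.ceil(size_km2 / grid.cell_area)), 1)
    eco = grid.ecoregion[origin]
    in_event = {int(origin)}
    frontier: set[int] = set()

    def add_frontier(cid: int) -> None:
        for nb in grid.neighbors8(cid):
            nb = int(nb)
            if (
                nb not in in_event
                and burnable[nb]
                and not burned_global[nb]
                and grid.ecoregion[nb] == eco
            ):
                frontier.add(nb)

    add_frontier(int(origin))
    while len(in_event) < n_target_cells and frontier:
        cand = np.fromiter(frontier, dtype=np.int64)
        w = weights[cand]
        best = cand[w == w.max()]
        chosen = int(best[rng.integers(best.size)]) if best.size > 1 else int(best[0])
        frontier.discard(chosen)
        in_event.add(chosen)
        add_frontier(chosen)
    return np.array(sorted(in_event), dtype=np.int64)


def simulate_fire_year(
    grid: LandscapeGrid,
    regime: FireRegime,
    year: int,
    rng: np.random.Generator,
) -> tuple[list[FireEvent], float]:
    """Simulate one ecoregion-year of discrete fire events.

    Events accumulate until burned area meets the annual target (the last
    event may overshoot by less than one drawn size).  Returns the events and
    any shortfall (burnable area exhausted before the target was met).
    """
    target = float(regime.annual_target_area.get(int(year), 0.0))
    if target < 0:
        raise ValidationError("burn-area target must be >= 0")
    events: list[FireEvent] = []
    if target <= 0:
        return events, 0.0

    burnable = grid.class_mask(*sorted(BURNABLE_CLASSES)) & (grid.ecoregion == regime.ecoregion)
    burned = np.zeros(grid.n_cells, dtype=bool)
    weights = getattr(grid, regime.rel_prob_field).astype(float)
    sev_labels = list(regime.severity_distribution)
    sev_p = np.array([regime.severity_distribution[s] for s in sev_labels])

    burned_area = 0.0
    while burned_area < target:
        avail = np.flatnonzero(burnable & ~burned)
        if avail.size == 0:
            return events, target - burned_area
        w = weights[avail]
        p = w / w.sum() if w.sum() > 0 else None
        origin = int(rng.choice(avail, p=p))
        size = float(rng.choice(regime.size_distribution)) if regime.size_distribution.size else grid.cell_area
        cells = _spread_fire(grid, origin, size, burnable, burned, weights, rng)
        burned[cells] = True
        sev_draw = rng.choice(len(sev_labels), size=cells.size, p=sev_p)
        severity = {int(c): sev_labels[s] for c, s in zip(cells, sev_draw)}
        events.append(
            FireEvent(
                year=int(year),
                ecoregion=int(regime.ecoregion),
                origin_cell=origin,
                burned_cells=cells,
                severity=severity,
            )
        )
        burned_area += cells.size * grid.cell_area
    return events, 0.0
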