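"""Synthetic landscape, climate, disturbance-history and carbon-lookup generators.

Everything downstream of this module (the state-and-transition engine, the
disturbance submodels, the stock-flow engine and the scenario driver) consumes
only the containers produced here, so the whole pipeline can be exercised on a
desk-scale world with the statistical structure the real inputs would carry:
stratified landscapes, trended and drought-punctuated climate, cross-correlated
historical transition rates, empirical fire-size/severity distributions and
saturating age-to-carbon curves.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    AGE_TRACKED_CLASSES,
    CLASS_CODE,
    OWNERSHIPS,
    STATE_CLASSES,
    ClimateSeries,
    LandscapeGrid,
    ValidationError,
)

__all__ = [
    "generate_landscape",
    "generate_climate",
    "generate_rate_history",
    "generate_age_carbon_lookup",
]

#: Upper bound of the uniform initial-age draw, by class.
DEFAULT_AGE_MAX = {
    "forest": 200,
    "grassland": 50,
    "shrubland": 80,
    "annual_crop": 30,
    "perennial_crop": 40,
}

CARBON_POOLS = ("live", "standing_dead", "down_dead", "litter", "soil")


def generate_landscape(
    n_rows: int,
    n_cols: int,
    n_ecoregions: int,
    class_mix: Mapping[str, float],
    protected_fraction: float = 0.0,
    seed: int = 0,
    cell_area: float = 1.0,
    counties_per_ecoregion: int = 2,
    multiplier_sd: float = 0.15,
) -> LandscapeGrid:
    """Generate a stratified synthetic landscape.

    Ecoregions are contiguous row-blocks; each ecoregion is split column-wise
    into ``counties_per_ecoregion`` counties.  Land-cover labels are drawn
    i.i.d. from ``class_mix``; initial ages are uniform per class (0-200 years
    for forest); the stationary NPP spatial multiplier is log-normal and
    re-normalised to mean exactly 1 within every (ecoregion, class) group.

    Parameters
    ----------
    class_mix
        Mapping of state-class name to proportion; must sum to 1.
    protected_fraction
        Bernoulli probability that a cell is protected from harvest.
    cell_area
        km^2 per cell (fluxes scale linearly with it).
    """
    if n_rows * n_cols < 1:
        raise ValidationError("grid must contain at least one cell")
    mix_total = float(sum(class_mix.values()))
    if abs(mix_total - 1.0) > 1e-9:
        raise ValidationError(f"class_mix proportions sum to {mix_total}, not 1")
    unknown = set(class_mix) - set(STATE_CLASSES)
    if unknown:
        raise ValidationError(f"unknown state classes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n_cells = n_rows * n_cols
    rows = np.arange(n_cells) // n_cols
    cols = np.arange(n_cells) % n_cols

    # contiguous row-block ecoregions
    ecoregion = np.minimum(rows * n_ecoregions // max(n_rows, 1), n_ecoregions - 1)
    county_within = np.minimum(
        cols * counties_per_ecoregion // max(n_cols, 1), counties_per_ecoregion - 1
    )
    county = ecoregion * counties_per_ecoregion + county_within

    names = list(class_mix)
    probs = np.array([class_mix[n] for n in names], dtype=float)
    drawn = rng.choice(len(names), size=n_cells, p=probs / probs.sum())
    state_class = np.array([CLASS_CODE[names[i]] for i in drawn], dtype=np.int64)

    age = np.zeros(n_cells, dtype=np.int64)
    for name, amax in DEFAULT_AGE_MAX.items():
        mask = state_class == CLASS_CODE[name]
        age[mask] = rng.integers(0, amax + 1, size=int(mask.sum()))

    ownership = rng.integers(0, len(OWNERSHIPS), size=n_cells)
    protected = rng.random(n_cells) < protected_fraction

    npp_multiplier = rng.lognormal(mean=0.0, sigma=multiplier_sd, size=n_cells)
    # renormalise to mean exactly 1 within each (ecoregion, class) group
    for eco in np.unique(ecoregion):
        for code in np.unique(state_class):
            m = (ecoregion == eco) & (state_class == code)
            if m.any():
                npp_multiplier[m] /= npp_multiplier[m].mean()

    fire_rel_prob = rng.lognormal(mean=0.0, sigma=0.4, size=n_cells)
    drought_rel_prob = rng.lognormal(mean=0.0, sigma=0.4, size=n_cells)

    return LandscapeGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_area=float(cell_area),
        ecoregion=ecoregion.astype(np.int64),
        county=county.astype(np.int64),
        ownership=ownership.astype(np.int64),
        state_class=state_class,
        age=age,
        tst=age.copy(),
        protected=protected,
        npp_multiplier=npp_multiplier,
        fire_rel_prob=fire_rel_prob,
        drought_rel_prob=drought_rel_prob,
    )


def _co2_ramp(years: np.ndarray, ca_baseline: float, base_year: int, target_2100: float) -> np.ndarray:
    """Quadratic CO2 ramp anchored at (base_year, ca_baseline) and (2100, target)."""
    t = years - base_year
    span = 2100 - base_year
    initial_slope = 1.5  # ppm/yr, contemporary growth rate
    curv = (target_2100 - ca_baseline - initial_slope * span) / span**2
    ca = ca_baseline + initial_slope * t + curv * t**2
    # before the anchor year hold a gentle linear rise
    return np.where(t < 0, ca_baseline + initial_slope * t, ca)


def generate_climate(
    n_ecoregions: int,
    years: Sequence[int],
    warming_per_century: float = 0.0,
    precip_cv: float = 0.15,
    drought_years: Iterable[int] = (),
    ca_pathway: str = "low",
    seed: int = 0,
    mean_temp: float = 15.0,
    mean_annual_precip: float = 600.0,
    drought_precip_factor: float = 0.4,
    ca_baseline: float = 371.0,
    ca_base_year: int = 2001,
    temp_noise_sd: float = 0.5,
    branch_year: int | None = None,
    baseline_seed: int | None = None,
) -> ClimateSeries:
    """Generate per-ecoregion monthly climate plus a CO2 trajectory.

    Temperature follows a linear warming trend (degC per century, starting at
    ``branch_year`` if given, else at the first year) plus Gaussian interannual
    noise on top of a sinusoidal seasonal cycle.  Annual precipitation is
    log-normal with coefficient of variation ``precip_cv``, spread over months
    with a mediterranean winter-wet profile; years in ``drought_years`` are
    scaled by ``drought_precip_factor``.  CO2 rises along a quadratic ramp to
    ~540 ppm ("low" pathway) or ~930 ppm ("high") at 2100.

    When ``branch_year`` and ``baseline_seed`` are given, all stochastic draws
    for years <= branch_year come from ``baseline_seed`` so that climate
    variants for different futures share a bit-identical historical baseline.
    """
    years = np.asarray(list(years), dtype=np.int64)
    if years.size == 0:
        raise ValidationError("empty year range")
    if precip_cv < 0:
        raise ValidationError("precip_cv must be >= 0")
    if ca_pathway not in ("low", "high"):
        raise ValidationError(f"unknown CO2 pathway {ca_pathway!r}")

    n_years = years.size
    drought_years = set(int(y) for y in drought_years)

    if branch_year is None or baseline_seed is None:
        rngs = [(np.random.default_rng(seed), np.ones(n_years, dtype=bool))]
    else:
        base_mask = years <= branch_year
        rngs = [
            (np.random.default_rng(baseline_seed), base_mask),
            (np.random.default_rng(seed), ~base_mask),
        ]

    temp_anom = np.zeros((n_ecoregions, n_years))
    log_precip_z = np.zeros((n_ecoregions, n_years))
    for rng, mask in rngs:
        k = int(mask.sum())
        if k:
            temp_anom[:, mask] = rng.normal(0.0, temp_noise_sd, size=(n_ecoregions, k))
            log_precip_z[:, mask] = rng.normal(0.0, 1.0, size=(n_ecoregions, k))

    trend_start = branch_year if branch_year is not None else int(years[0])
    trend = warming_per_century * np.maximum(years - trend_start, 0) / 100.0

    # regional baseline offsets: cooler/wetter in the north, deterministic
    region_ids = np.arange(n_ecoregions)
    region_temp_offset = np.linspace(-2.0, 2.0, n_ecoregions) if n_ecoregions > 1 else np.zeros(1)
    region_precip_factor = (
        np.linspace(1.4, 0.6, n_ecoregions) if n_ecoregions > 1 else np.ones(1)
    )

    months = np.arange(12)
    seasonal_temp = 8.0 * np.cos(2 * np.pi * (months - 6.5) / 12.0)  # peak ~July
    # mediterranean precip profile: wet winters, dry summers
    precip_profile = 1.0 + 0.9 * np.cos(2 * np.pi * (months - 0.5) / 12.0)
    precip_profile = precip_profile / precip_profile.sum()

    annual_t = mean_temp + region_temp_offset[:, None] + trend[None, :] + temp_anom
    monthly_temp = annual_t[:, :, None] + seasonal_temp[None, None, :]

    if precip_cv > 0:
        sigma = np.sqrt(np.log1p(precip_cv**2))
        annual_p = mean_annual_precip * np.exp(sigma * log_precip_z - sigma**2 / 2.0)
    else:
        annual_p = np.full((n_ecoregions, n_years), mean_annual_precip)
    annual_p = annual_p * region_precip_factor[:, None]
    dmask = np.isin(years, sorted(drought_years))
    annual_p[:, dmask] *= drought_precip_factor
    monthly_precip = annual_p[:, :, None] * precip_profile[None, None, :]

    target = 540.0 if ca_pathway == "low" else 930.0
    ca = _co2_ramp(years, ca_baseline, ca_base_year, target)

    return ClimateSeries(
        regions=region_ids,
        years=years,
        monthly_temp=monthly_temp,
        monthly_precip=monthly_precip,
        ca=ca,
        ca_baseline=float(ca_baseline),
        pathway=ca_pathway,
    )


def generate_rate_history(
    counties: int,
    groups: Sequence[str],
    n_years: int,
    mean_rates: Mapping[str, float] | pd.DataFrame,
    correlation: np.ndarray | None = None,
    seed: int = 0,
    first_year: int = 1993,
    log_sd: float = 0.5,
) -> pd.DataFrame:
    """Generate a jointly log-normal historical transition-rate table.

    For every (county, historical year) a multivariate-normal vector with the
    requested cross-group ``correlation`` is drawn and exponentiated, so that
    the scenario sampler can preserve covariance between transition types by
    re-drawing whole historical years.  Returns a tidy DataFrame with columns
    ``group, county, year, area_rate`` (km^2/year); all rates >= 0 and their
    expectation equals ``mean_rates``.
    """
    groups = list(groups)
    g = len(groups)
    if correlation is None:
        correlation = np.eye(g)
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (g, g):
        raise ValidationError("correlation shape must match number of groups")
    eigmin = np.linalg.eigvalsh((correlation + correlation.T) / 2).min()
    if eigmin < -1e-10:
        raise ValidationError("correlation matrix is not positive semi-definite")

    if isinstance(mean_rates, pd.DataFrame):
        mean_lookup = {
            (r.group, int(r.county)): float(r.area_rate) for r in mean_rates.itertuples()
        }
    else:
        mean_lookup = {(grp, c): float(mean_rates[grp]) for grp in groups for c in range(counties)}

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(correlation + 1e-12 * np.eye(g))
    years = first_year + np.arange(n_years)

    records = []
    for c in range(counties):
        z = rng.standard_normal(size=(n_years, g)) @ chol.T
        vals = np.exp(log_sd * z - log_sd**2 / 2.0)
        for j, grp in enumerate(groups):
            mu = mean_lookup.get((grp, c), 0.0)
            for i, y in enumerate(years):
                records.append((grp, c, int(y), mu * vals[i, j]))
    return pd.DataFrame(records, columns=["group", "county", "year", "area_rate"])


def generate_age_carbon_lookup(
    ecoregions: int,
    classes: Sequence[str],
    asymptote: float = 6500.0,
    half_age: float = 30.0,
    max_age: int = 300,
    dom_fractions: Mapping[str, float] | None = None,
    soil_fraction: float = 1.0,
    region_gradient: float = 0.15,
) -> pd.DataFrame:
    """Build a saturating age-to-carbon lookup table.

    Live density follows the Michaelis-Menten curve
    ``live(age) = asymptote * age / (age + half_age)`` (Mg C/km^2), so live(0)=0
    and live(half_age)=asymptote/2.  Dead-organic-matter pools are fixed
    fractions of the live asymptote (defaults: standing deadwood 0.10, down
    deadwood 0.13, litter 0.14) and soil is ``soil_fraction`` of it; a mild
    deterministic ecoregion gradient differentiates regions.  Non-woody classes
    use shorter-lived, smaller curves (scaled by class).
    """
    if asymptote <= 0:
        raise ValidationError("asymptote must be > 0")
    # default DOM/soil fractions sit near the steady state of the default
    # annual flow rates, so a mature landscape neither sheds nor hoards
    # carbon artificially at initialization
    dom_fractions = dict(dom_fractions or {"standing_dead": 0.10, "down_dead": 0.13, "litter": 0.14})

    class_scale = {
        "forest": 1.0,
        "shrubland": 0.35,
        "grassland": 0.18,
        "annual_crop": 0.15,
        "perennial_crop": 0.45,
    }
    class_half_age = {
        "forest": half_age,
        "shrubland": half_age / 3,
        "grassland": half_age / 6,
        "annual_crop": 1.0,
        "perennial_crop": half_age / 4,
    }
    ages = np.arange(max_age + 1)
    rows = []
    for eco in range(ecoregions):
        regional = 1.0 + region_gradient * ((eco - (ecoregions - 1) / 2) / max(ecoregions - 1, 1) * 2 if ecoregions > 1 else 0.0)
        for cls in classes:
            a = asymptote * class_scale.get(cls, 0.2) * regional
            h = class_half_age.get(cls, half_age)
            live = a * ages / (ages + h)
            df = pd.DataFrame(
                {
                    "ecoregion": eco,
                    "state_class": cls,
                    "age": ages,
                    "live": live,
                    "standing_dead": dom_fractions["standing_dead"] * a * np.ones_like(live),
                    "down_dead": dom_fractions["down_dead"] * a * np.ones_like(live),
                    "litter": dom_fractions["litter"] * a * np.ones_like(live),
                    "soil": soil_fraction * a * np.ones_like(live),
                }
            )
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
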