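"""Assemble a complete synthetic study world for scenario simulation.

A :class:`SyntheticWorld` bundles everything one simulation needs: the
landscape grid, one climate variant per (climate-model, forcing-pathway)
combination sharing a bit-identical historical baseline, a historical
transition-rate table with cross-type covariance, per-ecoregion fire regimes,
a drought-mortality model with precomputed SPEI series, the age-to-carbon
lookup, and the NPP model referenced to the baseline climate normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthdata
from .carbon import NPPModelParams
from .disturbance import DroughtModel, FireRegime, annual_spei, compute_spei
from .types import BURNABLE_CLASSES, ClimateSeries, LandscapeGrid

__all__ = ["SyntheticWorld", "make_world", "GCM_VARIANTS", "RCP_VARIANTS"]

#: Climate-model variants: (extra warming degC/century, precipitation factor
#: applied to projection years).  Labels follow the usual hot-dry / hot-wet /
#: average / complementary framing of downscaled model ensembles.
GCM_VARIANTS: dict[str, tuple[float, float]] = {
    "hot-dry": (1.5, 0.80),
    "hot-wet": (1.0, 1.20),
    "average": (0.0, 1.00),
    "complement": (0.5, 0.90),
}

#: Forcing pathways: (base warming degC/century, CO2 pathway name).
RCP_VARIANTS: dict[str, tuple[float, str]] = {
    "4.5": (2.0, "low"),
    "8.5": (4.5, "high"),
}

#: Historical transition-rate means, km^2/yr per county.
DEFAULT_MEAN_RATES = {
    "urbanization": 0.30,
    "ag_expansion": 0.20,
    "ag_contraction": 0.15,
    "clear_cut": 0.40,
    "selection": 0.60,
    "orchard_removal": 0.05,
}

RATE_GROUPS = tuple(DEFAULT_MEAN_RATES)

#: Cross-group correlation of historical rates: harvest types covary strongly,
#: agricultural expansion/contraction moderately, the rest are independent.
def default_rate_correlation() -> np.ndarray:
    g = len(RATE_GROUPS)
    corr = np.eye(g)
    idx = {name: i for i, name in enumerate(RATE_GROUPS)}
    corr[idx["clear_cut"], idx["selection"]] = corr[idx["selection"], idx["clear_cut"]] = 0.6
    corr[idx["ag_expansion"], idx["ag_contraction"]] = corr[idx["ag_contraction"], idx["ag_expansion"]] = 0.4
    return corr


def variant_code(gcm: str, rcp: str, land_use: str = "BAU") -> int:
    """Small deterministic integer identifying a scenario variant (seed offsets)."""
    gcms = list(GCM_VARIANTS)
    rcps = list(RCP_VARIANTS)
    land_uses = ["BAU", "low", "medium", "high"]
    return land_uses.index(land_use) * 100 + gcms.index(gcm) * 10 + rcps.index(rcp)


@dataclass
class SyntheticWorld:
    grid: LandscapeGrid
    climate: dict[tuple[str, str], ClimateSeries]  # keyed (gcm, rcp)
    history: pd.DataFrame
    lookup: pd.DataFrame
    fire_regimes: dict[tuple[str, str], dict[int, FireRegime]]
    drought_model: DroughtModel
    spei: dict[tuple[str, str], dict[int, pd.Series]]  # annual SPEI per ecoregion
    npp_params: NPPModelParams
    start_year: int = 2001
    end_year: int = 2100
    baseline_end: int = 2015
    seed: int = 0

    def climate_for(self, gcm: str, rcp: str) -> ClimateSeries:
        return self.climate[(gcm, rcp)]


def make_world(
    seed: int = 0,
    n_rows: int = 20,
    n_cols: int = 20,
    n_ecoregions: int = 3,
    class_mix: dict[str, float] | None = None,
    protected_fraction: float = 0.25,
    gcms: tuple[str, ...] = ("average", "hot-dry"),
    rcps: tuple[str, ...] = ("4.5", "8.5"),
    start_year: int = 2001,
    end_year: int = 2100,
    baseline_end: int = 2015,
    fire_fraction: float = 0.015,
    fire_trend: float = 1.0,
    mean_rates: dict[str, float] | None = None,
    history_years: int = 23,
) -> SyntheticWorld:
    """Build a fully-specified synthetic world.

    ``fire_fraction`` sets the annual ecoregional burn-area target as a
    fraction of burnable area; under the high forcing pathway the target ramps
    up by ``fire_trend`` (x2 by 2100 with the default 1.0).  Climate variants
    share one historical baseline stream so that all scenario pathways branch
    from identical 2001-``baseline_end`` conditions.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(8)]
    class_mix = class_mix or {
        "forest": 0.40,
        "grassland": 0.20,
        "shrubland": 0.20,
        "annual_crop": 0.08,
        "perennial_crop": 0.04,
        "developed": 0.05,
        "barren": 0.03,
    }
    grid = synthdata.generate_landscape(
        n_rows,
        n_cols,
        n_ecoregions,
        class_mix,
        protected_fraction=protected_fraction,
        seed=int(seeds[0]),
    )

    # climate: 5 years of spin-up before start_year so a 60-month SPEI window
    # is full in the first simulation year
    clim_years = range(start_year - 5, end_year + 1)
    drought_years = {2012, 2013, 2014, 2015}
    climate: dict[tuple[str, str], ClimateSeries] = {}
    for gcm, (dwarm, pfac) in GCM_VARIANTS.items():
        if gcm not in gcms:
            continue
        for rcp, (base_warm, pathway) in RCP_VARIANTS.items():
            if rcp not in rcps:
                continue
            clim = synthdata.generate_climate(
                n_ecoregions,
                clim_years,
                warming_per_century=base_warm + dwarm,
                precip_cv=0.25,
                drought_years=drought_years,
                ca_pathway=pathway,
                seed=int(seeds[1]) + variant_code(gcm, rcp),
                branch_year=baseline_end,
                baseline_seed=int(seeds[2]),
            )
            yrs = clim.years > baseline_end
            clim.monthly_precip[:, yrs, :] *= pfac
            clim.label = gcm
            climate[(gcm, rcp)] = clim

    history = synthdata.generate_rate_history(
        counties=len(grid.counties),
        groups=RATE_GROUPS,
        n_years=history_years,
        mean_rates=mean_rates or DEFAULT_MEAN_RATES,
        correlation=default_rate_correlation(),
        seed=int(seeds[3]),
        first_year=1993,
    )
    # era structure in the historical record: agricultural growth 1997-2002
    # (contraction-dominated before), harvest more intense 2002-2009 than
    # 2010-2014 — the eras the land-use scenario sampling windows draw from
    era_factors = {
        "ag_expansion": [((1993, 1996), 0.5), ((1997, 2002), 1.5)],
        "ag_contraction": [((1993, 1996), 1.3), ((1997, 2002), 0.6)],
        "clear_cut": [((2002, 2009), 1.4), ((2010, 2014), 0.6)],
        "selection": [((2002, 2009), 1.4), ((2010, 2014), 0.6)],
    }
    for grp, spans in era_factors.items():
        for (y0, y1), f in spans:
            m = (history["group"] == grp) & history["year"].between(y0, y1)
            history.loc[m, "area_rate"] *= f

    lookup = synthdata.generate_age_carbon_lookup(
        n_ecoregions,
        ["forest", "grassland", "shrubland", "annual_crop", "perennial_crop"],
    )

    # reference climate normals from the shared baseline (identical across variants)
    ref_clim = next(iter(climate.values()))
    base_mask = ref_clim.years <= baseline_end
    ref_temp = {int(r): float(ref_clim.annual_temp[i, base_mask].mean()) for i, r in enumerate(ref_clim.regions)}
    ref_precip = {int(r): float(ref_clim.annual_precip[i, base_mask].mean()) for i, r in enumerate(ref_clim.regions)}
    npp_params = NPPModelParams(ref_temp=ref_temp, ref_precip=ref_precip)

    # fire regimes: empirical size distribution drawn once, burn-area targets
    # per variant with an upward ramp under stronger forcing
    size_rng = np.random.default_rng(int(seeds[4]))
    size_dist = np.exp(size_rng.normal(1.0, 0.7, size=200))
    severity = {"low": 0.5, "medium": 0.3, "high": 0.2}
    burnable = grid.class_mask(*sorted(BURNABLE_CLASSES))
    fire_regimes: dict[tuple[str, str], dict[int, FireRegime]] = {}
    all_years = np.arange(start_year, end_year + 1)
    for (gcm, rcp), clim in climate.items():
        per_eco: dict[int, FireRegime] = {}
        ramp_scale = {"4.5": 0.5, "8.5": 1.0}[rcp] * fire_trend
        for eco in grid.ecoregions:
            base = fire_fraction * float(burnable[grid.ecoregion == eco].sum()) * grid.cell_area
            targets = {}
            for y in all_years:
                ramp = 1.0 + ramp_scale * max(0, int(y) - baseline_end) / (end_year - baseline_end)
                targets[int(y)] = base * (ramp if y > baseline_end else 1.0)
            per_eco[int(eco)] = FireRegime(
                ecoregion=int(eco),
                annual_target_area=targets,
                size_distribution=size_dist,
                severity_distribution=dict(severity),
            )
        fire_regimes[(gcm, rcp)] = per_eco

    drought_model = DroughtModel(
        glm_coeffs={"low": (-4.5, -1.0), "medium": (-5.5, -1.2), "high": (-6.5, -1.5)}
    )

    # precomputed annual SPEI per ecoregion and climate variant
    spei: dict[tuple[str, str], dict[int, pd.Series]] = {}
    for key, clim in climate.items():
        per_region = {}
        for i, r in enumerate(clim.regions):
            monthly = compute_spei(
                clim.monthly_precip[i].reshape(-1),
                clim.monthly_temp[i].reshape(-1),
                window=drought_model.spei_window,
            )
            per_region[int(r)] = annual_spei(monthly, clim.years)
        spei[key] = per_region

    return SyntheticWorld(
        grid=grid,
        climate=climate,
        history=history,
        lookup=lookup,
        fire_regimes=fire_regimes,
        drought_model=drought_model,
        spei=spei,
        npp_params=npp_params,
        start_year=start_year,
        end_year=end_year,
        baseline_end=baseline_end,
        seed=seed,
    )
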