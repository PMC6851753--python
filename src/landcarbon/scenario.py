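"""Scenario orchestration: the annual loop, Monte-Carlo replication and summaries.

One scenario is a (land-use, forcing-pathway, climate-model) combination run
for a number of Monte-Carlo realizations.  Each rep-year: sample land-use
transition targets, simulate wildfire events and drought mortality, step the
landscape, apply the event-triggered carbon flows, apply the automatic flows
with the year's Q10 and CO2-fertilization multipliers, and append a ledger
row.  The baseline period (through ``baseline_end``) consumes the historical
inputs and a seed stream shared by every scenario, so all scenario pathways
carry bit-identical baselines and branch in the first projection year.

Ledger identities, enforced exactly on every row:
``NEP = NPP - Rh`` and ``NECB = NEP - LULCC``; between consecutive years
``dTEC = NECB - (carbon transferred out of ecosystem classes)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .accounting import accounting_necb, accounting_nep, window_mean
from .carbon import (
    CarbonState,
    CFEParams,
    DEFAULT_FLOWS,
    Q10Params,
    TRIGGERED_FLOW_DEFAULTS,
    annual_npp,
    apply_automatic_flows,
    apply_triggered_flows,
    cfe_multiplier,
    initialize_carbon,
)
from .disturbance import MORTALITY_CLASSES, sample_mortality_area, simulate_fire_year
from .stsm import (
    DEFAULT_TRANSITIONS,
    SCENARIO_WINDOWS,
    TransitionEvent,
    TransitionTarget,
    advance_ages,
    sample_targets,
    select_cells,
    step_year,
)
from .types import ValidationError, class_codes
from .world import SyntheticWorld, variant_code

__all__ = [
    "ScenarioConfig",
    "run_scenario",
    "summarize",
    "accounting_nep",
    "accounting_necb",
]

MG_PER_TG = 1e6

LEDGER_COLUMNS = [
    "year",
    "mc_rep",
    "npp",
    "rh",
    "nep",
    "lulcc",
    "necb",
    "tec",
    "live",
    "dom",
    "soil",
    "transfer",
    "atmosphere",
    "aquatic",
    "hwp",
    "ag_products",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: land-use pathway x forcing pathway x climate model."""

    land_use: str = "BAU"
    rcp: str = "4.5"
    gcm: str = "average"
    cfe: CFEParams = field(default_factory=CFEParams)
    q10: Q10Params = field(default_factory=Q10Params)
    n_reps: int = 100
    years: tuple[int, int] = (2001, 2100)
    baseline_end: int = 2015
    seed: int = 0
    transitions_enabled: bool = True
    fire_enabled: bool = True
    drought_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if not (self.years[0] <= self.baseline_end <= self.years[1]):
            raise ValidationError("baseline_end must lie within the simulated years")
        if self.land_use not in SCENARIO_WINDOWS:
            raise ValidationError(f"unknown land-use scenario {self.land_use!r}")

    @property
    def label(self) -> str:
        return f"{self.land_use}_rcp{self.rcp}_{self.gcm}"


def _drought_targets(
    world: SyntheticWorld,
    config: ScenarioConfig,
    grid,
    year: int,
    rng: np.random.Generator,
) -> list[tuple[str, TransitionTarget]]:
    """Per-(ecoregion, severity) drought mortality area targets for one year."""
    out = []
    spei_by_region = world.spei[(config.gcm, config.rcp)]
    forest = grid.class_mask("forest")
    for eco in grid.ecoregions:
        spei_val = float(spei_by_region[int(eco)].get(year, 0.0))
        eligible = float(forest[grid.ecoregion == eco].sum()) * grid.cell_area
        areas = sample_mortality_area(world.drought_model, spei_val, eligible, rng)
        for sev in MORTALITY_CLASSES:
            if areas.get(sev, 0.0) > 0:
                out.append((sev, TransitionTarget("drought_mortality", int(eco), year, areas[sev])))
    return out


def run_scenario(
    world: SyntheticWorld,
    config: ScenarioConfig,
    return_events: bool = False,
    audit_mass_balance: bool = False,
    flows=DEFAULT_FLOWS,
):
    """Run all Monte-Carlo reps of one scenario; returns the annual ledger.

    The ledger has one row per (rep, year) with fluxes in Tg C/yr and stocks
    in Tg C.  ``lulcc`` stores removals as positive values (losses to the
    atmosphere, product pools and aquatic systems from land use, land-use
    change, disturbance, agricultural harvest, biomass background emission
    and leaching); ``transfer`` is cumulative carbon frozen in non-ecosystem
    classes.  With ``return_events`` the per-cell event log is returned too.
    """
    clim = world.climate_for(config.gcm, config.rcp)
    scen_code = variant_code(config.gcm, config.rcp, config.land_use)
    tdefs = DEFAULT_TRANSITIONS
    hist_years = set(world.history["year"].unique())

    rows = []
    all_events: list[TransitionEvent] = []
    carbon0 = initialize_carbon(world.grid, world.lookup)
    for rep in range(config.n_reps):
        # baseline stream shared by every scenario; projection stream branches
        rng_base = np.random.default_rng(np.random.SeedSequence([config.seed, rep]))
        rng_proj = np.random.default_rng(np.random.SeedSequence([config.seed, rep, scen_code]))
        grid = world.grid.copy()
        carbon = carbon0.copy()
        total0 = carbon.total()

        for year in range(config.years[0], config.years[1] + 1):
            in_baseline = year <= config.baseline_end
            rng = rng_base if in_baseline else rng_proj
            yi = clim.year_index(year)
            temp = {int(r): float(clim.annual_temp[i, yi]) for i, r in enumerate(clim.regions)}
            precip = {int(r): float(clim.annual_precip[i, yi]) for i, r in enumerate(clim.regions)}

            # 1. land-use targets
            targets: list[TransitionTarget] = []
            if config.transitions_enabled:
                hist_year = year if (in_baseline and year in hist_years) else None
                targets = sample_targets(
                    world.history, config.land_use, year, rng, historical_year=hist_year
                )

            # 2. disturbances, selected on the pre-transition landscape
            fire_cells: list[tuple[int, str]] = []
            if config.fire_enabled:
                for eco, regime in world.fire_regimes[(config.gcm, config.rcp)].items():
                    events, _short = simulate_fire_year(grid, regime, year, rng)
                    for ev in events:
                        for cid in ev.burned_cells:
                            fire_cells.append((int(cid), ev.severity[int(cid)]))

            drought_cells: list[tuple[int, str]] = []
            if config.drought_enabled:
                claimed = np.zeros(grid.n_cells, dtype=bool)
                for sev, dt in _drought_targets(world, config, grid, year, rng):
                    cells, _short = select_cells(
                        grid, dt, tdefs["drought_mortality"], rng,
                        stratum_field="ecoregion", exclude=claimed,
                    )
                    claimed[cells] = True
                    drought_cells.extend((int(c), sev) for c in cells)

            # 3. step the landscape (applies transitions, advances ages)
            lu_events = step_year(grid, targets, tdefs, rng, year)

            # 4. triggered flows
            trig = {"to_atmosphere": 0.0, "to_products": 0.0, "transferred": 0.0}
            for ev in lu_events:
                tdef = tdefs[ev.transition]
                moved = apply_triggered_flows(
                    carbon, grid, ev.cell_id, tdef.group, to_class=tdef.to_class
                )
                for k in trig:
                    trig[k] += moved[k]
            for group, cells in (("fire", fire_cells), ("drought", drought_cells)):
                for cid, sev in cells:
                    moved = apply_triggered_flows(carbon, grid, cid, group, severity=sev)
                    for k in trig:
                        trig[k] += moved[k]
                    grid.tst[cid] = 0
                    all_events.append(
                        TransitionEvent(year, group, group, int(grid.county[cid]),
                                        int(grid.ecoregion[cid]), cid, grid.cell_area, sev)
                    )
            all_events.extend(lu_events)

            # 5. automatic flows with the year's CFE and Q10 multipliers
            cfe = cfe_multiplier(clim.ca[yi], clim.ca_baseline, config.cfe)
            npp_flux = annual_npp(grid, temp, precip, world.npp_params, cfe=cfe)
            anomalies = {r: temp[r] - world.npp_params.ref_temp.get(r, temp[r]) for r in temp}
            totals = apply_automatic_flows(
                carbon, grid, flows, config.q10,
                temp_anomaly_by_region=anomalies, npp_flux=npp_flux,
            )

            # 6. ledger row (Tg C)
            npp = totals.get("growth", 0.0) / MG_PER_TG
            rh = (totals.get("emission_litter", 0.0) + totals.get("emission_soil", 0.0)) / MG_PER_TG
            lulcc = (
                totals.get("emission_biomass", 0.0)
                + totals.get("leaching", 0.0)
                + totals.get("harvest_grain", 0.0)
                + totals.get("harvest_straw", 0.0)
                + trig["to_atmosphere"]
                + trig["to_products"]
            ) / MG_PER_TG
            nep = accounting_nep(npp, rh)
            necb = accounting_necb(nep, lulcc)
            mass_residual = abs(carbon.total() - total0) / abs(total0) if audit_mass_balance else np.nan
            rows.append(
                {
                    "year": year,
                    "mass_residual": mass_residual,
                    "mc_rep": rep,
                    "npp": npp,
                    "rh": rh,
                    "nep": nep,
                    "lulcc": lulcc,
                    "necb": necb,
                    "tec": carbon.tec(grid) / MG_PER_TG,
                    "live": float(carbon.live.sum()) / MG_PER_TG,
                    "dom": float((carbon.standing_dead + carbon.down_dead + carbon.litter).sum()) / MG_PER_TG,
                    "soil": float(carbon.soil.sum()) / MG_PER_TG,
                    "transfer": carbon.transferred / MG_PER_TG,
                    "atmosphere": carbon.atmosphere / MG_PER_TG,
                    "aquatic": carbon.aquatic / MG_PER_TG,
                    "hwp": carbon.hwp / MG_PER_TG,
                    "ag_products": (carbon.ag_grain + carbon.ag_straw) / MG_PER_TG,
                }
            )

    cols = LEDGER_COLUMNS + (["mass_residual"] if audit_mass_balance else [])
    ledger = pd.DataFrame(rows, columns=cols)
    if return_events:
        from .stsm import events_to_frame

        return ledger, events_to_frame(all_events)
    return ledger


def summarize(
    ledger: pd.DataFrame,
    windows: list[tuple[int, int]] | None = None,
    variables: tuple[str, ...] = ("npp", "rh", "nep", "lulcc", "necb", "tec"),
) -> dict[str, pd.DataFrame]:
    """Monte-Carlo summary: annual mean and 95% percentile band per variable.

    Returns ``{"annual": ..., "windows": ..., "cumulative": ...}``.  The
    annual table carries mean, 2.5th and 97.5th percentiles across reps per
    year; the windows table carries window means of each flux (sum over the
    window divided by flux-years); the cumulative table carries the
    across-rep mean cumulative NECB.
    """
    if ledger.empty:
        raise ValidationError("empty ledger")
    records = []
    for var in variables:
        wide = ledger.pivot_table(index="year", columns="mc_rep", values=var)
        records.append(
            pd.DataFrame(
                {
                    "year": wide.index,
                    "variable": var,
                    "mean": wide.mean(axis=1).to_numpy(),
                    "lower": wide.quantile(0.025, axis=1).to_numpy(),
                    "upper": wide.quantile(0.975, axis=1).to_numpy(),
                }
            )
        )
    annual = pd.concat(records, ignore_index=True)

    win_rows = []
    mean_by_year = ledger.groupby("year").mean(numeric_only=True)
    for window in windows or []:
        for var in variables:
            win_rows.append(
                {
                    "window": f"{window[0]}-{window[1]}",
                    "variable": var,
                    "mean": window_mean(mean_by_year[var], window),
                }
            )
    windows_df = pd.DataFrame(win_rows, columns=["window", "variable", "mean"])

    necb_cum = (
        ledger.pivot_table(index="year", columns="mc_rep", values="necb").cumsum()
    )
    cumulative = pd.DataFrame(
        {
            "year": necb_cum.index,
            "cumulative_necb_mean": necb_cum.mean(axis=1).to_numpy(),
            "cumulative_necb_lower": necb_cum.quantile(0.025, axis=1).to_numpy(),
            "cumulative_necb_upper": necb_cum.quantile(0.975, axis=1).to_numpy(),
        }
    )
    return {"annual": annual, "windows": windows_df, "cumulative": cumulative}
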