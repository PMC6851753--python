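"""Carbon stock-flow (gain-loss) engine.

Every cell carries five carbon pools — live biomass, standing deadwood, down
deadwood, litter and soil — and the model moves carbon between them (and the
global atmosphere, aquatic, harvested-wood-product and agricultural-product
accumulators) through annual *automatic* flows (growth, litterfall, mortality,
deadfall, decay, decomposition, emission, leaching, agricultural harvest) and
event-driven *triggered* flows (harvest, land-use change, fire, drought).

Dead-organic-matter turnover responds to annual temperature through Q10
multipliers (2.0 for down-deadwood decay, litter decomposition and soil
emission; 2.65 for the litter gaseous emission), and growth responds to
atmospheric CO2 through a beta-factor fertilization multiplier that can
saturate at a configurable concentration.

The atmosphere pool is a signed accumulator starting at zero, so the grand
total over all pools is exactly conserved — the mass-balance invariant every
run is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .types import (
    ECOSYSTEM_CLASSES,
    CLASS_CODE,
    ContractError,
    LandscapeGrid,
    ValidationError,
)

__all__ = [
    "CarbonState",
    "FlowPathway",
    "CFEParams",
    "Q10Params",
    "NPPModelParams",
    "DEFAULT_FLOWS",
    "TRIGGERED_FLOW_DEFAULTS",
    "cfe_multiplier",
    "q10_multiplier",
    "annual_npp",
    "apply_automatic_flows",
    "apply_triggered_flows",
    "initialize_carbon",
]

CELL_POOLS = ("live", "standing_dead", "down_dead", "litter", "soil")
GLOBAL_POOLS = ("atmosphere", "aquatic", "hwp", "ag_grain", "ag_straw", "transferred")


@dataclass
class CarbonState:
    """Per-cell carbon pools (Mg C) plus global accumulators (Mg C)."""

    live: np.ndarray
    standing_dead: np.ndarray
    down_dead: np.ndarray
    litter: np.ndarray
    soil: np.ndarray
    atmosphere: float = 0.0  # signed cumulative flux; negative = net uptake
    aquatic: float = 0.0
    hwp: float = 0.0
    ag_grain: float = 0.0
    ag_straw: float = 0.0
    transferred: float = 0.0  # frozen stocks of cells converted out of ecosystems

    def cell_pool(self, name: str) -> np.ndarray:
        if name not in CELL_POOLS:
            raise ValidationError(f"unknown cell pool {name!r}")
        return getattr(self, name)

    def cell_total(self) -> np.ndarray:
        return self.live + self.standing_dead + self.down_dead + self.litter + self.soil

    def total(self) -> float:
        """Grand total over every pool; conserved across all operations."""
        return float(
            self.cell_total().sum()
            + self.atmosphere
            + self.aquatic
            + self.hwp
            + self.ag_grain
            + self.ag_straw
            + self.transferred
        )

    def tec(self, grid: LandscapeGrid) -> float:
        """Total ecosystem carbon: pools summed over ecosystem-class cells."""
        mask = grid.class_mask(*sorted(ECOSYSTEM_CLASSES))
        return float(self.cell_total()[mask].sum())

    def copy(self) -> "CarbonState":
        return replace(
            self,
            live=self.live.copy(),
            standing_dead=self.standing_dead.copy(),
            down_dead=self.down_dead.copy(),
            litter=self.litter.copy(),
            soil=self.soil.copy(),
        )


@dataclass(frozen=True)
class FlowPathway:
    """One automatic flow: a fractional annual rate from one pool to another."""

    name: str
    from_pool: str
    to_pool: str
    base_rate: float  # fraction of the source pool per year
    q10: float | None = None  # temperature sensitivity, if any
    applies_to: frozenset[str] | None = None  # state classes; None = all vegetated

    def __post_init__(self) -> None:
        if self.from_pool == self.to_pool:
            raise ValidationError(f"{self.name}: from and to pools must differ")
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValidationError(f"{self.name}: fractional rate outside [0, 1]")


def _f(names: Sequence[str]) -> frozenset[str]:
    return frozenset(names)


#: Default automatic flows.  Live-pool turnover rates vary by land-cover
#: class; dead-organic-matter and soil rates are common.  Q10 values: 2.0 for
#: down-deadwood decay, litter decomposition and soil emission, 2.65 for the
#: litter gaseous emission.
DEFAULT_FLOWS: tuple[FlowPathway, ...] = (
    # live-pool turnover
    FlowPathway("litterfall", "live", "litter", 0.040, applies_to=_f(["forest"])),
    FlowPathway("litterfall", "live", "litter", 0.060, applies_to=_f(["shrubland"])),
    FlowPathway("litterfall", "live", "litter", 0.250, applies_to=_f(["grassland"])),
    FlowPathway("litterfall", "live", "litter", 0.300, applies_to=_f(["annual_crop"])),
    FlowPathway("litterfall", "live", "litter", 0.100, applies_to=_f(["perennial_crop"])),
    FlowPathway("mortality", "live", "standing_dead", 0.006, applies_to=_f(["forest"])),
    FlowPathway("mortality", "live", "standing_dead", 0.004, applies_to=_f(["shrubland", "perennial_crop"])),
    FlowPathway("emission_biomass", "live", "atmosphere", 0.005),
    # DOM and soil turnover
    FlowPathway("deadfall", "standing_dead", "down_dead", 0.050),
    FlowPathway("decay", "down_dead", "litter", 0.040, q10=2.0),
    FlowPathway("decomposition", "litter", "soil", 0.160, q10=2.0),
    FlowPathway("emission_litter", "litter", "atmosphere", 0.150, q10=2.65),
    FlowPathway("emission_soil", "soil", "atmosphere", 0.022, q10=2.0),
    FlowPathway("leaching", "soil", "aquatic", 0.0008),
    # agricultural harvest
    FlowPathway("harvest_grain", "live", "ag_grain", 0.250, applies_to=_f(["annual_crop"])),
    FlowPathway("harvest_grain", "live", "ag_grain", 0.100, applies_to=_f(["perennial_crop"])),
    FlowPathway("harvest_straw", "live", "ag_straw", 0.180, applies_to=_f(["annual_crop"])),
    FlowPathway("harvest_straw", "live", "ag_straw", 0.050, applies_to=_f(["perennial_crop"])),
)

#: Application order within a year (growth first, then turnover, then harvest).
FLOW_ORDER = (
    "litterfall",
    "mortality",
    "deadfall",
    "decay",
    "decomposition",
    "emission_biomass",
    "emission_litter",
    "emission_soil",
    "leaching",
    "harvest_grain",
    "harvest_straw",
)


@dataclass(frozen=True)
class CFEParams:
    """CO2-fertilization multiplier parameters.

    ``beta`` is the fractional NPP increase per 100 ppm CO2 (e.g. 0.082 means
    +8.2% NPP for +100 ppm).  ``ca_cap`` saturates the effect: concentrations
    above the cap contribute no further increase.
    """

    beta: float = 0.0
    ca_cap: float | None = None
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")


@dataclass(frozen=True)
class Q10Params:
    q10_down_dead: float = 2.0
    q10_litter_decomposition: float = 2.0
    q10_soil_emission: float = 2.0
    q10_litter_emission: float = 2.65

    def __post_init__(self) -> None:
        for v in (
            self.q10_down_dead,
            self.q10_litter_decomposition,
            self.q10_soil_emission,
            self.q10_litter_emission,
        ):
            if v < 1:
                raise ValidationError("Q10 values must be >= 1")


@dataclass
class NPPModelParams:
    """Saturating empirical NPP response to annual temperature and precipitation.

    ``npp(T, P) = max_npp * (1 - exp(-k_p * P)) * logistic((T - t_half)/t_scale)``

    Growth for a cell is the response at the year's climate divided by the
    response at the ecoregion's 30-year reference normals, times the reference
    NPP — so at reference climate each (ecoregion, class) produces exactly its
    base NPP and the absolute functional form cancels out.
    """

    max_npp: Mapping[str, float] = field(
        default_factory=lambda: {
            "forest": 550.0,
            "shrubland": 300.0,
            "grassland": 350.0,
            "annual_crop": 500.0,
            "perennial_crop": 450.0,
        }
    )  # Mg C / km^2 / yr at saturation
    k_p: float = 0.002  # per mm precipitation
    t_half: float = 5.0  # degC at half temperature response
    t_scale: float = 6.0  # degC logistic width
    ref_temp: Mapping[int, float] = field(default_factory=dict)  # per ecoregion
    ref_precip: Mapping[int, float] = field(default_factory=dict)

    def response(self, temp: float | np.ndarray, precip: float | np.ndarray) -> np.ndarray:
        p_resp = 1.0 - np.exp(-self.k_p * np.maximum(np.asarray(precip, dtype=float), 0.0))
        t_resp = 1.0 / (1.0 + np.exp(-(np.asarray(temp, dtype=float) - self.t_half) / self.t_scale))
        return p_resp * t_resp


def cfe_multiplier(ca_year: float, ca_baseline: float, params: CFEParams) -> float:
    """CO2-fertilization NPP multiplier: ``1 + dCa * beta / 100``.

    ``dCa`` is the CO2 rise (ppm) above the baseline, floored at zero and
    capped at ``ca_cap`` when saturation is enabled.
    """
    if ca_year < 0:
        raise ValidationError("ca_year must be >= 0")
    if not params.enabled or params.beta == 0:
        return 1.0
    ca_eff = min(ca_year, params.ca_cap) if params.ca_cap is not None else ca_year
    d_ca = max(ca_eff - ca_baseline, 0.0)
    return 1.0 + d_ca * params.beta / 100.0


def q10_multiplier(t_annual: float | np.ndarray, t_ref: float | np.ndarray, q10: float):
    """Temperature multiplier ``q10 ** ((T - T_ref) / 10)`` for turnover rates."""
    if q10 < 1:
        raise ValidationError("q10 must be >= 1")
    return q10 ** ((np.asarray(t_annual, dtype=float) - np.asarray(t_ref, dtype=float)) / 10.0)


def annual_npp(
    grid: LandscapeGrid,
    temp_by_region: Mapping[int, float],
    precip_by_region: Mapping[int, float],
    params: NPPModelParams,
    cfe: float = 1.0,
) -> np.ndarray:
    """Per-cell annual growth flux (Mg C), atmosphere -> live.

    Base NPP density for each (ecoregion, class) is the class maximum scaled
    by the climate response at the year's regional T and P relative to the
    response at the 30-year reference normals, then scaled by the cell's
    stationary spatial multiplier and the CO2-fertilization multiplier.
    Non-vegetated classes grow nothing.
    """
    npp = np.zeros(grid.n_cells)
    for eco in grid.ecoregions:
        t = float(temp_by_region[int(eco)])
        p = float(precip_by_region[int(eco)])
        t_ref = float(params.ref_temp.get(int(eco), t))
        p_ref = float(params.ref_precip.get(int(eco), p))
        resp = float(params.response(t, p))
        resp_ref = float(params.response(t_ref, p_ref))
        ratio = resp / resp_ref if resp_ref > 0 else 0.0
        for cls, mx in params.max_npp.items():
            mask = (grid.ecoregion == eco) & (grid.state_class == CLASS_CODE[cls])
            if mask.any():
                base = mx * resp_ref  # reference-climate NPP density
                npp[mask] = base * ratio * grid.npp_multiplier[mask]
    return npp * grid.cell_area * cfe


def _q10_for_flow(flow: FlowPathway, q10_params: Q10Params) -> float | None:
    return {
        "decay": q10_params.q10_down_dead,
        "decomposition": q10_params.q10_litter_decomposition,
        "emission_litter": q10_params.q10_litter_emission,
        "emission_soil": q10_params.q10_soil_emission,
    }.get(flow.name)


def apply_automatic_flows(
    carbon: CarbonState,
    grid: LandscapeGrid,
    flows: Sequence[FlowPathway] = DEFAULT_FLOWS,
    q10_params: Q10Params = Q10Params(),
    temp_anomaly_by_region: Mapping[int, float] | None = None,
    npp_flux: np.ndarray | None = None,
) -> dict[str, float]:
    """Apply one year of automatic flows; returns total Mg C moved per flow name.

    Growth (``npp_flux``, atmosphere -> live) is applied first; every
    fractional flow is then computed from the start-of-year value of its
    source pool, with Q10 multipliers (from each ecoregion's annual
    temperature anomaly) applied to the temperature-sensitive flows.  If the
    fractional outflows from a pool would overdraw it they are rescaled
    proportionally, with a warning.  Flows act only on ecosystem-class cells.
    """
    eco_mask = grid.class_mask(*sorted(ECOSYSTEM_CLASSES))
    totals: dict[str, float] = {}

    if npp_flux is not None:
        growth = np.where(eco_mask, npp_flux, 0.0)
        if growth.min() < 0:
            raise ContractError("negative growth flux")
        carbon.live = carbon.live + growth
        carbon.atmosphere -= float(growth.sum())
        totals["growth"] = float(growth.sum())

    # temperature anomaly per cell for Q10 scaling
    dt = np.zeros(grid.n_cells)
    if temp_anomaly_by_region:
        for eco, anom in temp_anomaly_by_region.items():
            dt[grid.ecoregion == eco] = anom

    snapshot = {p: carbon.cell_pool(p).copy() for p in CELL_POOLS}

    # compute all flow amounts from start-of-step source values
    amounts: list[tuple[FlowPathway, np.ndarray]] = []
    for name in FLOW_ORDER:
        for flow in flows:
            if flow.name != name:
                continue
            mask = eco_mask.copy()
            if flow.applies_to is not None:
                mask &= grid.class_mask(*sorted(flow.applies_to))
            rate = np.where(mask, flow.base_rate, 0.0)
            q10 = _q10_for_flow(flow, q10_params)
            if q10 is not None:
                rate = rate * q10_multiplier(dt, 0.0, q10)
            amounts.append((flow, rate * snapshot[flow.from_pool]))

    # cap: never overdraw a source pool within the year
    for pool in CELL_POOLS:
        out = np.zeros(grid.n_cells)
        for flow, amt in amounts:
            if flow.from_pool == pool:
                out += amt
        over = out > snapshot[pool]
        if over.any():
            warnings.warn(
                f"fractional outflows from {pool!r} exceed the pool in "
                f"{int(over.sum())} cells; rescaled",
                stacklevel=2,
            )
            scale = np.ones(grid.n_cells)
            with np.errstate(divide="ignore", invalid="ignore"):
                scale[over] = snapshot[pool][over] / out[over]
            for i, (flow, amt) in enumerate(amounts):
                if flow.from_pool == pool:
                    amounts[i] = (flow, amt * scale)

    for flow, amt in amounts:
        src = carbon.cell_pool(flow.from_pool)
        src -= amt
        moved = float(amt.sum())
        if flow.to_pool in CELL_POOLS:
            dst = carbon.cell_pool(flow.to_pool)
            dst += amt
        else:
            setattr(carbon, flow.to_pool, getattr(carbon, flow.to_pool) + moved)
        totals[flow.name] = totals.get(flow.name, 0.0) + moved

    if min(carbon.cell_pool(p).min() for p in CELL_POOLS) < -1e-9:
        raise ContractError("automatic flows produced a negative pool")
    return totals


#: Triggered-flow fractions per transition group: (from_pool, fraction, to_pool).
#: Severity-dependent groups (fire, drought) key on the event's severity class.
#: Defaults are plausibility choices, exposed in config — not authoritative.
TRIGGERED_FLOW_DEFAULTS: dict[str, list[tuple[str, float, str]]] = {
    "selection": [("live", 0.20, "hwp")],
    "clear_cut": [
        ("live", 0.55, "hwp"),
        ("live", 0.08, "atmosphere"),
        ("live", 0.30, "down_dead"),
        ("litter", 0.10, "atmosphere"),
    ],
    "urbanization": [
        ("live", 0.60, "atmosphere"),
        ("live", 0.10, "hwp"),
        ("standing_dead", 0.50, "atmosphere"),
        ("down_dead", 0.50, "atmosphere"),
        ("litter", 0.50, "atmosphere"),
        ("soil", 0.10, "atmosphere"),
    ],
    "ag_expansion": [
        ("live", 0.70, "atmosphere"),
        ("live", 0.10, "hwp"),
        ("litter", 0.30, "atmosphere"),
        ("soil", 0.05, "atmosphere"),
    ],
    "ag_contraction": [("live", 0.50, "litter")],
    "orchard_removal": [
        ("live", 0.80, "atmosphere"),
        ("litter", 0.30, "atmosphere"),
        ("soil", 0.02, "atmosphere"),
    ],
    "fire:low": [
        ("live", 0.05, "atmosphere"),
        ("live", 0.10, "standing_dead"),
        ("litter", 0.30, "atmosphere"),
        ("down_dead", 0.10, "atmosphere"),
    ],
    "fire:medium": [
        ("live", 0.15, "atmosphere"),
        ("live", 0.30, "standing_dead"),
        ("litter", 0.60, "atmosphere"),
        ("down_dead", 0.30, "atmosphere"),
    ],
    "fire:high": [
        ("live", 0.35, "atmosphere"),
        ("live", 0.50, "standing_dead"),
        ("litter", 0.90, "atmosphere"),
        ("down_dead", 0.50, "atmosphere"),
    ],
    "drought:low": [("live", 0.10, "standing_dead")],
    "drought:medium": [("live", 0.30, "standing_dead")],
    "drought:high": [("live", 0.70, "standing_dead")],
}


def apply_triggered_flows(
    carbon: CarbonState,
    grid: LandscapeGrid,
    cell_id: int,
    group: str,
    severity: str | None = None,
    to_class: str | None = None,
    rules: Mapping[str, list[tuple[str, float, str]]] | None = None,
) -> dict[str, float]:
    """Apply the event-triggered carbon flows for one transitioned cell.

    Fractions of the cell's start-of-event pools move per the group's rule
    list (severity-keyed for fire and drought).  If the cell leaves the
    ecosystem classes (``to_class`` non-ecosystem, e.g. urbanization), its
    remaining stocks are frozen into the global ``transferred`` pool.

    Returns totals: carbon emitted/removed to atmosphere, moved to product
    pools, redistributed between cell pools, and transferred out.
    """
    rules = dict(rules or TRIGGERED_FLOW_DEFAULTS)
    key = f"{group}:{severity}" if f"{group}:{severity}" in rules else group
    if key not in rules:
        raise ValidationError(f"no triggered-flow rule for group {group!r} (severity {severity!r})")
    if not 0 <= cell_id < grid.n_cells:
        raise ValidationError(f"cell {cell_id} outside grid")

    start = {p: float(carbon.cell_pool(p)[cell_id]) for p in CELL_POOLS}
    out = {"to_atmosphere": 0.0, "to_products": 0.0, "internal": 0.0, "transferred": 0.0}

    for from_pool, frac, to_pool in rules[key]:
        amt = frac * start[from_pool]
        if amt == 0:
            continue
        carbon.cell_pool(from_pool)[cell_id] -= amt
        if to_pool in CELL_POOLS:
            carbon.cell_pool(to_pool)[cell_id] += amt
            out["internal"] += amt
        else:
            setattr(carbon, to_pool, getattr(carbon, to_pool) + amt)
            if to_pool == "atmosphere":
                out["to_atmosphere"] += amt
            else:
                out["to_products"] += amt

    if to_class is not None and to_class not in ECOSYSTEM_CLASSES:
        for p in CELL_POOLS:
            arr = carbon.cell_pool(p)
            out["transferred"] += float(arr[cell_id])
            carbon.transferred += float(arr[cell_id])
            arr[cell_id] = 0.0

    if min(carbon.cell_pool(p)[cell_id] for p in CELL_POOLS) < -1e-9:
        raise ContractError("triggered flows produced a negative pool")
    return out


def initialize_carbon(
    grid: LandscapeGrid,
    lookup: pd.DataFrame,
    soil_scaling: np.ndarray | float = 1.0,
    use_spatial_multiplier: bool = True,
) -> CarbonState:
    """Initialize per-cell pools from the age-to-carbon lookup table.

    Live and dead-organic-matter densities come from the (ecoregion, class,
    age) lookup row (age clipped to the table's maximum), scaled by the cell's
    stationary spatial growth multiplier; soil is scaled by ``soil_scaling``
    instead.  Non-ecosystem cells start empty; global pools start at zero.
    """
    pools = {p: np.zeros(grid.n_cells) for p in CELL_POOLS}
    table: dict[tuple[int, str], pd.DataFrame] = {
        (int(e), str(c)): g.set_index("age")
        for (e, c), g in lookup.groupby(["ecoregion", "state_class"], sort=False)
    }
    eco_mask = grid.class_mask(*sorted(ECOSYSTEM_CLASSES))
    names = grid.class_names()
    soil_scaling = np.broadcast_to(np.asarray(soil_scaling, dtype=float), (grid.n_cells,))
    mult = grid.npp_multiplier if use_spatial_multiplier else np.ones(grid.n_cells)

    for cid in np.flatnonzero(eco_mask):
        key = (int(grid.ecoregion[cid]), str(names[cid]))
        if key not in table:
            raise ValidationError(f"age-to-carbon lookup missing entry for {key}")
        sub = table[key]
        age = min(int(grid.age[cid]), int(sub.index.max()))
        row = sub.loc[age]
        for p in ("live", "standing_dead", "down_dead", "litter"):
            pools[p][cid] = float(row[p]) * mult[cid] * grid.cell_area
        pools["soil"][cid] = float(row["soil"]) * soil_scaling[cid] * grid.cell_area
    return CarbonState(**pools)
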