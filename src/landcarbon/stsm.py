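"""Annual cell-based state-and-transition engine.

Each simulation year the engine (1) samples area targets per transition group
and county from a historical rate table — drawing one shared historical-year
index per (county, sampling window) so covariance between transition types is
preserved; (2) selects eligible cells for each target, weighted by a spatial
probability layer and constrained by class, minimum age and protection; and
(3) applies the transitions in a uniformly random order, updating state class,
age and time-since-transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AGE_TRACKED_CLASSES, CLASS_CODE, ContractError, LandscapeGrid, ValidationError

__all__ = [
    "TransitionDefinition",
    "TransitionTarget",
    "TransitionEvent",
    "ScenarioWindows",
    "DEFAULT_TRANSITIONS",
    "SCENARIO_WINDOWS",
    "load_transition_config",
    "sample_targets",
    "select_cells",
    "apply_transition",
    "step_year",
]


@dataclass(frozen=True)
class TransitionDefinition:
    """One transition pathway with its constraints and update rules."""

    name: str
    group: str  # urbanization, ag_expansion, ag_contraction, clear_cut,
    #             selection, orchard_removal, fire, drought
    from_class: str
    to_class: str
    min_age: int | None = None
    age_reset: bool = False
    prob_map: str | None = None  # attribute name of a grid weight layer
    respects_protection: bool = False

    def __post_init__(self) -> None:
        non_class_changing = self.group in ("selection", "fire", "drought", "clear_cut", "orchard_removal")
        if self.from_class == self.to_class and not non_class_changing:
            raise ValidationError(f"{self.name}: from_class == to_class for a class-changing group")


@dataclass(frozen=True)
class TransitionTarget:
    transition: str
    stratum: int  # county id (land-use groups) or ecoregion id (disturbance)
    year: int
    target_area: float  # km^2

    def __post_init__(self) -> None:
        if self.target_area < 0:
            raise ValidationError("target_area must be >= 0")


@dataclass(frozen=True)
class TransitionEvent:
    """One applied transition on one cell (the event-log record)."""

    year: int
    transition: str
    group: str
    county: int
    ecoregion: int
    cell_id: int
    area: float
    severity: str | None = None


#: Default transition pathways.  Minimum harvest ages: 40 (clear-cut),
#: 20 (selection); clear-cut resets stand age, selection does not.
DEFAULT_TRANSITIONS: dict[str, TransitionDefinition] = {
    t.name: t
    for t in [
        TransitionDefinition("urbanization_grass", "urbanization", "grassland", "developed"),
        TransitionDefinition("urbanization_shrub", "urbanization", "shrubland", "developed"),
        TransitionDefinition("urbanization_crop", "urbanization", "annual_crop", "developed"),
        TransitionDefinition("ag_expansion_grass", "ag_expansion", "grassland", "annual_crop", age_reset=True),
        TransitionDefinition("ag_expansion_shrub", "ag_expansion", "shrubland", "annual_crop", age_reset=True),
        TransitionDefinition("ag_contraction", "ag_contraction", "annual_crop", "grassland", age_reset=True),
        TransitionDefinition(
            "clear_cut", "clear_cut", "forest", "forest",
            min_age=40, age_reset=True, respects_protection=True,
        ),
        TransitionDefinition(
            "selection_harvest", "selection", "forest", "forest",
            min_age=20, age_reset=False, respects_protection=True,
        ),
        TransitionDefinition("orchard_removal", "orchard_removal", "perennial_crop", "perennial_crop", age_reset=True),
        TransitionDefinition("fire", "fire", "forest", "forest", prob_map="fire_rel_prob"),
        TransitionDefinition("drought_mortality", "drought", "forest", "forest", prob_map="drought_rel_prob"),
    ]
}

#: Sampling-window category per land-use transition group.  One historical
#: year index is drawn per (county, category) so that covariance between the
#: groups of a category is preserved.
GROUP_CATEGORY = {
    "ag_expansion": "ag",
    "ag_contraction": "ag",
    "clear_cut": "harvest",
    "selection": "harvest",
    "urbanization": "urbanization",
    "orchard_removal": "other",
}


@dataclass(frozen=True)
class ScenarioWindows:
    """Historical-year sampling windows (inclusive) per category, or None = full series."""

    ag: tuple[int, int] | None = None
    harvest: tuple[int, int] | None = None
    urbanization: tuple[int, int] | None = None
    other: tuple[int, int] | None = None
    urbanization_multiplier: float = 1.0

    def window(self, category: str) -> tuple[int, int] | None:
        return getattr(self, category)


#: The four land-use scenarios.  High: agricultural rates from the 1997-2002
#: expansion era and harvest from 2002-2009; low: agriculture 1993-1996 and
#: harvest 2010-2014; BAU and medium sample the full series and differ only in
#: the urbanization source (here a rate multiplier, since the underlying
#: population projections are exogenous).
SCENARIO_WINDOWS: dict[str, ScenarioWindows] = {
    "BAU": ScenarioWindows(urbanization_multiplier=1.0),
    "low": ScenarioWindows(ag=(1993, 1996), harvest=(2010, 2014), urbanization_multiplier=0.6),
    "medium": ScenarioWindows(urbanization_multiplier=0.85),
    "high": ScenarioWindows(ag=(1997, 2002), harvest=(2002, 2009), urbanization_multiplier=1.3),
}


def load_transition_config(
    path: str | None = None,
) -> tuple[dict[str, TransitionDefinition], dict[str, ScenarioWindows]]:
    """Load transition definitions and scenario windows from a YAML config.

    Without ``path``, the bundled default configuration is read (it mirrors
    :data:`DEFAULT_TRANSITIONS` and :data:`SCENARIO_WINDOWS`).
    """
    import yaml
    from importlib import resources

    if path is None:
        text = resources.files("landcarbon.data").joinpath("transitions.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    tdefs = {t["name"]: TransitionDefinition(**t) for t in raw.get("transitions", [])}
    windows = {}
    for scen, spec in raw.get("scenario_windows", {}).items():
        kwargs = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in spec.items()
        }
        windows[scen] = ScenarioWindows(**kwargs)
    return tdefs, windows


def _window_years(history: pd.DataFrame, window: tuple[int, int] | None) -> np.ndarray:
    years = np.unique(history["year"].to_numpy())
    if window is not None:
        years = years[(years >= window[0]) & (years <= window[1])]
    if years.size == 0:
        raise ValidationError(f"sampling window {window} contains no historical years")
    return years


def sample_targets(
    history: pd.DataFrame,
    scenario: str,
    year: int,
    rng: np.random.Generator,
    windows: dict[str, ScenarioWindows] | None = None,
    historical_year: int | None = None,
) -> list[TransitionTarget]:
    """Sample per-county area targets for one simulation year.

    For each county and window category one historical year is drawn uniformly
    (with replacement across simulation years) and *all* transition groups in
    that category adopt that year's rates, preserving their covariance.  If
    ``historical_year`` is given (baseline period), that year's rates are used
    verbatim for every category.
    """
    windows = windows or SCENARIO_WINDOWS
    if scenario not in windows:
        raise ValidationError(f"unknown scenario {scenario!r}")
    sw = windows[scenario]

    targets: list[TransitionTarget] = []
    counties = np.unique(history["county"].to_numpy())
    groups = history["group"].unique()
    categories = sorted({GROUP_CATEGORY.get(g, "other") for g in groups})
    by_cat_years = {c: _window_years(history, sw.window(c)) for c in categories}

    idx = history.set_index(["county", "year", "group"])["area_rate"]
    for county in counties:
        if historical_year is not None:
            chosen = {c: historical_year for c in categories}
        else:
            chosen = {c: int(rng.choice(by_cat_years[c])) for c in categories}
        for group in groups:
            cat = GROUP_CATEGORY.get(group, "other")
            try:
                rate = float(idx.loc[(county, chosen[cat], group)])
            except KeyError:
                continue
            if group == "urbanization" and historical_year is None:
                # scenario-specific urbanization source applies only to
                # projected years; the baseline uses history verbatim
                rate *= sw.urbanization_multiplier
            targets.append(TransitionTarget(group, int(county), int(year), rate))
    return targets


def probabilistic_round(area: float, cell_area: float, rng: np.random.Generator) -> int:
    """Round an area target to whole cells, unbiased in expectation."""
    q = area / cell_area
    n = math.floor(q)
    if rng.random() < (q - n):
        n += 1
    return n


def eligible_mask(
    grid: LandscapeGrid,
    tdef: TransitionDefinition,
    stratum: int | None = None,
    stratum_field: str = "county",
) -> np.ndarray:
    mask = grid.state_class == CLASS_CODE[tdef.from_class]
    if tdef.min_age is not None:
        mask &= grid.age >= tdef.min_age
    if tdef.respects_protection:
        mask &= ~grid.protected
    if stratum is not None:
        mask &= getattr(grid, stratum_field) == stratum
    return mask


def select_cells(
    grid: LandscapeGrid,
    target: TransitionTarget,
    tdef: TransitionDefinition,
    rng: np.random.Generator,
    stratum_field: str = "county",
    exclude: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Select cells for a transition target, without replacement.

    Returns ``(cell_ids, shortfall_km2)``.  Selection probability is
    proportional to the transition's weight layer among eligible cells; the
    target is rounded to whole cells by probabilistic rounding so the expected
    selected area is unbiased.  A shortfall (eligible area < target) is
    reported, not raised.
    """
    mask = eligible_mask(grid, tdef, target.stratum, stratum_field)
    if exclude is not None:
        mask &= ~exclude
    ids = np.flatnonzero(mask)
    n_want = probabilistic_round(target.target_area, grid.cell_area, rng)
    if n_want == 0:
        return np.empty(0, dtype=np.int64), 0.0
    if ids.size == 0:
        return np.empty(0, dtype=np.int64), float(n_want * grid.cell_area)
    k = min(n_want, ids.size)
    if tdef.prob_map is not None:
        w = getattr(grid, tdef.prob_map)[ids].astype(float)
        if w.sum() <= 0:
            w = np.ones_like(w)
        chosen = rng.choice(ids, size=k, replace=False, p=w / w.sum())
    else:
        chosen = rng.choice(ids, size=k, replace=False)
    shortfall = max(n_want - k, 0) * grid.cell_area
    return np.sort(chosen), float(shortfall)


def apply_transition(grid: LandscapeGrid, cell_id: int, tdef: TransitionDefinition) -> LandscapeGrid:
    """Apply one transition to one cell in place (returned for chaining).

    State class changes for class-changing pathways; stand age resets to 0 iff
    the pathway resets age; time-since-transition always resets.
    """
    if grid.state_class[cell_id] != CLASS_CODE[tdef.from_class]:
        raise ContractError(f"cell {cell_id} is not in class {tdef.from_class}")
    if tdef.min_age is not None and grid.age[cell_id] < tdef.min_age:
        raise ContractError(f"cell {cell_id} below minimum age {tdef.min_age}")
    if tdef.respects_protection and grid.protected[cell_id]:
        raise ContractError(f"cell {cell_id} is protected")
    grid.state_class[cell_id] = CLASS_CODE[tdef.to_class]
    if tdef.age_reset or tdef.to_class not in AGE_TRACKED_CLASSES:
        grid.age[cell_id] = 0
    grid.tst[cell_id] = 0
    return grid


def step_year(
    grid: LandscapeGrid,
    targets: list[TransitionTarget],
    tdefs: dict[str, TransitionDefinition],
    rng: np.random.Generator,
    year: int | None = None,
) -> list[TransitionEvent]:
    """Apply one year's land-use transitions and advance ages.

    Targets are processed in a uniformly random order; a cell transitions at
    most once per (year, transition group); afterwards age and TST of every
    tracked, un-reset cell increment by one year.  Returns the event log.
    """
    events: list[TransitionEvent] = []
    order = rng.permutation(len(targets))
    done_by_group: dict[str, np.ndarray] = {}
    reset_this_year = np.zeros(grid.n_cells, dtype=bool)
    transitioned = np.zeros(grid.n_cells, dtype=bool)

    group_defs: dict[str, list[TransitionDefinition]] = {}
    for td in tdefs.values():
        group_defs.setdefault(td.group, []).append(td)

    for i in order:
        target = targets[i]
        # a target may name one pathway or a whole transition group
        if target.transition in tdefs:
            defs = [tdefs[target.transition]]
        elif target.transition in group_defs:
            defs = group_defs[target.transition]
        else:
            raise ValidationError(f"unknown transition or group {target.transition!r}")
        group = defs[0].group
        already = done_by_group.setdefault(group, np.zeros(grid.n_cells, dtype=bool))
        cells, defs_by_cell, _short = _select_for_group(grid, target, defs, rng, exclude=already)
        yr = year if year is not None else target.year
        for cid in cells:
            tdef = defs_by_cell[int(cid)]
            apply_transition(grid, int(cid), tdef)
            already[cid] = True
            transitioned[cid] = True
            if tdef.age_reset:
                reset_this_year[cid] = True
            events.append(
                TransitionEvent(
                    year=int(yr),
                    transition=tdef.name,
                    group=tdef.group,
                    county=int(grid.county[cid]),
                    ecoregion=int(grid.ecoregion[cid]),
                    cell_id=int(cid),
                    area=grid.cell_area,
                )
            )

    advance_ages(grid, reset_this_year, transitioned)
    return events


def _select_for_group(
    grid: LandscapeGrid,
    target: TransitionTarget,
    defs: list[TransitionDefinition],
    rng: np.random.Generator,
    exclude: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[int, TransitionDefinition], float]:
    """Select cells for a target over the union of a group's pathways.

    Eligible cells are pooled across the pathways (a cell matches at most one,
    via its current class) and drawn without replacement, weighted by each
    pathway's probability layer.
    """
    masks = [eligible_mask(grid, d, target.stratum) for d in defs]
    union = np.zeros(grid.n_cells, dtype=bool)
    weights = np.zeros(grid.n_cells)
    owner = np.full(grid.n_cells, -1, dtype=np.int64)
    for j, (d, m) in enumerate(zip(defs, masks)):
        fresh = m & ~union
        union |= m
        w = getattr(grid, d.prob_map)[fresh] if d.prob_map is not None else 1.0
        weights[fresh] = w
        owner[fresh] = j
    if exclude is not None:
        union &= ~exclude
    ids = np.flatnonzero(union)
    n_want = probabilistic_round(target.target_area, grid.cell_area, rng)
    if n_want == 0:
        return np.empty(0, dtype=np.int64), {}, 0.0
    if ids.size == 0:
        return np.empty(0, dtype=np.int64), {}, float(n_want * grid.cell_area)
    k = min(n_want, ids.size)
    w = weights[ids]
    p = w / w.sum() if w.sum() > 0 else None
    chosen = rng.choice(ids, size=k, replace=False, p=p)
    defs_by_cell = {int(c): defs[owner[c]] for c in chosen}
    return np.sort(chosen), defs_by_cell, float(max(n_want - k, 0) * grid.cell_area)


def advance_ages(
    grid: LandscapeGrid,
    reset_this_year: np.ndarray | None = None,
    transitioned: np.ndarray | None = None,
) -> None:
    """Increment age (tracked classes) and TST, holding freshly reset cells at 0."""
    tracked = grid.age_tracked_mask()
    if reset_this_year is None:
        reset_this_year = np.zeros(grid.n_cells, dtype=bool)
    if transitioned is None:
        transitioned = np.zeros(grid.n_cells, dtype=bool)
    grid.age[tracked & ~reset_this_year] += 1
    grid.age[~tracked] = 0
    grid.tst[~transitioned] += 1
    grid.tst[transitioned] = 0


def events_to_frame(events: list[TransitionEvent]) -> pd.DataFrame:
    cols = ["year", "transition", "group", "county", "ecoregion", "cell_id", "area", "severity"]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([e.__dict__ for e in events])[cols]
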