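"""Stock-flow engine: multipliers, automatic and triggered flows, initialization."""

import numpy as np
import pytest

from landcarbon.carbon import (
    CarbonState,
    CFEParams,
    FlowPathway,
    Q10Params,
    annual_npp,
    apply_automatic_flows,
    apply_triggered_flows,
    cfe_multiplier,
    initialize_carbon,
    q10_multiplier,
    NPPModelParams,
)
from landcarbon.synthdata import generate_age_carbon_lookup, generate_landscape
from landcarbon.types import ContractError, ValidationError


class TestCfeMultiplier:
    def test_zero_beta_is_identity(self):
        assert cfe_multiplier(800.0, 371.0, CFEParams(beta=0.0)) == 1.0

    def test_direct_substitution(self):
        # +100 ppm at beta = 0.082 (8.2% per 100 ppm) -> multiplier 1.082
        assert cfe_multiplier(471.0, 371.0, CFEParams(beta=0.082)) == pytest.approx(1.082)

    def test_saturation_freezes_multiplier(self):
        params = CFEParams(beta=0.082, ca_cap=600.0)
        assert cfe_multiplier(700.0, 371.0, params) == cfe_multiplier(600.0, 371.0, params)

    def test_no_effect_below_baseline(self):
        assert cfe_multiplier(300.0, 371.0, CFEParams(beta=0.1)) == 1.0

    def test_negative_beta_rejected(self):
        with pytest.raises(ValidationError):
            CFEParams(beta=-0.1)


class TestQ10Multiplier:
    @pytest.mark.parametrize(
        "t, t_ref, q10, expected",
        [
            (15.0, 15.0, 2.0, 1.0),
            (25.0, 15.0, 2.0, 2.0),
            (20.0, 15.0, 2.65, 2.65**0.5),
            (5.0, 15.0, 2.0, 0.5),
        ],
    )
    def test_closed_forms(self, t, t_ref, q10, expected):
        assert q10_multiplier(t, t_ref, q10) == pytest.approx(expected)

    def test_q10_below_one_rejected(self):
        with pytest.raises(ValidationError):
            q10_multiplier(10.0, 10.0, 0.5)


class TestAnnualNpp:
    def _params(self):
        return NPPModelParams(ref_temp={0: 15.0}, ref_precip={0: 600.0})

    def test_reference_climate_gives_base_npp(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        p = self._params()
        flux = annual_npp(grid, {0: 15.0}, {0: 600.0}, p)
        base = p.max_npp["forest"] * float(p.response(15.0, 600.0))
        assert flux[0] == pytest.approx(base * grid.npp_multiplier[0])

    def test_dry_year_reduces_growth(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        p = self._params()
        wet = annual_npp(grid, {0: 15.0}, {0: 600.0}, p)
        dry = annual_npp(grid, {0: 15.0}, {0: 240.0}, p)
        assert dry[0] < wet[0]

    def test_unvegetated_cell_grows_nothing(self):
        grid = generate_landscape(1, 1, 1, {"developed": 1.0}, seed=1)
        flux = annual_npp(grid, {0: 15.0}, {0: 600.0}, self._params())
        assert flux[0] == 0.0

    def test_cfe_scales_linearly(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        p = self._params()
        base = annual_npp(grid, {0: 15.0}, {0: 600.0}, p, cfe=1.0)
        boosted = annual_npp(grid, {0: 15.0}, {0: 600.0}, p, cfe=1.082)
        assert boosted[0] == pytest.approx(1.082 * base[0])


def _single_forest_state(live=100.0, litter=50.0, soil=200.0):
    return CarbonState(
        live=np.array([live]),
        standing_dead=np.array([10.0]),
        down_dead=np.array([20.0]),
        litter=np.array([litter]),
        soil=np.array([soil]),
    )


class TestAutomaticFlows:
    def test_zero_rates_leave_state_unchanged(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        carbon = _single_forest_state()
        before = carbon.total()
        totals = apply_automatic_flows(carbon, grid, flows=())
        assert totals == {}
        assert carbon.total() == before
        assert carbon.live[0] == 100.0

    def test_single_flow_bookkeeping(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        carbon = _single_forest_state(live=100.0)
        flows = (FlowPathway("litterfall", "live", "litter", 0.105),)
        totals = apply_automatic_flows(carbon, grid, flows=flows)
        assert totals["litterfall"] == pytest.approx(10.5)
        assert carbon.live[0] == pytest.approx(89.5)
        assert carbon.litter[0] == pytest.approx(60.5)
        assert carbon.atmosphere == 0.0

    def test_mass_conserved_with_defaults(self, world):
        carbon = initialize_carbon(world.grid, world.lookup)
        before = carbon.total()
        npp = annual_npp(
            world.grid,
            {int(r): 15.0 for r in world.grid.ecoregions},
            {int(r): 600.0 for r in world.grid.ecoregions},
            world.npp_params,
        )
        apply_automatic_flows(carbon, world.grid, npp_flux=npp)
        assert carbon.total() == pytest.approx(before, rel=1e-12)

    def test_q10_scales_temperature_sensitive_flows(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        warm, cool = _single_forest_state(), _single_forest_state()
        flows = (FlowPathway("emission_soil", "soil", "atmosphere", 0.02, q10=2.0),)
        t_warm = apply_automatic_flows(warm, grid, flows=flows, temp_anomaly_by_region={0: 10.0})
        t_cool = apply_automatic_flows(cool, grid, flows=flows, temp_anomaly_by_region={0: 0.0})
        assert t_warm["emission_soil"] == pytest.approx(2.0 * t_cool["emission_soil"])

    def test_overdraw_capped_with_warning(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        carbon = _single_forest_state(litter=10.0)
        flows = (
            FlowPathway("decomposition", "litter", "soil", 0.9),
            FlowPathway("emission_litter", "litter", "atmosphere", 0.9),
        )
        with pytest.warns(UserWarning):
            apply_automatic_flows(carbon, grid, flows=flows)
        assert carbon.litter[0] == pytest.approx(0.0)
        assert carbon.litter[0] >= 0


class TestTriggeredFlows:
    def test_selection_harvest_moves_twenty_percent(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        carbon = _single_forest_state(live=100.0)
        apply_triggered_flows(carbon, grid, 0, "selection", to_class="forest")
        assert carbon.hwp == pytest.approx(20.0)
        assert carbon.live[0] == pytest.approx(80.0)

    def test_drought_is_transfer_only(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        carbon = _single_forest_state(live=100.0)
        before = carbon.total()
        apply_triggered_flows(carbon, grid, 0, "drought", severity="high")
        assert carbon.live[0] == pytest.approx(30.0)
        assert carbon.standing_dead[0] == pytest.approx(10.0 + 70.0)
        assert carbon.atmosphere == 0.0
        assert carbon.total() == pytest.approx(before)

    def test_clear_cut_splits_live_pool(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        carbon = _single_forest_state(live=100.0)
        moved = apply_triggered_flows(carbon, grid, 0, "clear_cut", to_class="forest")
        assert carbon.hwp == pytest.approx(55.0)
        assert carbon.live[0] == pytest.approx(100.0 * (1 - 0.55 - 0.08 - 0.30))
        assert moved["to_products"] == pytest.approx(55.0)

    def test_zero_fraction_fire_rule_is_noop(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        carbon = _single_forest_state()
        before = carbon.copy()
        rules = {"fire:low": [("live", 0.0, "atmosphere")]}
        apply_triggered_flows(carbon, grid, 0, "fire", severity="low", rules=rules)
        assert carbon.live[0] == before.live[0]
        assert carbon.atmosphere == 0.0

    def test_conversion_freezes_remaining_stocks(self):
        grid = generate_landscape(1, 1, 1, {"grassland": 1.0}, seed=1)
        carbon = _single_forest_state(live=100.0, litter=50.0, soil=200.0)
        before = carbon.total()
        apply_triggered_flows(carbon, grid, 0, "urbanization", to_class="developed")
        assert carbon.cell_total()[0] == 0.0
        assert carbon.transferred > 0
        assert carbon.total() == pytest.approx(before)

    def test_unknown_group_rejected(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        with pytest.raises(ValidationError):
            apply_triggered_flows(_single_forest_state(), grid, 0, "meteor")


class TestInitializeCarbon:
    def test_age_zero_forest_has_no_live_but_soil(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        grid.age[:] = 0
        lut = generate_age_carbon_lookup(1, ["forest"])
        carbon = initialize_carbon(grid, lut)
        assert carbon.live[0] == 0.0
        assert carbon.soil[0] > 0

    def test_spatial_multiplier_scales_live_linearly(self):
        grid = generate_landscape(1, 1, 1, {"forest": 1.0}, seed=1)
        grid.age[:] = 50
        lut = generate_age_carbon_lookup(1, ["forest"])
        base = initialize_carbon(grid, lut)
        grid2 = grid.copy()
        grid2.npp_multiplier[:] = 2.0 * grid.npp_multiplier
        doubled = initialize_carbon(grid2, lut)
        assert doubled.live[0] == pytest.approx(2.0 * base.live[0])
        assert doubled.soil[0] == pytest.approx(base.soil[0])  # soil scales separately

    def test_ecoregion_rows_differentiate_stocks(self):
        grid = generate_landscape(2, 1, 2, {"forest": 1.0}, seed=1)
        grid.age[:] = 100
        grid.npp_multiplier[:] = 1.0
        lut = generate_age_carbon_lookup(2, ["forest"])
        carbon = initialize_carbon(grid, lut)
        assert carbon.live[0] != carbon.live[1]

    def test_missing_lookup_key_rejected(self):
        grid = generate_landscape(1, 1, 1, {"grassland": 1.0}, seed=1)
        lut = generate_age_carbon_lookup(1, ["forest"])
        with pytest.raises(ValidationError):
            initialize_carbon(grid, lut)
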