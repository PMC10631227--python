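"""Damage functions, SLR surfaces, scaling, aggregation, registry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from climdamage import (DamageFunction, SLRSurface, SectorRegistry,
                        GMSLTrajectory, TemperatureTrajectory,
                        damages_share_of_gdp, eval_slr_damage,
                        eval_temp_damage, gcm_average, run_damages,
                        scale_impacts, synth_damage_registry,
                        generate_scenario_set)
from climdamage.damages import (registry_from_json, registry_to_json,
                                VARIANT_NO_ADAPT, VARIANT_PROACTIVE,
                                VARIANT_REACTIVE)
from climdamage.errors import ConfigurationError, InvalidArgumentError
from climdamage.scenarios import REGIONS
from climdamage.trajectories import default_years


def _func(temps=(0, 1, 2), impacts=(0, 10, 30), **kw):
    kw.setdefault("sector", "s")
    kw.setdefault("region", "Midwest")
    kw.setdefault("variant", VARIANT_NO_ADAPT)
    kw.setdefault("gcm", "g0")
    return DamageFunction(anchor_temps=np.array(temps, float),
                          anchor_impacts=np.array(impacts, float), **kw)


class TestTempDamage:
    @pytest.mark.parametrize("t,expected", [
        (1.5, 20.0),    # interior interpolation
        (3.0, 50.0),    # extrapolation with final slope 20/degC
        (0.0, 0.0),     # baseline anchor
        (1.0, 10.0),    # exact anchor
        (-1.0, -10.0),  # below zero: first segment's slope continued
    ])
    def test_examples(self, t, expected):
        assert eval_temp_damage(_func(), t) == pytest.approx(expected)

    def test_nan_rejected(self):
        with pytest.raises(InvalidArgumentError):
            eval_temp_damage(_func(), float("nan"))

    def test_anchor_validation(self):
        with pytest.raises(InvalidArgumentError):
            _func(temps=(0.5, 1), impacts=(0, 1))      # first anchor not 0
        with pytest.raises(InvalidArgumentError):
            _func(temps=(0, 2, 1), impacts=(0, 1, 2))  # not increasing
        with pytest.raises(InvalidArgumentError):
            _func(temps=(0, 12), impacts=(0, 1))       # beyond range

    @given(st.lists(st.floats(0.1, 3.0), min_size=2, max_size=6),
           st.integers(0, 2 ** 31 - 1))
    def test_matches_bruteforce_oracle_on_random_anchors(self, steps, seed):
        rng = np.random.default_rng(seed)
        temps = np.concatenate([[0.0], np.cumsum(steps)])
        temps = temps / temps[-1] * 10.0
        impacts = np.concatenate([[0.0], rng.normal(0, 5, len(steps))])
        f = _func(temps=temps, impacts=impacts)
        queries = rng.uniform(-2, 14, 1000)

        def oracle(x):
            # brute force: locate the segment (or the edge segment) and
            # apply its line
            k = np.searchsorted(temps, x) - 1
            k = min(max(k, 0), len(temps) - 2)
            s = (impacts[k + 1] - impacts[k]) / (temps[k + 1] - temps[k])
            return impacts[k] + s * (x - temps[k])

        got = eval_temp_damage(f, queries)
        want = np.array([oracle(x) for x in queries])
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)


class TestSlrDamage:
    def _surface(self, years=None, heights=(0.0, 50.0), rows=None):
        years = np.arange(2020, 2023) if years is None else years
        heights = np.asarray(heights, float)
        if rows is None:
            rows = np.tile(np.array([0.0, 100.0]), (len(years), 1))
        return SLRSurface(sector="coastal properties", region="Southeast",
                          variant=VARIANT_REACTIVE, gcm="g0", years=years,
                          heights=heights, values=np.asarray(rows, float))

    def test_midpoint_interpolation(self):
        assert eval_slr_damage(self._surface(), 2021, 25.0) == pytest.approx(50.0)

    def test_grid_height_returns_grid_value(self):
        s = self._surface()
        assert eval_slr_damage(s, 2020, 50.0) == pytest.approx(100.0)
        assert eval_slr_damage(s, 2020, 0.0) == pytest.approx(0.0)

    def test_year_outside_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            eval_slr_damage(self._surface(), 2050, 10.0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_1d_interpolation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        heights = np.concatenate([[0.0],
                                  np.cumsum(rng.uniform(5, 60, 5))])
        years = np.arange(2020, 2025)
        rows = rng.uniform(0, 200, (5, 6))
        s = self._surface(years=years, heights=heights, rows=rows)
        year = int(rng.integers(2020, 2025))
        row = rows[year - 2020]
        queries = rng.uniform(-5, heights[-1] * 1.5, 1000)
        got = eval_slr_damage(s, year, queries)
        slope_hi = (row[-1] - row[-2]) / (heights[-1] - heights[-2])
        want = np.array([
            row[-1] + slope_hi * (h - heights[-1]) if h > heights[-1]
            else np.interp(max(h, 0.0), heights, row)
            for h in queries])
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)


class TestScaling:
    def test_neutral_scaling_leaves_impact_unchanged(self):
        out = scale_impacts(42.0, 1e6, 5e4, 9e9, 9e9,
                            {"population_proportional": False,
                             "gdppc_elasticity": 0.0})
        assert out == 42.0

    def test_unit_elasticity_doubles_with_gdppc(self):
        out = scale_impacts(10.0, 1e6, 5e4, 1e6, 1e5,
                            {"population_proportional": False,
                             "gdppc_elasticity": 1.0})
        assert out == pytest.approx(20.0)

    def test_population_proportionality(self):
        out = scale_impacts(10.0, 1e6, 5e4, 2e6, 5e4,
                            {"population_proportional": True,
                             "gdppc_elasticity": 0.0})
        assert out == pytest.approx(20.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InvalidArgumentError):
            scale_impacts(1.0, 0.0, 5e4, 1e6, 5e4, {})


class TestGcmAverage:
    def test_identical_members(self):
        assert gcm_average([7.0, 7.0, 7.0]) == pytest.approx(7.0)

    def test_two_members(self):
        assert gcm_average([10.0, 30.0]) == pytest.approx(20.0)

    def test_matches_sum_over_n(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=11)
        assert gcm_average(list(vals)) == pytest.approx(vals.sum() / 11)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gcm_average([])


class TestRegistry:
    def test_seeded_determinism(self):
        assert synth_damage_registry(3) == synth_damage_registry(3)

    def test_twenty_sectors_seven_regions(self, registry):
        assert len(registry.sectors) == 20
        for s in registry.sectors:
            assert {k[1] for k in registry._by_key if k[0] == s} == set(REGIONS)

    def test_registry_validates(self, registry):
        registry.validate()

    def test_has_beneficial_sector_somewhere(self, registry):
        entries = registry.lookup("air quality mortality", "Midwest",
                                  VARIANT_NO_ADAPT)
        assert all(e.anchor_impacts[-1] < 0 for e in entries)

    def test_has_two_slr_sectors(self, registry):
        slr_sectors = {e.sector for e in registry.entries
                       if isinstance(e, SLRSurface)}
        assert slr_sectors == {"coastal properties",
                               "high-tide flooding transportation"}

    def test_json_round_trip(self, registry):
        assert registry_from_json(registry_to_json(registry)) == registry

    def test_unknown_variant_message_lists_valid_set(self, registry):
        with pytest.raises(ConfigurationError, match="available"):
            registry.lookup("labor", "Midwest", "imaginary")


@pytest.fixture(scope="module")
def chain(small_set, registry):
    from climdamage import sample_climate_params, run_climate_ensemble
    ens = sample_climate_params(len(small_set), 13)
    clim = run_climate_ensemble(small_set, ens)
    conus = TemperatureTrajectory(small_set.years, clim["conus"][0],
                                  baseline="1986-2005", domain="CONUS")
    gmsl = GMSLTrajectory(small_set.years, clim["gmsl"][0])
    table = run_damages(small_set.scenario(0), conus, gmsl, registry)
    return small_set.scenario(0), conus, gmsl, table


class TestRunDamages:

    def test_regions_sum_to_national(self, chain):
        _, _, _, table = chain
        national = table.national_total().values
        regional = table.regional_totals().sum(axis=1).to_numpy()
        np.testing.assert_allclose(national, regional, rtol=1e-9)

    def test_categories_sum_to_national(self, chain, registry):
        _, _, _, table = chain
        national = table.national_total().values
        cats = table.category_totals(registry.category_map).sum(axis=1)
        np.testing.assert_allclose(national, cats.to_numpy(), rtol=1e-9)

    def test_hand_computed_single_cell(self, chain, registry):
        """One sector x region x year recomputed from the primitive ops."""
        scen, conus, gmsl, table = chain
        sector, region, year = "labor", "Southeast", 2090
        entries = registry.lookup(sector, region,
                                  registry.default_variant[sector])
        raw = gcm_average([eval_temp_damage(e, conus.at(year))
                           for e in entries])
        from climdamage import default_regional_shares
        shares = default_regional_shares()
        iy = year - 2020
        pop_r = (shares.share_matrix(scen.years)[REGIONS.index(region), iy]
                 * scen.population.values[iy])
        gdppc = scen.gdp.values[iy] / scen.population.values[iy]
        phys = raw * pop_r / registry.ref_region_pop[region]
        usd = (phys * entries[0].unit_value
               * (gdppc / registry.ref_gdppc))
        cell = table.data[(table.data.sector == sector)
                          & (table.data.region == region)
                          & (table.data.year == year)]
        assert cell.usd2015.iloc[0] == pytest.approx(usd, rel=1e-9)
        assert cell.physical_value.iloc[0] == pytest.approx(phys, rel=1e-9)

    def test_zero_warming_zero_rise_zero_damages(self, small_set, registry):
        years = small_set.years
        conus = TemperatureTrajectory(years, np.zeros(281),
                                      baseline="1986-2005", domain="CONUS")
        gmsl = GMSLTrajectory(years, np.zeros(281))
        table = run_damages(small_set.scenario(0), conus, gmsl, registry)
        assert table.national_total().values == pytest.approx(0.0, abs=1e-9)

    def test_empty_registry_gives_empty_table(self, small_set):
        empty = SectorRegistry([], {}, {}, 5e4, {r: 1e6 for r in REGIONS},
                               expected_sectors=0)
        years = small_set.years
        conus = TemperatureTrajectory(years, np.ones(281),
                                      baseline="1986-2005", domain="CONUS")
        gmsl = GMSLTrajectory(years, np.zeros(281))
        table = run_damages(small_set.scenario(0), conus, gmsl, empty)
        assert table.data.empty

    def test_monotone_registry_gives_monotone_damages(self, small_set,
                                                      registry):
        years = small_set.years
        gmsl = GMSLTrajectory(years, np.zeros(281))
        totals = []
        for level in (0.5, 1.5, 3.0, 6.0):
            conus = TemperatureTrajectory(years, np.full(281, level),
                                          baseline="1986-2005",
                                          domain="CONUS")
            t = run_damages(small_set.scenario(0), conus, gmsl, registry)
            totals.append(t.national_total().values.sum())
        assert np.all(np.diff(totals) > 0)

    def test_variant_ordering_preserved(self, small_set, registry):
        """no additional adaptation >= reactive >= proactive, everywhere."""
        years = small_set.years
        sector = "coastal properties"
        scen = small_set.scenario(0)
        conus = TemperatureTrajectory(years, np.full(281, 2.0),
                                      baseline="1986-2005", domain="CONUS")
        gmsl = GMSLTrajectory(years, np.linspace(5, 120, 281))
        totals = {}
        for variant in (VARIANT_NO_ADAPT, VARIANT_REACTIVE,
                        VARIANT_PROACTIVE):
            t = run_damages(scen, conus, gmsl, registry,
                            variant_selection={sector: variant})
            sec = t.data[t.data.sector == sector]
            totals[variant] = sec.groupby("year").usd2015.sum().to_numpy()
        assert np.all(totals[VARIANT_NO_ADAPT] >= totals[VARIANT_REACTIVE])
        assert np.all(totals[VARIANT_REACTIVE] >= totals[VARIANT_PROACTIVE])

    def test_unknown_variant_selection_names_sector(self, small_set,
                                                    registry):
        years = small_set.years
        conus = TemperatureTrajectory(years, np.ones(281),
                                      baseline="1986-2005", domain="CONUS")
        gmsl = GMSLTrajectory(years, np.zeros(281))
        with pytest.raises(ConfigurationError, match="labor"):
            run_damages(small_set.scenario(0), conus, gmsl, registry,
                        variant_selection={"labor": VARIANT_PROACTIVE})


class TestShareOfGdp:
    def test_simple_division(self, small_set, registry):
        years = small_set.years
        conus = TemperatureTrajectory(years, np.ones(281),
                                      baseline="1986-2005", domain="CONUS")
        gmsl = GMSLTrajectory(years, np.zeros(281))
        scen = small_set.scenario(1)
        table = run_damages(scen, conus, gmsl, registry)
        share = damages_share_of_gdp(table, scen.gdp)
        oracle = table.national_total().values / scen.gdp.values
        np.testing.assert_allclose(share.values, oracle, rtol=1e-12)
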