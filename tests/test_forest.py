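"""Demography core: light, photosynthesis, allometry, mortality, recruitment."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hydrogap.forest import (PATCH_AREA_M2, SpeciesParams, SpeciesTable,
                             Stand, allometric_biomass, dbh_from_biomass,
                             leaf_photosynthesis, light_profile,
                             load_species_table, tree_gross_production)


@pytest.fixture(scope="module")
def sp(species_table):
    return species_table.species[0]


def one_species_table(**overrides):
    base = dict(species_id="test", pmax=2.5, alpha_light=0.05,
                light_extinction_k=0.5, leaf_transmittance_m=0.1,
                resp_maintenance=0.02, resp_growth=0.25, h_max=30.0,
                h_half=50.0, cd_per_dbh=0.12, crown_length_frac=0.5,
                crown_lai=4.0, form_factor=0.5, wood_density=0.5,
                max_dbh=100.0, mort_background=0.015, mort_slow=0.05,
                slow_growth_dbh=0.05, max_recruits=3.0, light_threshold=0.1)
    base.update(overrides)
    return SpeciesTable([SpeciesParams(**base)])


class TestSpeciesIO:
    def test_demo_table_loads_and_validates(self, species_table):
        assert len(species_table) == 3
        assert all(sp.max_dbh > 1 for sp in species_table.species)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("species_id\tpmax\nx\t3.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_species_table(p)

    def test_out_of_range_mortality_rejected(self):
        with pytest.raises(ValueError, match="mort_background"):
            one_species_table(mort_background=1.5)


class TestLightProfile:
    def test_empty_patch_full_light(self):
        prof = light_profile(np.zeros(10), k=0.5)
        assert np.allclose(prof, 1.0)

    def test_single_layer_extinction(self):
        # one layer of LAI 1 at the top: everything below sees exp(-0.5)
        la = np.zeros(5)
        la[-1] = PATCH_AREA_M2 / PATCH_AREA_M2  # LAI 1 in layer units
        prof = light_profile(la, k=0.5)
        assert prof[-1] == pytest.approx(1.0)
        assert np.allclose(prof[:-1], math.exp(-0.5))

    @given(st.lists(st.floats(0, 3), min_size=1, max_size=30))
    def test_monotone_nonincreasing_downward(self, lai_layers):
        prof = light_profile(np.array(lai_layers), k=0.5)
        assert np.all(np.diff(prof) >= -1e-12)  # bottom-up ordering


class TestPhotosynthesis:
    def test_darkness_gives_zero(self, sp):
        assert tree_gross_production(0.0, 4.0, sp.pmax, sp.alpha_light,
                                     sp.light_extinction_k,
                                     sp.leaf_transmittance_m) == 0.0

    def test_closed_form_matches_quadrature(self, sp):
        """Brute-force layer integration agrees to 1e-6 relative."""
        i0, lai = 900.0, 4.5
        closed = tree_gross_production(i0, lai, sp.pmax, sp.alpha_light,
                                       sp.light_extinction_k,
                                       sp.leaf_transmittance_m)
        # midpoint rule over 10^4 sublayers of the same leaf response
        k = sp.light_extinction_k
        ell = (np.arange(10_000) + 0.5) * (lai / 10_000)
        rates = leaf_photosynthesis(i0 * np.exp(-k * ell), sp.pmax,
                                    sp.alpha_light, k,
                                    sp.leaf_transmittance_m)
        brute = rates.sum() * (lai / 10_000)
        assert closed == pytest.approx(brute, rel=1e-6)

    def test_thin_canopy_limit_recovers_leaf_rate(self, sp):
        """Per unit LAI the integral tends to the single-leaf rate."""
        i0, lai = 700.0, 1e-7
        per_lai = tree_gross_production(
            i0, lai, sp.pmax, sp.alpha_light, sp.light_extinction_k,
            sp.leaf_transmittance_m) / lai
        leaf = leaf_photosynthesis(i0, sp.pmax, sp.alpha_light,
                                   sp.light_extinction_k,
                                   sp.leaf_transmittance_m)
        assert per_lai == pytest.approx(leaf, rel=1e-5)

    def test_increasing_and_saturating_in_light(self, sp):
        light = np.linspace(0, 3000, 50)
        rates = tree_gross_production(light, 4.0, sp.pmax, sp.alpha_light,
                                      sp.light_extinction_k,
                                      sp.leaf_transmittance_m)
        diffs = np.diff(rates)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) < 0)  # concave


class TestAllometry:
    @given(st.floats(1.0, 150.0))
    def test_biomass_inversion_round_trip(self, dbh):
        h_max = np.array([30.0]); h_half = np.array([50.0])
        ff = np.array([0.5]); wd = np.array([0.5])
        b = allometric_biomass(np.array([dbh]), h_max, h_half, ff, wd)
        d = dbh_from_biomass(b, np.array([10.0]), h_max, h_half, ff, wd)
        assert d[0] == pytest.approx(dbh, rel=1e-8)

    def test_geometry_consistency(self, species_table):
        stand = Stand(species_table, 1, 1)
        stand.dbh = np.array([50.0])
        stand.species = np.array([0])
        stand.patch = np.array([0])
        stand.last_increment = np.array([np.inf])
        t = stand.trees()[0]
        spp = species_table.species[0]
        assert t.height == pytest.approx(spp.h_max * 50 / (50 + spp.h_half))
        assert t.crown_area == pytest.approx(
            math.pi / 4 * (spp.cd_per_dbh * 50) ** 2)
        assert t.leaf_area == pytest.approx(t.crown_area * spp.crown_lai)


class TestGrowth:
    def make_stand(self, table, dbh):
        stand = Stand(table, 1, 1)
        n = len(dbh)
        stand.dbh = np.asarray(dbh, dtype=float)
        stand.species = np.zeros(n, dtype=np.int64)
        stand.patch = np.zeros(n, dtype=np.int64)
        stand.last_increment = np.full(n, np.inf)
        return stand

    def test_no_production_no_growth(self):
        table = one_species_table(resp_maintenance=0.0)
        stand = self.make_stand(table, [20.0])
        stand.grow(np.array([0.0]), 1.0)
        assert stand.dbh[0] == 20.0

    def test_increment_monotone_in_omega(self):
        table = one_species_table()
        a = self.make_stand(table, [20.0])
        b = self.make_stand(table, [20.0])
        pb = np.array([20_000.0])
        a.grow(pb, 1.0)
        b.grow(pb, 0.5)
        assert a.dbh[0] > b.dbh[0] > 20.0

    def test_growth_shuts_down_near_max_dbh(self):
        """Increments shrink to zero as dbh approaches the species cap."""
        table = one_species_table(max_dbh=60.0)
        stand = self.make_stand(table, [5.0])
        incs = []
        for _ in range(400):
            stand.grow(np.array([50_000.0]), 1.0)
            incs.append(stand.last_increment[0])
        assert stand.dbh[0] < 60.0
        assert incs[-1] < 1e-3
        assert incs[-1] < incs[0]


class TestMortality:
    def test_immortal_uncrowded_stand(self):
        table = one_species_table(mort_background=0.0, mort_slow=0.0)
        stand = TestGrowth().make_stand(table, [10.0, 20.0, 30.0])
        removed = stand.apply_mortality(np.random.default_rng(0))
        assert removed == 0 and stand.n_trees == 3

    def test_background_rate_expectation(self):
        """Deaths over many tree-years match the rate within CLT bounds."""
        rate = 0.02
        table = one_species_table(mort_background=rate, mort_slow=0.0)
        n = 20_000
        stand = Stand(table, 50, 50)  # enough patches to avoid crowding
        stand.dbh = np.full(n, 5.0)
        stand.species = np.zeros(n, dtype=np.int64)
        stand.patch = np.arange(n, dtype=np.int64) % stand.n_patches
        stand.last_increment = np.full(n, np.inf)
        removed = stand.apply_mortality(np.random.default_rng(42))
        expect = n * rate
        assert abs(removed - expect) < 3 * math.sqrt(n * rate * (1 - rate))

    def test_self_thinning_enforces_crown_constraint(self):
        table = one_species_table(mort_background=0.0, mort_slow=0.0)
        # 60 trees of dbh 40: crown area ~ 18.1 m2 each > 400 m2 total
        stand = TestGrowth().make_stand(table, np.full(60, 40.0))
        stand.apply_mortality(np.random.default_rng(1))
        assert stand.n_trees > 0
        assert stand.crown_area().sum() <= PATCH_AREA_M2 + 1e-9


class TestRecruitment:
    def test_full_light_expectation(self):
        table = one_species_table(max_recruits=4.0, light_threshold=0.2)
        stand = Stand(table, 20, 20)  # 400 empty patches
        n = stand.apply_recruitment(np.random.default_rng(3))
        expect = 400 * 4.0
        assert abs(n - expect) < 3 * math.sqrt(expect)
        assert np.all(stand.dbh == 1.0)

    def test_darkness_blocks_light_demander(self):
        table = one_species_table(light_threshold=0.3)
        stand = Stand(table, 2, 2)
        n = stand.apply_recruitment(np.random.default_rng(0),
                                    floor_light=np.zeros(4))
        assert n == 0

    def test_monotone_in_floor_light(self):
        table = one_species_table(max_recruits=6.0, light_threshold=0.5)
        means = []
        for light in (0.05, 0.2, 0.5, 1.0):
            stand = Stand(table, 20, 20)
            n = stand.apply_recruitment(
                np.random.default_rng(9),
                floor_light=np.full(400, light))
            means.append(n / 400)
        assert means == sorted(means)
        assert means[-1] == pytest.approx(6.0, abs=3 * math.sqrt(6 / 400))


class TestStandMetrics:
    def test_single_tree_basal_area(self, species_table):
        stand = Stand(species_table, 5, 5)  # 1 ha
        stand.dbh = np.array([50.0])
        stand.species = np.array([0])
        stand.patch = np.array([0])
        stand.last_increment = np.array([np.inf])
        assert stand.basal_area() == pytest.approx(math.pi * 0.0625,
                                                   rel=1e-12)

    def test_empty_stand_zeros(self, species_table):
        stand = Stand.bare_ground(species_table)
        m = stand.metrics()
        assert m["n_trees"] == 0
        assert m["basal_area_m2_ha"] == 0.0
        assert m["agb_tc_ha"] == 0.0
        assert m["stand_lai"] == 0.0

    def test_metrics_additive_over_patches(self, species_table):
        rng = np.random.default_rng(8)
        stand = Stand(species_table, 2, 2)
        n = 40
        stand.dbh = rng.uniform(5, 60, n)
        stand.species = rng.integers(0, 3, n)
        stand.patch = rng.integers(0, 4, n)
        stand.last_increment = np.full(n, np.inf)
        total_ba = stand.basal_area() * stand.area_m2 / 1e4
        per_patch = sum(
            float(np.sum(math.pi * (stand.dbh[stand.patch == p] / 200.0) ** 2))
            for p in range(4))
        assert total_ba == pytest.approx(per_patch, rel=1e-12)

    def test_inventory_round_trip(self, species_table):
        inv = pd.DataFrame({
            "species_id": ["shadetol_conifer", "midtol_broadleaf"],
            "dbh_cm": [35.0, 12.0],
        })
        stand = Stand.from_inventory(species_table, inv, 2, 2)
        assert stand.n_trees == 2
        assert sorted(stand.dbh) == [12.0, 35.0]

    def test_inventory_below_threshold_rejected(self, species_table):
        inv = pd.DataFrame({"species_id": ["midtol_broadleaf"],
                            "dbh_cm": [0.5]})
        with pytest.raises(ValueError, match="1 cm"):
            Stand.from_inventory(species_table, inv)
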