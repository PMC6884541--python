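"""Cohort operations: litter production, decay, aggregation, excavation."""

import math

import numpy as np
import pytest

import bogsim as bs
from bogsim.column import FIXED_HEAD
from conftest import make_column


@pytest.fixture()
def litter():
    return bs.LitterParams()


class TestLitterProduction:
    def test_maximum_at_optimum_depth_and_reference_temperature(self, litter):
        p = bs.litter_production(litter.optimum_wtd_m,
                                 litter.reference_temp_c, litter)
        assert p == pytest.approx(litter.max_production)

    def test_zero_beyond_cutoff_depth(self, litter):
        deep = litter.optimum_wtd_m + litter.zero_range_m
        assert bs.litter_production(deep, 7.1, litter) == pytest.approx(0.0, abs=1e-9)
        assert bs.litter_production(deep + 0.01, 7.1, litter) == 0.0
        assert bs.litter_production(deep + 1.0, 7.1, litter) == 0.0

    def test_unimodal_in_water_table_depth(self, litter):
        opt = litter.optimum_wtd_m
        at_opt = bs.litter_production(opt, 7.1, litter)
        assert bs.litter_production(opt + 0.3, 7.1, litter) < at_opt
        assert bs.litter_production(0.0, 7.1, litter) < at_opt  # inundation

    def test_temperature_ramp_is_monotone_and_unity_at_reference(self, litter):
        p_ref = bs.litter_production(litter.optimum_wtd_m, 7.1, litter)
        p_warm = bs.litter_production(litter.optimum_wtd_m, 9.1, litter)
        p_cold = bs.litter_production(litter.optimum_wtd_m, 5.1, litter)
        assert p_cold < p_ref < p_warm
        assert p_warm / p_ref == pytest.approx(math.exp(litter.temp_coeff * 2))

    def test_negative_depth_clamped_to_surface(self, litter):
        assert (bs.litter_production(-0.2, 7.1, litter)
                == bs.litter_production(0.0, 7.1, litter))


class TestDecomposeCohorts:
    def test_zero_dt_is_identity(self):
        params = bs.ModelParams()
        col = make_column([100.0, 50.0], params)
        ox, an = bs.decompose_cohorts(col, [1.0, 0.0], 7.1, 0.0, params)
        assert ox == an == 0.0
        np.testing.assert_array_equal(col.mass, [100.0, 50.0])

    def test_fully_oxic_exponential_closed_form(self):
        """100 g at alpha=0.01/yr for 100 yr leaves 100/e ~ 36.788 g."""
        params = bs.ModelParams(oxic_decay_rate=0.01, anoxic_decay_rate=1e-9)
        col = make_column([100.0], params)
        ox, an = bs.decompose_cohorts(col, 1.0, 7.1, 100.0, params)
        assert col.mass[0] == pytest.approx(100.0 * math.exp(-1.0), rel=1e-12)
        assert ox == pytest.approx(100.0 * (1 - math.exp(-1.0)), rel=1e-12)
        assert an == 0.0

    def test_oxic_anoxic_instantaneous_loss_ratio(self):
        """With a 100x rate contrast, oxic loss outpaces anoxic 100:1."""
        params = bs.ModelParams(oxic_decay_rate=0.05, anoxic_decay_rate=0.0005)
        oxic_col = make_column([100.0], params)
        anoxic_col = make_column([100.0], params)
        dt = 1e-4
        ox, _ = bs.decompose_cohorts(oxic_col, 1.0, 7.1, dt, params)
        _, an = bs.decompose_cohorts(anoxic_col, 0.0, 7.1, dt, params)
        assert ox / an == pytest.approx(100.0, rel=1e-3)

    def test_temperature_q10_scaling(self):
        params = bs.ModelParams(decay_temp_q10=2.0)
        cold = make_column([100.0], params)
        warm = make_column([100.0], params)
        bs.decompose_cohorts(cold, 1.0, 7.1, 1.0, params)
        bs.decompose_cohorts(warm, 1.0, 17.1, 1.0, params)
        rate_cold = -math.log(cold.mass[0] / 100.0)
        rate_warm = -math.log(warm.mass[0] / 100.0)
        assert rate_warm / rate_cold == pytest.approx(2.0, rel=1e-9)

    def test_mass_never_increases_and_derived_fields_follow(self):
        params = bs.ModelParams()
        col = make_column([100.0, 80.0, 60.0], params)
        k0 = col.conductivity.copy()
        for _ in range(5):
            before = col.mass.copy()
            bs.decompose_cohorts(col, [1.0, 0.5, 0.0], 8.0, 1.0, params)
            assert np.all(col.mass <= before)
        np.testing.assert_allclose(col.thickness,
                                   col.mass / params.dry_bulk_density)
        assert np.all(col.conductivity <= k0)


class TestAddAnnualCohort:
    def test_zero_litter_is_noop(self):
        col = make_column([10.0])
        bs.add_annual_cohort(col, 0.0, 5)
        assert col.n == 1

    def test_height_increment_from_bulk_density(self):
        params = bs.ModelParams(dry_bulk_density=1.0e5)
        col = make_column([10.0], params)
        h0 = col.height
        bs.add_annual_cohort(col, 200.0, 2)
        assert col.height - h0 == pytest.approx(2.0e-3, rel=1e-12)

    def test_repeated_addition_sums_masses(self):
        col = bs.Column(0.0, 2.0, bs.ModelParams())
        for year in range(1, 26):
            bs.add_annual_cohort(col, 37.0, year)
        assert col.total_mass == pytest.approx(25 * 37.0, rel=1e-12)
        assert col.n == 25


class TestAggregateThinLayers:
    def test_noop_when_no_thin_layers(self):
        col = make_column([300.0, 300.0], water_table=1.0)  # 3 mm each
        bs.aggregate_thin_layers(col, threshold=2.5e-3)
        assert col.n == 2

    def test_merges_adjacent_thin_layers_and_conserves_mass(self):
        # two adjacent 1e-3 m cohorts (100 g each at rho=1e5) merge into one
        # 2e-3 m cohort; masses, thickness and the year span are conserved
        col = make_column([100.0, 120.0, 300.0], years=[1, 2, 3],
                          water_table=1.0)
        bs.aggregate_thin_layers(col, threshold=2.5e-3)
        assert col.n == 2
        assert col.mass[0] == pytest.approx(220.0, rel=1e-12)
        assert col.thickness[0] == pytest.approx(2.2e-3, rel=1e-12)
        old, young = col.deposition_year_span
        assert (old[0], young[0]) == (1.0, 2.0)
        # mass-weighted mean year: (100*1 + 120*2) / 220
        assert col.deposition_year[0] == pytest.approx(340.0 / 220.0)

    def test_never_merges_above_water_table(self):
        col = make_column([50.0, 60.0, 70.0])
        col.water_table_elevation = col.base_elevation  # everything oxic
        bs.aggregate_thin_layers(col, threshold=2.5e-3)
        assert col.n == 3

    def test_no_adjacent_thin_pairs_remain_below_water_table(self):
        rng = np.random.default_rng(0)
        masses = rng.uniform(20.0, 400.0, 60)
        col = make_column(masses, water_table=10.0)
        total = col.total_mass
        bs.aggregate_thin_layers(col, threshold=2.5e-3)
        assert col.total_mass == pytest.approx(total, rel=1e-12)
        thin = col.thickness < 2.5e-3
        assert not np.any(thin[:-1] & thin[1:])


class TestExcavateDitch:
    def test_zero_depth_is_identity(self):
        col = make_column([100.0, 100.0])
        assert bs.excavate_ditch(col, 0.0) == 0.0
        assert col.n == 2
        assert col.boundary_kind != FIXED_HEAD

    def test_pro_rata_split_of_partial_cohort(self):
        # two 0.3 m cohorts (mass 3e4 each at rho=1e5); 0.5 m ditch removes
        # the top one whole and 2/3 of the second
        col = make_column([3.0e4, 3.0e4])
        removed = bs.excavate_ditch(col, 0.5)
        assert removed == pytest.approx(3.0e4 + (0.2 / 0.3) * 3.0e4, rel=1e-12)
        assert col.n == 1
        assert col.height == pytest.approx(0.1, rel=1e-12)
        assert col.boundary_kind == FIXED_HEAD
        assert col.fixed_head == pytest.approx(col.surface_elevation)
        assert not col.receives_litter

    def test_partial_cohort_keeps_decomposition_state(self):
        col = make_column([3.0e4, 3.0e4], m0=[6.0e4, 3.0e4])
        bs.excavate_ditch(col, 0.45)
        assert col.mass[0] / col.initial_mass[0] == pytest.approx(0.5)

    def test_over_deep_ditch_rejected(self):
        col = make_column([100.0])
        with pytest.raises(bs.ExcavationError):
            bs.excavate_ditch(col, 0.5)

    def test_default_ditch_plan_geometry(self):
        plan = bs.DitchPlan()
        offsets = plan.offsets_from_margin()
        np.testing.assert_allclose(offsets, 10.0 + 12.0 * np.arange(10))
        idx = plan.column_indices(75, 2.0)
        assert len(idx) == 10
        assert plan.depth_m == 0.5
        spacing = np.diff(sorted(150.0 - 2.0 * idx))
        np.testing.assert_allclose(np.abs(spacing), 12.0)
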