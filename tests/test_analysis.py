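"""Core statistics: apparent rates, windowed means, LORCA, budgets."""

import numpy as np
import pandas as pd
import pytest

import bogsim as bs
from bogsim.analysis import (AccumulationHistory, EmptyWindowError,
                             MalformedCoreError)
from conftest import make_column


def simple_core(masses, ages, thickness=None):
    masses = np.asarray(masses, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if thickness is None:
        thickness = masses / 1e5
    return bs.VirtualCore(age=ages, age_old=ages + 1.0, age_young=ages,
                          mass=masses, initial_mass=masses,
                          thickness=thickness)


class TestApparentRateHistory:
    def test_sequential_pair_formula(self):
        """Masses 100 and 110 one year apart give 0.5 * 105 = 52.5."""
        core = simple_core([100.0, 110.0], [2.0, 1.0])
        h = bs.apparent_rate_history(core)
        assert h.rate[0] == pytest.approx(52.5)
        assert h.age[0] == pytest.approx(1.5)
        assert h.delta_age[0] == 1.0

    def test_zero_mass_core_gives_zero_rates(self):
        core = simple_core([0.0, 0.0, 0.0], [3.0, 2.0, 1.0])
        h = bs.apparent_rate_history(core)
        np.testing.assert_array_equal(h.rate, 0.0)

    def test_rate_is_linear_in_carbon_fraction(self):
        core = simple_core([80.0, 120.0, 90.0], [30.0, 20.0, 10.0])
        half = bs.apparent_rate_history(core, carbon_fraction=0.5)
        full = bs.apparent_rate_history(core, carbon_fraction=1.0)
        np.testing.assert_allclose(full.rate, 2.0 * half.rate)

    def test_merged_layers_contribute_multi_year_denominators(self):
        core = bs.VirtualCore(age=[10.0, 4.0], age_old=[13.0, 5.0],
                              age_young=[8.0, 4.0], mass=[300.0, 100.0],
                              initial_mass=[300.0, 100.0],
                              thickness=[3e-3, 1e-3])
        h = bs.apparent_rate_history(core)
        assert h.delta_age[0] == pytest.approx(6.0)  # mean-age increment
        assert h.rate[0] == pytest.approx(0.5 * 200.0 / 6.0)

    def test_single_layer_core_rejected(self):
        core = simple_core([10.0], [5.0])
        with pytest.raises(MalformedCoreError):
            bs.apparent_rate_history(core)


class TestWindowedMeanRate:
    def test_constant_history_returns_the_constant(self):
        h = AccumulationHistory(age=np.array([50.0, 150.0, 250.0]),
                                rate=np.full(3, 12.5),
                                delta_age=np.array([10.0, 80.0, 30.0]))
        assert bs.windowed_mean_rate(h, 0, 300) == pytest.approx(12.5)

    def test_age_increment_weighting(self):
        """Rates 10 (over 50 yr) and 20 (over 150 yr) average to 17.5."""
        h = AccumulationHistory(age=np.array([100.0, 200.0]),
                                rate=np.array([10.0, 20.0]),
                                delta_age=np.array([50.0, 150.0]))
        assert bs.windowed_mean_rate(h, 0, 300) == pytest.approx(17.5)

    def test_empty_window_is_an_explicit_error(self):
        h = AccumulationHistory(age=np.array([100.0]),
                                rate=np.array([10.0]),
                                delta_age=np.array([1.0]))
        with pytest.raises(EmptyWindowError):
            bs.windowed_mean_rate(h, 500, 600)


class TestLorca:
    def test_single_layer(self):
        core = simple_core([240.0], [120.0])
        # basal age counts the full first year of deposition
        assert bs.lorca(core) == pytest.approx(0.5 * 240.0 / 121.0)

    def test_sum_over_basal_age(self):
        core = bs.VirtualCore(age=[599.0, 400.0, 200.0],
                              age_old=[600.0, 401.0, 201.0],
                              age_young=[599.0, 400.0, 200.0],
                              mass=[100.0, 200.0, 300.0],
                              initial_mass=[100.0, 200.0, 300.0],
                              thickness=[1e-3, 2e-3, 3e-3])
        assert bs.lorca(core) == pytest.approx(0.5 * 600.0 / 600.0)

    def test_equals_whole_core_windowed_mean_for_uniform_layers(self):
        n = 50
        ages = np.arange(n, 0, -1, dtype=float)
        core = simple_core(np.full(n, 80.0), ages)
        h = bs.apparent_rate_history(core)
        assert bs.lorca(core) == pytest.approx(
            bs.windowed_mean_rate(h, 0, n + 1), rel=0.03)


class TestThicknessYoungerThan:
    def test_whole_core_beyond_basal_age(self):
        core = simple_core([100.0, 100.0], [2.0, 1.0])
        assert (bs.thickness_younger_than(core, 10.0)
                == pytest.approx(core.total_thickness))

    def test_selection_sum_with_cutoff(self):
        core = simple_core([100.0] * 3, [250.0, 150.0, 50.0],
                           thickness=np.full(3, 0.1))
        assert bs.thickness_younger_than(core, 200.0) == pytest.approx(0.2)

    def test_zero_cutoff_selects_nothing(self):
        core = simple_core([100.0, 100.0], [2.0, 1.0])
        assert bs.thickness_younger_than(core, 0.0) == 0.0

    def test_straddling_layer_contributes_pro_rata(self):
        core = bs.VirtualCore(age=[150.0, 50.0], age_old=[200.0, 100.0],
                              age_young=[100.0, 0.0], mass=[100.0, 100.0],
                              initial_mass=[100.0, 100.0],
                              thickness=[0.1, 0.1])
        assert bs.thickness_younger_than(core, 150.0) == pytest.approx(0.15)


class TestCoreExtractionAndIO:
    def test_extract_core_orders_and_ages_layers(self):
        col = make_column([50.0, 60.0, 70.0], years=[1, 2, 3])
        core = bs.extract_core(col, 3)
        np.testing.assert_allclose(core.age, [2.0, 1.0, 0.0])
        assert core.basal_age == 3.0
        assert core.total_mass == pytest.approx(180.0)

    def test_field_core_table_conventions_accepted(self):
        df = pd.DataFrame({
            "depth_top": [0.2, 0.1, 0.0], "depth_bottom": [0.3, 0.2, 0.1],
            "age": [300.0, 200.0, 100.0],
            "dry_mass_per_area": [90.0, 100.0, 110.0]})
        core = bs.core_from_frame(df)
        np.testing.assert_allclose(core.thickness, 0.1)
        assert core.total_mass == pytest.approx(300.0)
        h = bs.apparent_rate_history(core)
        assert h.rate[0] == pytest.approx(0.5 * 95.0 / 100.0)

    def test_core_frame_roundtrip(self):
        col = make_column([50.0, 60.0, 70.0], years=[1, 2, 3])
        core = bs.extract_core(col, 3)
        back = bs.core_from_frame(bs.core_to_frame(core))
        np.testing.assert_allclose(back.mass, core.mass)
        np.testing.assert_allclose(back.age_young, core.age_young)

    def test_aggregation_leaves_windowed_means_nearly_unchanged(self):
        """Thin-layer aggregation must not distort the accumulation history:
        windowed means from an aggregated copy agree within 5%."""
        climate = bs.default_weekly_climate(n_years=150, seed=21)
        result = bs.run_simulation(bs.ModelParams(), climate, n_columns=5)
        col = result.columns[2]
        raw = bs.extract_core(col, result.n_years)
        merged_col = col.copy()
        merged_col.water_table_elevation = merged_col.surface_elevation
        bs.aggregate_thin_layers(merged_col, threshold=4e-3)
        merged = bs.extract_core(merged_col, result.n_years)
        assert merged.n_layers < raw.n_layers
        for lo, hi in ((0, 50), (50, 150)):
            a = bs.windowed_mean_rate(bs.apparent_rate_history(raw), lo, hi)
            b = bs.windowed_mean_rate(bs.apparent_rate_history(merged), lo, hi)
            assert b == pytest.approx(a, rel=0.05)


class TestNetBalance:
    def test_stock_series_and_closure(self):
        climate = bs.default_weekly_climate(n_years=50, seed=9)
        plan = bs.DitchPlan(depth_m=0.02, first_offset_from_margin_m=2.0,
                            spacing_m=6.0, count=2, open_years_before_end=15)
        result = bs.run_simulation(bs.ModelParams(), climate, ditch_plan=plan,
                                   n_columns=8)
        mid = result.midpoint_index()
        stock, change = bs.net_balance_series(result, mid)
        assert stock.shape == (50,)
        np.testing.assert_allclose(
            stock, 0.5 * result.total_mass[:, mid], rtol=1e-12)
        start = 0.5 * result.budget.stock_at_start[mid]
        assert change.net == pytest.approx(stock[-1] - start, rel=1e-9)

    def test_column_outside_transect_rejected(self, small_climate):
        result = bs.run_simulation(bs.ModelParams(), small_climate,
                                   n_columns=4)
        with pytest.raises(IndexError):
            bs.net_balance_series(result, 99)
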