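import numpy as np
import pytest

import bogsim as bs


@pytest.fixture(scope="session")
def default_params() -> bs.ModelParams:
    return bs.ModelParams()


@pytest.fixture()
def small_climate() -> bs.WeeklyClimateSeries:
    """A short noisy driver for fast whole-pipeline tests."""
    return bs.default_weekly_climate(n_years=40, seed=7)


def random_short_run(seed: int) -> bs.SimulationResult:
    """A randomized small transect run for conservation property tests."""
    rng = np.random.default_rng(seed)
    params = bs.ModelParams(
        oxic_decay_rate=float(rng.uniform(0.005, 0.08)),
        anoxic_decay_rate=float(rng.uniform(1e-5, 1e-3)),
        decay_temp_q10=float(rng.uniform(1.5, 3.0)),
        litter=bs.LitterParams(
            max_production=float(rng.uniform(100.0, 900.0)),
            optimum_wtd_m=float(rng.uniform(0.05, 0.3)),
            zero_range_m=float(rng.uniform(0.2, 0.6)),
        ),
        dry_bulk_density=float(rng.uniform(5e4, 1.5e5)),
        k_surface=float(rng.uniform(1.0, 40.0)),
        k_decomposition_exponent=float(rng.uniform(1.0, 6.0)),
        drainable_porosity=float(rng.uniform(0.2, 0.5)),
    )
    climate = bs.default_weekly_climate(
        n_years=int(rng.integers(8, 20)), seed=int(rng.integers(2**31)),
        amplitude=float(rng.uniform(0.0, 2.2)),
        mean_rain=float(rng.uniform(60.0, 130.0)),
        rain_sd=float(rng.uniform(0.0, 15.0)))
    n_cols = int(rng.integers(3, 7))
    return bs.run_simulation(params, climate, n_columns=n_cols)


def make_column(masses, params=None, m0=None, years=None,
                water_table=0.0) -> bs.Column:
    """Column with the given cohort masses (base to top)."""
    params = params or bs.ModelParams()
    col = bs.Column(1.0, 2.0, params)
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    for i, m in enumerate(masses):
        bs.add_annual_cohort(col, float(m), (years[i] if years is not None
                                             else i + 1))
    if m0 is not None:
        col._m0[: col.n] = np.asarray(m0, dtype=float)
    col.water_table_elevation = water_table
    return col
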