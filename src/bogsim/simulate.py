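"""Annual simulation loop coupling cohorts, litter, decay and hydrology.

Each simulated year:

1. 52 weekly hydrological steps driven by the weekly net-rainfall series;
   the weekly water-table elevations are recorded per column.
2. Per-cohort oxic-exposure fractions for the year are computed from the
   weekly water tables (share of weeks the water table sat below the cohort
   midpoint).
3. All cohorts decay once with those fractions and the year's air
   temperature.
4. Litter production from the annual-mean water-table depth and temperature
   is added as a new top cohort at the end of the year.
5. Thin layers below the water table are aggregated.

Ditches are excavated at the configured opening year and stay open to the
end of the run.  Full mass- and water-budget bookkeeping is kept per column
per year, and every source of randomness lives in the climate driver, so a
run is a pure function of (parameters, climate series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate import WeeklyClimateSeries, N_WEEKS
from .column import (COMP_ACRO, COMP_CATO, COMP_NEW, Column,
                     add_annual_cohort, aggregate_thin_layers,
                     decompose_cohorts, excavate_ditch, litter_production)
from .hydrology import HydrologyError, Transect
from .params import DitchPlan, ModelParams

__all__ = ["Simulator", "SimulationResult", "run_simulation",
           "mass_deposited_on_or_before"]


@dataclass
class BudgetAccount:
    """Decomposition/excavation losses partitioned by original peat position.

    Opened at a period start (e.g. the ditch-opening year): peat above the
    annual-mean water table at that time is 'original acrotelm', peat below
    is 'original upper catotelm'; litter added later is 'new'.  All values
    are dry mass, g m-2, per column.
    """

    start_year: int
    stock_at_start: np.ndarray
    acro_decay_loss: np.ndarray
    cato_decay_loss: np.ndarray
    acro_excavated: np.ndarray
    cato_excavated: np.ndarray
    new_excavated: np.ndarray


@dataclass
class SimulationResult:
    """Per-year per-column records plus end-of-run cohort inventories."""

    n_years: int
    column_width_m: float
    columns: list[Column]
    total_mass: np.ndarray        # [years, columns] g m-2
    height: np.ndarray            # m
    wtd_annual_mean: np.ndarray   # m below surface
    litter_added: np.ndarray      # g m-2 yr-1
    oxic_loss: np.ndarray         # g m-2 yr-1
    anoxic_loss: np.ndarray       # g m-2 yr-1
    runoff: np.ndarray            # m water yr-1
    excavated: np.ndarray         # g m-2 yr-1
    water_recharge: np.ndarray    # m water yr-1 actually applied
    water_lateral: np.ndarray     # m water yr-1 net lateral inflow
    water_boundary: np.ndarray    # m water yr-1 absorbed by fixed-head nodes
    water_lagg: np.ndarray        # m water yr-1 absorbed at the lagg face
    head_start: np.ndarray        # m, water-table elevation at year start
    head_end: np.ndarray          # m, at year end
    budget: BudgetAccount | None = None
    snapshot_columns: list[Column] | None = None
    snapshot_year: int | None = None

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, self.n_years + 1)

    def mass_balance_residual(self) -> np.ndarray:
        """Per-column relative closure error of the cumulative mass budget.

        |sum litter - sum decay - sum excavated - final mass| relative to
        total litter input.  Should sit at numerical roundoff.
        """
        inputs = self.litter_added.sum(axis=0)
        losses = (self.oxic_loss + self.anoxic_loss + self.excavated).sum(axis=0)
        final = np.array([c.total_mass for c in self.columns])
        scale = np.where(inputs > 0, inputs, 1.0)
        return np.abs(inputs - losses - final) / scale

    def water_balance_residual(self) -> np.ndarray:
        """Per-year relative closure error of the water budget.

        For every column, porosity * (head change over the year) must equal
        applied recharge + net lateral inflow - runoff; fixed-head columns
        satisfy this trivially (all terms zero).  The residual is the summed
        absolute error relative to the year's gross water turnover.
        """
        porosity = self.columns[0].params.drainable_porosity
        lhs = porosity * (self.head_end - self.head_start)
        rhs = self.water_recharge + self.water_lateral - self.runoff
        err = np.abs(lhs - rhs).sum(axis=1)
        scale = (np.abs(self.water_recharge).sum(axis=1)
                 + np.abs(self.runoff).sum(axis=1)
                 + np.abs(self.water_lateral).sum(axis=1))
        return err / np.where(scale > 0, scale, 1.0)

    def midpoint_index(self) -> int:
        """Column at the midpoint between the centre and the margin."""
        return self.n_columns // 2


class Simulator:
    """Stateful runner; supports branching a scenario from a shared history."""

    def __init__(self, params: ModelParams, climate: WeeklyClimateSeries,
                 n_columns: int = 75, column_width_m: float = 2.0):
        self.params = params
        self.climate = climate
        self.column_width_m = column_width_m
        cols = [Column((i + 0.5) * column_width_m, column_width_m, params)
                for i in range(n_columns)]
        self.transect = Transect(cols, params, column_width_m)
        self.year = 0
        self._records: dict[str, list[np.ndarray]] = {
            k: [] for k in ("total_mass", "height", "wtd_annual_mean",
                            "litter_added", "oxic_loss", "anoxic_loss",
                            "runoff", "excavated",
                            "water_recharge", "water_lateral",
                            "water_boundary", "water_lagg",
                            "head_start", "head_end")}
        self._last_mean_wt_elevation: np.ndarray | None = None
        self._budget: BudgetAccount | None = None
        self._snapshot: list[Column] | None = None
        self._snapshot_year: int | None = None

    # -- core loop ---------------------------------------------------------
    def step_year(self) -> None:
        """Simulate one year (52 weekly hydrological steps + annual biology)."""
        if self.year >= self.climate.n_years:
            raise ValueError("climate series exhausted; cannot step further")
        y = self.year  # 0-based index into the climate arrays
        params = self.params
        transect = self.transect
        cols = transect.columns
        n = len(cols)
        transect.refresh_transmissivity()

        weekly_cm = self.climate.weekly_net_rainfall_cm[y]
        temperature = float(self.climate.temperature_c[y])
        head_start = transect.heads
        try:
            wt_weekly, diag = transect.run_weeks(weekly_cm / 100.0)
        except HydrologyError as exc:
            raise HydrologyError(
                f"simulation year {y + 1} (weeks {y * N_WEEKS + 1}-"
                f"{(y + 1) * N_WEEKS}): {exc}") from exc
        runoff = diag.runoff

        surfaces = transect.surfaces
        mean_wt = wt_weekly.mean(axis=0)
        self._last_mean_wt_elevation = mean_wt
        wtd_mean = np.maximum(surfaces - mean_wt, 0.0)

        excavated = np.zeros(n)  # ditches are cut between years, not here
        oxic = np.zeros(n)
        anoxic = np.zeros(n)
        litter = np.zeros(n)
        wt_sorted = np.sort(wt_weekly, axis=0)
        for i, col in enumerate(cols):
            if col.n:
                thick = col.thickness
                mids = col.base_elevation + np.cumsum(thick) - 0.5 * thick
                n_below = np.searchsorted(wt_sorted[:, i], mids)
                f_ox = n_below / N_WEEKS
                comp_before = (col.components.sum(axis=0)
                               if col.components is not None else None)
                oxic[i], anoxic[i] = decompose_cohorts(
                    col, f_ox, temperature, 1.0, params)
                if comp_before is not None and self._budget is not None:
                    d = comp_before - col.components.sum(axis=0)
                    self._budget.acro_decay_loss[i] += d[COMP_ACRO]
                    self._budget.cato_decay_loss[i] += d[COMP_CATO]
            if col.receives_litter:
                litter[i] = litter_production(wtd_mean[i], temperature,
                                              params.litter)
                add_annual_cohort(col, litter[i], self.year + 1)
            aggregate_thin_layers(col)

        self.year += 1
        rec = self._records
        rec["total_mass"].append(np.array([c.total_mass for c in cols]))
        rec["height"].append(np.array([c.height for c in cols]))
        rec["wtd_annual_mean"].append(wtd_mean)
        rec["litter_added"].append(litter)
        rec["oxic_loss"].append(oxic)
        rec["anoxic_loss"].append(anoxic)
        rec["runoff"].append(runoff)
        rec["excavated"].append(excavated)
        rec["water_recharge"].append(diag.recharge_applied)
        rec["water_lateral"].append(diag.lateral_net)
        rec["water_boundary"].append(diag.boundary_absorbed)
        rec["water_lagg"].append(np.array([diag.lagg_absorbed]))
        rec["head_start"].append(head_start)
        rec["head_end"].append(wt_weekly[-1].copy())

    def run_years(self, n_years: int) -> None:
        for _ in range(n_years):
            self.step_year()

    # -- scenario plumbing --------------------------------------------------
    def snapshot(self) -> None:
        """Record copies of all columns (pre-drainage state for analyses)."""
        self._snapshot = [c.copy() for c in self.transect.columns]
        self._snapshot_year = self.year

    def start_budget_tracking(self) -> None:
        """Open a budget period at the current year.

        The acrotelm/catotelm divide is the annual-mean water-table
        elevation of the year just simulated.
        """
        if self._last_mean_wt_elevation is None:
            raise ValueError("run at least one year before opening a budget period")
        for col, divide in zip(self.transect.columns,
                               self._last_mean_wt_elevation):
            col.start_budget_tracking(divide)
        n = self.transect.n_columns
        self._budget = BudgetAccount(
            start_year=self.year,
            stock_at_start=np.array([c.total_mass
                                     for c in self.transect.columns]),
            acro_decay_loss=np.zeros(n), cato_decay_loss=np.zeros(n),
            acro_excavated=np.zeros(n), cato_excavated=np.zeros(n),
            new_excavated=np.zeros(n))

    def excavate_ditches(self, plan: DitchPlan) -> np.ndarray:
        """Cut all ditches of the plan; returns removed mass per column."""
        idx = plan.column_indices(self.transect.n_columns, self.column_width_m)
        removed = np.zeros(self.transect.n_columns)
        for i in idx:
            col = self.transect.columns[i]
            comp_before = (col.components.sum(axis=0)
                           if col.components is not None else None)
            removed[i] = excavate_ditch(col, plan.depth_m)
            if comp_before is not None and self._budget is not None:
                d = comp_before - col.components.sum(axis=0)
                self._budget.acro_excavated[i] += d[COMP_ACRO]
                self._budget.cato_excavated[i] += d[COMP_CATO]
                self._budget.new_excavated[i] += d[COMP_NEW]
        if self._records["excavated"]:
            # book the removal against the year just completed
            self._records["excavated"][-1] = \
                self._records["excavated"][-1] + removed
        self.transect.refresh_transmissivity()
        return removed

    def copy(self) -> "Simulator":
        """Branch point: an independent simulator sharing history and climate."""
        other = Simulator.__new__(Simulator)
        other.params = self.params
        other.climate = self.climate
        other.column_width_m = self.column_width_m
        other.transect = Transect([c.copy() for c in self.transect.columns],
                                  self.params, self.column_width_m)
        other.year = self.year
        other._records = {k: list(v) for k, v in self._records.items()}
        other._last_mean_wt_elevation = (
            None if self._last_mean_wt_elevation is None
            else self._last_mean_wt_elevation.copy())
        other._budget = None
        other._snapshot = self._snapshot
        other._snapshot_year = self._snapshot_year
        return other

    def result(self) -> SimulationResult:
        rec = {k: np.array(v) for k, v in self._records.items()}
        budget = self._budget
        return SimulationResult(
            n_years=self.year, column_width_m=self.column_width_m,
            columns=self.transect.columns,
            total_mass=rec["total_mass"], height=rec["height"],
            wtd_annual_mean=rec["wtd_annual_mean"],
            litter_added=rec["litter_added"], oxic_loss=rec["oxic_loss"],
            anoxic_loss=rec["anoxic_loss"], runoff=rec["runoff"],
            excavated=rec["excavated"],
            water_recharge=rec["water_recharge"],
            water_lateral=rec["water_lateral"],
            water_boundary=rec["water_boundary"],
            water_lagg=rec["water_lagg"].ravel(),
            head_start=rec["head_start"], head_end=rec["head_end"],
            budget=budget,
            snapshot_columns=self._snapshot,
            snapshot_year=self._snapshot_year)


def run_simulation(params: ModelParams, climate: WeeklyClimateSeries,
                   ditch_plan: DitchPlan | None = None,
                   n_years: int | None = None, n_columns: int = 75,
                   column_width_m: float = 2.0) -> SimulationResult:
    """Run one scenario start to finish.

    With a ditch plan, the ditches are excavated
    ``plan.open_years_before_end`` years before the end and remain open; a
    budget period is opened at the same time (also for natural runs, so the
    two scenarios' budgets are comparable), and a pre-drainage snapshot of
    all columns is kept.
    """
    n_years = climate.n_years if n_years is None else n_years
    if n_years > climate.n_years:
        raise ValueError(
            f"run length {n_years} exceeds climate series length "
            f"{climate.n_years}")
    sim = Simulator(params, climate, n_columns, column_width_m)
    open_year = None
    plan_years = (ditch_plan.open_years_before_end if ditch_plan is not None
                  else DitchPlan().open_years_before_end)
    if n_years > plan_years:
        open_year = n_years - plan_years
    if open_year is None:
        sim.run_years(n_years)
    else:
        sim.run_years(open_year)
        sim.snapshot()
        sim.start_budget_tracking()
        if ditch_plan is not None:
            sim.excavate_ditches(ditch_plan)
        sim.run_years(n_years - open_year)
    return sim.result()


def mass_deposited_on_or_before(column: Column, year_cutoff: float) -> float:
    """Dry mass (g m-2) in cohorts deposited in or before ``year_cutoff``.

    Merged cohorts straddling the cutoff contribute pro-rata by the share of
    their deposition-year span at or before the cutoff (mass assumed uniform
    across the span).
    """
    if column.n == 0:
        return 0.0
    old, young = column.deposition_year_span
    span = young - old + 1.0
    frac = np.clip((year_cutoff - old + 1.0) / span, 0.0, 1.0)
    return float(np.dot(column.mass, frac))
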