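"""Peat columns as ordered cohort stacks.

Each column is a vertical stack of annual *cohorts* (the parcel of litter
added in one year), ordered base to top.  A cohort keeps its deposition
year, its initial dry mass m0 and its current mass m (g m-2); thickness and
hydraulic conductivity are derived from mass:

    thickness    = m / dry_bulk_density
    conductivity = k_surface * (m / m0) ** k_decomposition_exponent

so decomposition simultaneously thins a layer and reduces its permeability.
Mass never increases after deposition.

Arrays are pre-allocated with capacity doubling; all per-cohort state is
held in flat numpy arrays so a 6,000-cohort column costs microseconds per
annual update.
"""

from __future__ import annotations

import math

import numpy as np

from .params import LitterParams, ModelParams

__all__ = [
    "Column",
    "ExcavationError",
    "litter_production",
    "add_annual_cohort",
    "decompose_cohorts",
    "aggregate_thin_layers",
    "excavate_ditch",
]

INTERIOR = 0
FIXED_HEAD = 1

# Budget-tracking mass components (active only while a budget period is open):
# peat that at the period start lay above the annual-mean water table
# (original acrotelm), below it (original upper catotelm), and material
# deposited after the period start (new).
COMP_ACRO, COMP_CATO, COMP_NEW = 0, 1, 2


class ExcavationError(ValueError):
    """Raised when a ditch would remove an entire column of peat."""


class Column:
    """One 2 m x 2 m peat column on the transect."""

    __slots__ = (
        "x_position", "width", "base_elevation", "params",
        "n", "_m", "_m0", "_yr", "_yr_old", "_yr_young", "_comp",
        "water_table_elevation", "boundary_kind", "fixed_head",
        "receives_litter",
    )

    def __init__(self, x_position: float, width: float, params: ModelParams,
                 base_elevation: float = 0.0, capacity: int = 64):
        self.x_position = x_position
        self.width = width
        self.base_elevation = base_elevation
        self.params = params
        self.n = 0
        self._m = np.empty(capacity)
        self._m0 = np.empty(capacity)
        self._yr = np.empty(capacity)
        self._yr_old = np.empty(capacity)
        self._yr_young = np.empty(capacity)
        self._comp: np.ndarray | None = None
        self.water_table_elevation = base_elevation
        self.boundary_kind = INTERIOR
        self.fixed_head = math.nan
        self.receives_litter = True

    # -- array views -------------------------------------------------------
    @property
    def mass(self) -> np.ndarray:
        """Current cohort masses, base to top (g m-2)."""
        return self._m[: self.n]

    @property
    def initial_mass(self) -> np.ndarray:
        return self._m0[: self.n]

    @property
    def deposition_year(self) -> np.ndarray:
        """Mass-weighted mean deposition year of each (possibly merged) cohort."""
        return self._yr[: self.n]

    @property
    def deposition_year_span(self) -> tuple[np.ndarray, np.ndarray]:
        """(oldest, youngest) deposition year of each cohort."""
        return self._yr_old[: self.n], self._yr_young[: self.n]

    @property
    def thickness(self) -> np.ndarray:
        return self.mass / self.params.dry_bulk_density

    @property
    def conductivity(self) -> np.ndarray:
        """Cohort hydraulic conductivity (m wk-1), declining with decomposition."""
        frac = np.divide(self.mass, self.initial_mass,
                         out=np.ones(self.n), where=self.initial_mass > 0)
        return self.params.k_surface * frac ** self.params.k_decomposition_exponent

    @property
    def height(self) -> float:
        """Total peat thickness (m)."""
        return float(self.mass.sum()) / self.params.dry_bulk_density

    @property
    def surface_elevation(self) -> float:
        return self.base_elevation + self.height

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    @property
    def components(self) -> np.ndarray | None:
        return None if self._comp is None else self._comp[: self.n]

    # -- capacity management ----------------------------------------------
    def _grow(self, extra: int = 1) -> None:
        need = self.n + extra
        if need <= self._m.size:
            return
        cap = max(need, 2 * self._m.size)
        for name in ("_m", "_m0", "_yr", "_yr_old", "_yr_young"):
            old = getattr(self, name)
            new = np.empty(cap)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)
        if self._comp is not None:
            new = np.empty((cap, 3))
            new[: self.n] = self._comp[: self.n]
            self._comp = new

    def _replace(self, m, m0, yr, yr_old, yr_young, comp=None) -> None:
        n = m.size
        self._grow(n - self.n)
        self._m[:n] = m
        self._m0[:n] = m0
        self._yr[:n] = yr
        self._yr_old[:n] = yr_old
        self._yr_young[:n] = yr_young
        if self._comp is not None:
            self._comp[:n] = comp
        self.n = n

    # -- budget component tracking ----------------------------------------
    def start_budget_tracking(self, acrotelm_divide_elevation: float) -> None:
        """Label current peat as original acrotelm/catotelm for budget accounting.

        ``acrotelm_divide_elevation`` is normally the annual-mean water-table
        elevation at the period start; peat above it is 'original acrotelm',
        peat below 'original upper catotelm'.  The straddling cohort is split
        pro-rata by thickness.  Litter added afterwards accumulates in the
        'new' component.
        """
        comp = np.zeros((self._m.size, 3))
        if self.n:
            top = self.base_elevation + np.cumsum(self.thickness)
            bottom = top - self.thickness
            thick = np.maximum(top - bottom, 0.0)
            above = np.clip(top - np.maximum(acrotelm_divide_elevation, bottom),
                            0.0, thick)
            frac_above = np.divide(above, thick, out=np.zeros(self.n),
                                   where=thick > 0)
            comp[: self.n, COMP_ACRO] = self.mass * frac_above
            comp[: self.n, COMP_CATO] = self.mass * (1.0 - frac_above)
        self._comp = comp

    def stop_budget_tracking(self) -> None:
        self._comp = None

    def copy(self) -> "Column":
        """Deep copy (used to branch scenarios from a shared history)."""
        other = Column(self.x_position, self.width, self.params,
                       self.base_elevation, capacity=self._m.size)
        other.n = self.n
        for name in ("_m", "_m0", "_yr", "_yr_old", "_yr_young"):
            getattr(other, name)[: self.n] = getattr(self, name)[: self.n]
        if self._comp is not None:
            other._comp = self._comp.copy()
        other.water_table_elevation = self.water_table_elevation
        other.boundary_kind = self.boundary_kind
        other.fixed_head = self.fixed_head
        other.receives_litter = self.receives_litter
        return other


# ---------------------------------------------------------------------------
# Operations

def litter_production(annual_mean_wtd: float, temperature: float,
                      litter: LitterParams) -> float:
    """Annual litter addition (g m-2 yr-1) from water-table depth and temperature.

    Unimodal in water-table depth: maximal at the optimum depth, reduced
    under inundation (depth 0) and falling to zero for water tables at or
    beyond ``optimum_wtd_m + zero_range_m``.  The temperature ramp
    exp(temp_coeff * (T - T_ref)) is monotone and equals 1 at the reference
    temperature.
    """
    wtd = max(annual_mean_wtd, 0.0)
    shape = 1.0 - ((wtd - litter.optimum_wtd_m) / litter.zero_range_m) ** 2
    if shape <= 0.0:
        return 0.0
    ramp = math.exp(litter.temp_coeff * (temperature - litter.reference_temp_c))
    return litter.max_production * shape * ramp


def add_annual_cohort(column: Column, litter_mass: float, year: int) -> None:
    """Append one year's litter as a new top cohort (no-op for zero litter)."""
    if litter_mass < 0:
        raise ValueError("litter mass must be >= 0")
    if litter_mass == 0.0:
        return
    column._grow(1)
    i = column.n
    column._m[i] = litter_mass
    column._m0[i] = litter_mass
    column._yr[i] = year
    column._yr_old[i] = year
    column._yr_young[i] = year
    if column._comp is not None:
        column._comp[i] = (0.0, 0.0, litter_mass)
    column.n += 1


def decompose_cohorts(column: Column, oxic_fraction, temperature: float,
                      dt: float, params: ModelParams):
    """Decay every cohort for ``dt`` years and return (oxic_loss, anoxic_loss).

    Each cohort decays as m <- m * exp(-alpha_eff * dt) with

        alpha_eff = [f_ox * a_ox + (1 - f_ox) * a_an] * Q10^((T - T_ref)/10)

    where ``f_ox`` is the cohort's oxic-exposure fraction for the period
    (the share of the year it spent above the water table).  Losses are
    partitioned between the oxic and anoxic pathways in proportion to their
    contribution to alpha_eff, for budget accounting.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    n = column.n
    if n == 0 or dt == 0.0:
        return 0.0, 0.0
    f = np.clip(np.asarray(oxic_fraction, dtype=float), 0.0, 1.0)
    if f.ndim == 0:
        f = np.full(n, float(f))
    if f.size != n:
        raise ValueError("need one oxic fraction per cohort")
    temp_fac = params.decay_temp_q10 ** ((temperature - params.reference_temp_c) / 10.0)
    a_ox = f * params.oxic_decay_rate
    a_an = (1.0 - f) * params.anoxic_decay_rate
    alpha = (a_ox + a_an) * temp_fac
    m = column.mass
    factor = np.exp(-alpha * dt)
    loss = m * (1.0 - factor)
    with np.errstate(invalid="ignore", divide="ignore"):
        ox_share = np.divide(a_ox, a_ox + a_an, out=np.zeros(n),
                             where=(a_ox + a_an) > 0)
    oxic_loss = float(np.dot(loss, ox_share))
    anoxic_loss = float(loss.sum()) - oxic_loss
    if column._comp is not None:
        column._comp[:n] *= factor[:, None]
    m *= factor
    return oxic_loss, anoxic_loss


def aggregate_thin_layers(column: Column, threshold: float | None = None) -> None:
    """Merge maximal runs of adjacent sub-threshold cohorts below the water table.

    Merged cohorts sum m, m0 (and budget components) exactly; the deposition
    year becomes the mass-weighted mean and the (oldest, youngest) span is
    retained so age increments remain meaningful for core analysis.  Cohorts
    above the current water table are never merged, preserving annual age
    resolution in the near-surface peat that the 0-200-yr analysis window
    depends on.
    """
    if threshold is None:
        threshold = column.params.aggregation_threshold
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n = column.n
    if n < 2:
        return
    thick = column.thickness
    top = column.base_elevation + np.cumsum(thick)
    below_wt = top <= column.water_table_elevation
    small = (thick < threshold) & below_wt
    # Pairs of adjacent small cohorts trigger a merge.
    if not np.any(small[:-1] & small[1:]):
        return
    # Group ids: start a new group wherever the previous cohort is not part
    # of the same small-run.
    start = np.ones(n, dtype=bool)
    start[1:] = ~(small[1:] & small[:-1])
    group = np.cumsum(start) - 1
    n_groups = group[-1] + 1
    m = np.zeros(n_groups)
    m0 = np.zeros(n_groups)
    np.add.at(m, group, column.mass)
    np.add.at(m0, group, column.initial_mass)
    wsum = np.zeros(n_groups)
    np.add.at(wsum, group, column.mass * column.deposition_year)
    w0sum = np.zeros(n_groups)
    np.add.at(w0sum, group, column.initial_mass * column.deposition_year)
    # Mass-weighted mean year; fall back to the m0 weighting if fully decayed.
    yr = np.where(m > 0, wsum / np.where(m > 0, m, 1.0),
                  w0sum / np.where(m0 > 0, m0, 1.0))
    yr_old_src, yr_young_src = column.deposition_year_span
    yr_old = np.full(n_groups, np.inf)
    np.minimum.at(yr_old, group, yr_old_src)
    yr_young = np.full(n_groups, -np.inf)
    np.maximum.at(yr_young, group, yr_young_src)
    comp = None
    if column._comp is not None:
        comp = np.zeros((n_groups, 3))
        np.add.at(comp, group, column.components)
    column._replace(m, m0, yr, yr_old, yr_young, comp)


def excavate_ditch(column: Column, depth: float):
    """Remove the top ``depth`` m of peat and convert the column to a ditch.

    The topmost partially-intersected cohort is split pro-rata by thickness.
    The column becomes a fixed-head (Dirichlet) node with its water level at
    the new surface (the ditch bottom) and stops receiving litter while the
    ditch is open.  Returns the removed dry mass (g m-2).
    """
    if depth < 0:
        raise ValueError("ditch depth must be >= 0")
    if depth == 0.0:
        return 0.0
    if depth >= column.height:
        raise ExcavationError(
            f"ditch depth {depth} m >= column height {column.height:.3f} m"
        )
    thick = column.thickness
    depth_from_top = np.cumsum(thick[::-1])[::-1]  # depth of each cohort's bottom...
    # depth_from_top[i] = summed thickness of cohort i and everything above it.
    rho = column.params.dry_bulk_density
    removed = 0.0
    keep = column.n
    for i in range(column.n - 1, -1, -1):
        above = depth_from_top[i] - thick[i]  # peat above cohort i (already removed)
        if above >= depth:
            break
        take = min(thick[i], depth - above)
        frac = take / thick[i] if thick[i] > 0 else 1.0
        if frac >= 1.0:
            removed += column._m[i]
            keep = i
        else:
            removed += column._m[i] * frac
            column._m[i] *= 1.0 - frac
            column._m0[i] *= 1.0 - frac  # keep m/m0 (decomposition state) unchanged
            if column._comp is not None:
                column._comp[i] *= 1.0 - frac
            keep = i + 1
            break
    column.n = keep
    column.boundary_kind = FIXED_HEAD
    column.fixed_head = column.surface_elevation
    column.water_table_elevation = column.fixed_head
    column.receives_litter = False
    return float(removed)
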