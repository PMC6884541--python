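"""Transect hydrology: weekly Boussinesq-type water-table dynamics.

The transect is a line of peat columns on a flat impermeable base.  Lateral
saturated flow between adjacent columns follows Darcy's law with a
depth-integrated transmissivity of the saturated part of each cohort
profile; storage changes are divided by the drainable porosity.  The centre
of the bog is a no-flow (symmetry) boundary; the margin face is a Dirichlet
(fixed-head) lagg, and ditch columns are interior Dirichlet nodes.

Within each week the explicit update is sub-stepped for stability
(dt <= s dx^2 / (2 T_max), with a safety factor).  Water tables are capped
at the peat surface with the excess recorded as runoff, and floored at the
base (evapotranspiration demand that cannot be met is recorded).

Face transmissivities are arithmetic means of the nodal depth-integrated
transmissivities; for a homogeneous profile this reduces the scheme to the
classic Dupuit finite-difference form whose steady state matches the
closed-form solution at the nodes.  The inner loop is compiled with numba
and can advance a whole year (52 weeks) per call; `weekly_step` exposes the
single-week operation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .column import Column, FIXED_HEAD
from .params import ModelParams

__all__ = ["Transect", "HydrologyError", "hydro_step", "WeekDiagnostics"]

#: Vertical resolution (m) of the per-column transmissivity lookup grid.
T_GRID_DZ = 0.01


class HydrologyError(RuntimeError):
    """Raised when a weekly step cannot be integrated stably."""


@njit(cache=False)
def _interp_t(tgrid, i, z, dz):
    if z <= 0.0:
        return 0.0
    nz = tgrid.shape[1]
    pos = z / dz
    k = int(pos)
    if k >= nz - 1:
        return tgrid[i, nz - 1]
    w = pos - k
    return tgrid[i, k] * (1.0 - w) + tgrid[i, k + 1] * w


@njit(cache=False)
def _weeks_kernel(h, surface, base, fixed, tgrid, dz, recharge_weeks,
                  dt_week, n_sub, porosity, dx, lagg_head, wt_out,
                  recharge_applied, lateral_net, runoff, boundary_absorbed,
                  lagg_absorbed):
    """Advance several weeks of sub-stepped explicit Boussinesq flow.

    ``recharge_weeks`` holds one uniform recharge rate (m water / wk) per
    week; fixed-head nodes receive none.  ``wt_out[w]`` receives the head
    profile at the end of week ``w``.  Diagnostic arrays accumulate metres
    of water per unit plan area over all weeks; ``boundary_absorbed`` is
    positive where a fixed-head node takes water out of the modelled
    storage, ``lagg_absorbed[0]`` likewise for the margin face.
    """
    n = h.size
    n_weeks = recharge_weeks.size
    dt = dt_week / n_sub
    t_node = np.empty(n)
    flux = np.empty(n)  # net lateral inflow rate per column (m water / wk)
    for week in range(n_weeks):
        r_week = recharge_weeks[week]
        for _ in range(n_sub):
            for i in range(n):
                t_node[i] = _interp_t(tgrid, i, h[i] - base[i], dz)
            # margin-column transmissivity at the lagg level: the margin
            # face then uses the Dupuit ghost-node average
            t_lagg = _interp_t(tgrid, n - 1, lagg_head - base[n - 1], dz)
            for i in range(n):
                f = 0.0
                if i > 0:
                    tf = 0.5 * (t_node[i - 1] + t_node[i])
                    f += tf * (h[i - 1] - h[i]) / dx
                if i < n - 1:
                    tf = 0.5 * (t_node[i] + t_node[i + 1])
                    f += tf * (h[i + 1] - h[i]) / dx
                else:
                    tf = 0.5 * (t_node[i] + t_lagg)
                    lagg_flux = tf * (lagg_head - h[i]) / (0.5 * dx)
                    f += lagg_flux
                    lagg_absorbed[0] -= lagg_flux * dt / dx
                flux[i] = f / dx
            for i in range(n):
                if fixed[i]:
                    # Dirichlet node: head unchanged; it absorbs (or
                    # supplies) whatever its neighbours exchange with it.
                    boundary_absorbed[i] += flux[i] * dt
                    continue
                lateral_net[i] += flux[i] * dt
                r = r_week
                h_new = h[i] + (flux[i] + r) * dt / porosity
                applied = r * dt
                if h_new < base[i]:
                    applied += (base[i] - h_new) * porosity  # unmet ET
                    h_new = base[i]
                if h_new > surface[i]:
                    runoff[i] += (h_new - surface[i]) * porosity
                    h_new = surface[i]
                recharge_applied[i] += applied
                h[i] = h_new
        for i in range(n):
            wt_out[week, i] = h[i]


class Transect:
    """A line of coupled peat columns with centre-symmetry and a lagg margin."""

    def __init__(self, columns: list[Column], params: ModelParams,
                 column_width_m: float = 2.0):
        if not columns:
            raise ValueError("transect needs at least one column")
        self.columns = columns
        self.params = params
        self.dx = column_width_m
        self.lagg_head = params.lagg_head_m
        self._tgrid: np.ndarray | None = None
        self._t_full: np.ndarray | None = None

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def heads(self) -> np.ndarray:
        return np.array([c.water_table_elevation for c in self.columns])

    @property
    def surfaces(self) -> np.ndarray:
        return np.array([c.surface_elevation for c in self.columns])

    @property
    def bases(self) -> np.ndarray:
        return np.array([c.base_elevation for c in self.columns])

    def refresh_transmissivity(self) -> None:
        """Rebuild per-column transmissivity lookup grids.

        Must be called whenever the cohort structure changes (once per
        simulated year: after decomposition, litter addition, aggregation or
        excavation).  The grid holds cumulative transmissivity (m^2 wk-1)
        against height above the base at ``T_GRID_DZ`` resolution; lookups
        between nodes are linear, matching the exact piecewise-linear
        integral of a layered conductivity profile up to grid resolution.
        """
        zmax = max(float(np.max(self.surfaces - self.bases)), T_GRID_DZ)
        nz = int(np.ceil(zmax / T_GRID_DZ)) + 2
        grid = np.zeros((self.n_columns, nz))
        zs = np.arange(nz) * T_GRID_DZ
        for i, col in enumerate(self.columns):
            if col.n == 0:
                continue
            thick = col.thickness
            tops = np.cumsum(thick)
            cum_t = np.cumsum(col.conductivity * thick)
            grid[i] = np.interp(zs, np.concatenate(([0.0], tops)),
                                np.concatenate(([0.0], cum_t)))
        self._tgrid = grid
        self._t_full = grid[:, -1].copy()

    def _n_substeps(self, dt_weeks: float, safety: float) -> int:
        """Sub-step count from the fully saturated transmissivity bound."""
        t_full = self._t_full
        n = t_full.size
        if n > 1:
            face_max = float(np.max(0.5 * (t_full[:-1] + t_full[1:])))
        else:
            face_max = 0.0
        coeff_max = max(2.0 * face_max, face_max + 2.0 * float(t_full[-1]))
        if coeff_max <= 0.0:
            return 1
        dt_stable = (safety * self.params.drainable_porosity * self.dx**2
                     / coeff_max)
        n_sub = int(np.ceil(dt_weeks / dt_stable))
        if n_sub > self.params.max_substeps_per_week:
            raise HydrologyError(
                f"hydrological step needs {n_sub} substeps (> "
                f"{self.params.max_substeps_per_week}); transmissivity too "
                f"high for stable integration")
        return n_sub

    def run_weeks(self, recharge_weeks_m, dt_weeks: float = 1.0,
                  safety: float = 0.4):
        """Advance one week per entry of ``recharge_weeks_m`` (m water/wk).

        Returns ``(wt_weekly, diag)`` where ``wt_weekly[w, i]`` is column
        ``i``'s water-table elevation at the end of week ``w`` and ``diag``
        accumulates the water budget over all the weeks.
        """
        if self._tgrid is None:
            self.refresh_transmissivity()
        n = self.n_columns
        p = self.params
        h = self.heads
        fixed = np.zeros(n, dtype=np.bool_)
        for i, col in enumerate(self.columns):
            if col.boundary_kind == FIXED_HEAD:
                fixed[i] = True
                h[i] = col.fixed_head
        recharge_weeks = np.atleast_1d(np.asarray(recharge_weeks_m,
                                                  dtype=float))
        n_sub = self._n_substeps(dt_weeks, safety)
        wt_out = np.empty((recharge_weeks.size, n))
        recharge_applied = np.zeros(n)
        lateral_net = np.zeros(n)
        runoff = np.zeros(n)
        boundary_absorbed = np.zeros(n)
        lagg_absorbed = np.zeros(1)
        _weeks_kernel(h, self.surfaces, self.bases, fixed, self._tgrid,
                      T_GRID_DZ, recharge_weeks, dt_weeks, n_sub,
                      p.drainable_porosity, self.dx, self.lagg_head, wt_out,
                      recharge_applied, lateral_net, runoff,
                      boundary_absorbed, lagg_absorbed)
        for i, col in enumerate(self.columns):
            col.water_table_elevation = h[i]
        diag = WeekDiagnostics(recharge_applied, lateral_net, runoff,
                               boundary_absorbed, float(lagg_absorbed[0]),
                               n_sub)
        return wt_out, diag

    def weekly_step(self, recharge_m_per_wk: float, dt_weeks: float = 1.0,
                    safety: float = 0.4) -> "WeekDiagnostics":
        """Advance the water tables by a single week of uniform recharge."""
        _, diag = self.run_weeks(np.array([float(recharge_m_per_wk)]),
                                 dt_weeks, safety)
        return diag


class WeekDiagnostics:
    """Per-column water budget for one or more weekly steps.

    All amounts are metres of water per unit plan area.  For interior
    columns the closure identity

        porosity * (h_end - h_start) = recharge_applied + lateral_net - runoff

    holds to roundoff, and transect-wide
    ``sum(lateral_net) + sum(boundary_absorbed) + lagg_absorbed == 0``.
    """

    __slots__ = ("recharge_applied", "lateral_net", "runoff",
                 "boundary_absorbed", "lagg_absorbed", "n_substeps")

    def __init__(self, recharge_applied, lateral_net, runoff,
                 boundary_absorbed, lagg_absorbed, n_substeps):
        self.recharge_applied = recharge_applied
        self.lateral_net = lateral_net
        self.runoff = runoff
        self.boundary_absorbed = boundary_absorbed
        self.lagg_absorbed = lagg_absorbed
        self.n_substeps = n_substeps


def hydro_step(transect: Transect, weekly_recharge_cm: float,
               dt_weeks: float = 1.0, params: ModelParams | None = None
               ) -> WeekDiagnostics:
    """One week of water-table dynamics; recharge given in cm wk-1."""
    return transect.weekly_step(weekly_recharge_cm / 100.0, dt_weeks)
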