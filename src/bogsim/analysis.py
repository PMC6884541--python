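"""Peat-core statistics: apparent accumulation rates, LORCA, carbon budgets.

A *virtual core* is the end-of-run cohort inventory of one model column,
analysed exactly like a field peat core.  The apparent C accumulation rate
between two sequential layers is

    rate = carbon_fraction * (m_i + m_{i+1}) / 2 / delta_age

i.e. half the summed pair mass divided by the age difference, times the C
fraction of dry peat (0.5 by default).  Because young peat has not finished
decomposing, these apparent rates are strongly inflated near the surface —
the hockey-stick artefact this package exists to demonstrate — so windowed
means (0-200 vs 200-600 yr), the long-term rate LORCA, and the
N - A_o - C_s budget decomposition are provided to quantify it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .column import Column
from .simulate import SimulationResult

__all__ = [
    "VirtualCore", "AccumulationHistory", "CarbonBudgetChange",
    "MalformedCoreError", "EmptyWindowError",
    "extract_core", "apparent_rate_history", "windowed_mean_rate",
    "lorca", "net_balance_series", "thickness_younger_than",
    "core_to_frame", "core_from_frame", "history_to_frame",
]

DEFAULT_CARBON_FRACTION = 0.5


class MalformedCoreError(ValueError):
    """Raised for cores whose layer ages are not usable."""


class EmptyWindowError(ValueError):
    """Raised when an age window contains no history entries."""


@dataclass(frozen=True)
class VirtualCore:
    """Per-layer record of one column, ordered base to top.

    Ages are years before the notional present (the end of the run).
    ``age_old``/``age_young`` bound the deposition span of merged layers;
    ``age`` is the mass-weighted mean.
    """

    age: np.ndarray
    age_old: np.ndarray
    age_young: np.ndarray
    mass: np.ndarray
    initial_mass: np.ndarray
    thickness: np.ndarray

    def __post_init__(self) -> None:
        for name in ("age", "age_old", "age_young", "mass",
                     "initial_mass", "thickness"):
            object.__setattr__(self, name,
                               np.atleast_1d(np.asarray(getattr(self, name),
                                                        dtype=float)))
        if self.age.size == 0:
            raise MalformedCoreError("core has no layers")
        if np.any(self.mass < 0):
            raise MalformedCoreError("layer masses must be >= 0")
        if self.age.size > 1 and not np.all(np.diff(self.age) < 0):
            raise MalformedCoreError(
                "layer ages must decrease strictly from base to top")

    @property
    def n_layers(self) -> int:
        return self.age.size

    @property
    def basal_age(self) -> float:
        return float(self.age_old[0])

    @property
    def total_thickness(self) -> float:
        return float(self.thickness.sum())

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


@dataclass(frozen=True)
class AccumulationHistory:
    """Apparent C accumulation rate against age, one entry per layer pair."""

    age: np.ndarray        # midpoint age of the pair (yr before present)
    rate: np.ndarray       # g C m-2 yr-1
    delta_age: np.ndarray  # yr between the pair's layers (weighting)

    @property
    def n_entries(self) -> int:
        return self.age.size


@dataclass(frozen=True)
class CarbonBudgetChange:
    """N - A_o - C_s decomposition of a column's C-stock change (g C m-2).

    N    : new material still present at the period end,
    A_o  : losses from the original acrotelm (peat above the water table at
           the period start), including any excavated peat,
    C_s  : losses from the original upper catotelm (peat below it).
    ``net`` equals the change in total column C stock over the period.
    """

    new_addition: float
    acrotelm_loss: float
    catotelm_loss: float

    @property
    def net(self) -> float:
        return self.new_addition - self.acrotelm_loss - self.catotelm_loss


def extract_core(column: Column, end_year: int) -> VirtualCore:
    """Virtual core from a column at the end of year ``end_year``."""
    if column.n == 0:
        raise MalformedCoreError("column holds no peat")
    old, young = column.deposition_year_span
    return VirtualCore(
        age=end_year - column.deposition_year,
        age_old=end_year - old + 1.0,   # oldest layer material formed
        age_young=end_year - young,     # youngest material's age
        mass=column.mass.copy(),
        initial_mass=column.initial_mass.copy(),
        thickness=column.thickness.copy(),
    )


def apparent_rate_history(core: VirtualCore,
                          carbon_fraction: float = DEFAULT_CARBON_FRACTION
                          ) -> AccumulationHistory:
    """C accumulation history from sequential layer pairs, base to top.

    The age increment of a pair is the difference of the layers' (mass-
    weighted mean) ages, so merged layers contribute multi-year
    denominators.  Using mean ages keeps the estimator consistent across
    layers of unequal span: a uniform profile yields the same rates before
    and after thin-layer aggregation.
    """
    if core.n_layers < 2:
        raise MalformedCoreError("need at least two layers for a history")
    delta = core.age[:-1] - core.age[1:]
    if np.any(delta <= 0):
        raise MalformedCoreError("non-positive age increment between layers")
    pair_mass = 0.5 * (core.mass[:-1] + core.mass[1:])
    rate = carbon_fraction * pair_mass / delta
    mid_age = 0.5 * (core.age[:-1] + core.age[1:])
    return AccumulationHistory(age=mid_age, rate=rate, delta_age=delta)


def windowed_mean_rate(history: AccumulationHistory, age_lo: float,
                       age_hi: float) -> float:
    """Age-increment-weighted mean rate over entries with midpoint age in
    [age_lo, age_hi)."""
    if not age_lo < age_hi:
        raise ValueError("need age_lo < age_hi")
    mask = (history.age >= age_lo) & (history.age < age_hi)
    if not np.any(mask):
        raise EmptyWindowError(
            f"no history entries in age window [{age_lo}, {age_hi})")
    w = history.delta_age[mask]
    return float(np.dot(history.rate[mask], w) / w.sum())


def lorca(core: VirtualCore,
          carbon_fraction: float = DEFAULT_CARBON_FRACTION) -> float:
    """Long-term rate of C accumulation: total C stock over basal age."""
    if core.basal_age <= 0:
        raise MalformedCoreError("basal age must be > 0")
    return carbon_fraction * core.total_mass / core.basal_age


def thickness_younger_than(core: VirtualCore, age_cutoff: float) -> float:
    """Total thickness (m) of peat younger than ``age_cutoff`` years.

    Layers whose age span straddles the cutoff contribute pro-rata
    (thickness assumed uniform over the span).
    """
    if age_cutoff < 0:
        raise ValueError("age_cutoff must be >= 0")
    old = core.age_old
    young = core.age_young
    span = np.maximum(old - young, 1.0)
    frac = np.clip((age_cutoff - young) / span, 0.0, 1.0)
    return float(np.dot(core.thickness, frac))


def net_balance_series(result: SimulationResult, column_index: int,
                       carbon_fraction: float = DEFAULT_CARBON_FRACTION):
    """Yearly net C stock of a column plus its budget decomposition.

    Returns ``(stock, change)``: ``stock`` is the per-year total C stock
    (g C m-2, one entry per simulated year) and ``change`` the
    :class:`CarbonBudgetChange` over the run's tracked budget period (the
    drainage period in the standard experiment).
    """
    if not 0 <= column_index < result.n_columns:
        raise IndexError(f"column {column_index} outside the transect")
    stock = carbon_fraction * result.total_mass[:, column_index]
    change = None
    if result.budget is not None:
        b = result.budget
        col = result.columns[column_index]
        comp = col.components
        if comp is None:
            raise ValueError("budget components were discarded before analysis")
        new_remaining = float(comp[:, 2].sum())
        change = CarbonBudgetChange(
            new_addition=carbon_fraction * new_remaining,
            acrotelm_loss=carbon_fraction
            * float(b.acro_decay_loss[column_index]
                    + b.acro_excavated[column_index]),
            catotelm_loss=carbon_fraction
            * float(b.cato_decay_loss[column_index]
                    + b.cato_excavated[column_index]),
        )
    return stock, change


# ---------------------------------------------------------------------------
# Tabular I/O

def core_to_frame(core: VirtualCore) -> pd.DataFrame:
    depth_bottom = core.thickness[::-1].cumsum()[::-1]
    return pd.DataFrame({
        "age": core.age, "age_old": core.age_old, "age_young": core.age_young,
        "mass": core.mass, "initial_mass": core.initial_mass,
        "thickness": core.thickness,
        "depth_top": depth_bottom - core.thickness,
        "depth_bottom": depth_bottom,
    })


def core_from_frame(df: pd.DataFrame) -> VirtualCore:
    """Build a core from a layer table (simulator output or user data).

    Requires ``age``, ``mass`` and ``thickness`` columns, base first or top
    first (sorted internally); ``age_old``/``age_young`` and
    ``initial_mass`` are optional.  Field-core conventions are accepted:
    ``dry_mass_per_area`` as an alias for ``mass``, and ``thickness``
    derived from ``depth_top``/``depth_bottom`` when absent.
    """
    df = df.copy()
    if "mass" not in df.columns and "dry_mass_per_area" in df.columns:
        df["mass"] = df["dry_mass_per_area"]
    if ("thickness" not in df.columns and {"depth_top", "depth_bottom"}
            <= set(df.columns)):
        df["thickness"] = df["depth_bottom"] - df["depth_top"]
    for col in ("age", "mass", "thickness"):
        if col not in df.columns:
            raise MalformedCoreError(f"core table missing column {col!r}")
    df = df.sort_values("age", ascending=False)
    age = df["age"].to_numpy(dtype=float)
    return VirtualCore(
        age=age,
        age_old=df.get("age_old", pd.Series(age)).to_numpy(dtype=float),
        age_young=df.get("age_young", pd.Series(age)).to_numpy(dtype=float),
        mass=df["mass"].to_numpy(dtype=float),
        initial_mass=df.get("initial_mass",
                            df["mass"]).to_numpy(dtype=float),
        thickness=df["thickness"].to_numpy(dtype=float),
    )


def history_to_frame(history: AccumulationHistory) -> pd.DataFrame:
    return pd.DataFrame({"age": history.age,
                         "apparent_c_rate": history.rate,
                         "delta_age": history.delta_age})
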