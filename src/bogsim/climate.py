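"""Synthetic climate driver for the bog simulator.

The model is forced by net rainfall (precipitation minus evapotranspiration)
and annual air temperature.  The driver emulates a Holocene-style annual
reconstruction: an AR(1) series for each variable, affinely rescaled so the
sample mean (and standard deviation) hit the configured targets exactly, the
way a single fixed reconstruction would.  Annual net rainfall is then
distributed into 52 weekly depths by a fixed seasonal pattern of proportional
weights; imposing a seasonal cycle lets excess winter water leave the model
as runoff instead of being notionally carried into drier summer weeks.

Weights may be negative in mid-summer weeks where evapotranspiration exceeds
rainfall, producing negative weekly recharge (a water-table drawdown).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SeasonalPattern",
    "AnnualClimateSeries",
    "WeeklyClimateSeries",
    "derive_seasonal_pattern",
    "sinusoidal_pattern",
    "annual_to_weekly",
    "generate_annual_series",
    "default_weekly_climate",
    "write_weekly_csv",
    "read_weekly_csv",
]

N_WEEKS = 52

#: Reference annual means of the default 6,000-year driver (cm yr-1, degC).
DEFAULT_MEAN_NET_RAINFALL_CM = 96.2
DEFAULT_MEAN_TEMPERATURE_C = 7.1

#: Defaults for the stochastic structure of the synthetic reconstruction.
DEFAULT_N_YEARS = 6000
DEFAULT_RAIN_SD_CM = 8.0
DEFAULT_RAIN_AUTOCORR = 0.85
DEFAULT_TEMP_SD_C = 0.4
DEFAULT_TEMP_AUTOCORR = 0.85
#: Seasonal amplitude of the default weekly pattern (dimensionless; values
#: > 1 give a mid-summer evapotranspiration deficit, i.e. negative weeks).
DEFAULT_SEASONAL_AMPLITUDE = 1.8


class InvalidPatternError(ValueError):
    """Raised when 52 weekly observations cannot form a seasonal pattern."""


class ClimateConfigError(ValueError):
    """Raised for invalid climate-generator parameters."""


@dataclass(frozen=True)
class SeasonalPattern:
    """Fixed 52-week proportional pattern used for every simulated year.

    ``weights`` are shares of the annual total, so they sum to one.  Negative
    weights mark weeks in which evapotranspiration exceeds rainfall.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_WEEKS,):
            raise InvalidPatternError(
                f"a seasonal pattern needs exactly {N_WEEKS} weights, got shape {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise InvalidPatternError("seasonal pattern weights must be finite")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvalidPatternError(
                f"seasonal pattern weights must sum to 1, got {w.sum()!r}"
            )
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class AnnualClimateSeries:
    """Annual net rainfall (cm yr-1) and air temperature (degC), year 1..n."""

    net_rainfall_cm: np.ndarray
    temperature_c: np.ndarray

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.net_rainfall_cm, dtype=float))
        t = np.atleast_1d(np.asarray(self.temperature_c, dtype=float))
        if r.shape != t.shape or r.ndim != 1:
            raise ClimateConfigError(
                "net rainfall and temperature must be 1-d arrays of equal length"
            )
        object.__setattr__(self, "net_rainfall_cm", r)
        object.__setattr__(self, "temperature_c", t)

    @property
    def n_years(self) -> int:
        return self.net_rainfall_cm.size

    @property
    def year_index(self) -> np.ndarray:
        return np.arange(1, self.n_years + 1)


@dataclass(frozen=True)
class WeeklyClimateSeries:
    """Per-year weekly net-rainfall depths plus the year's air temperature.

    ``weekly_net_rainfall_cm`` has shape (n_years, 52); row sums equal the
    annual values of the parent :class:`AnnualClimateSeries`.
    """

    weekly_net_rainfall_cm: np.ndarray
    temperature_c: np.ndarray
    pattern: SeasonalPattern = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weekly_net_rainfall_cm, dtype=float)
        t = np.atleast_1d(np.asarray(self.temperature_c, dtype=float))
        if w.ndim != 2 or w.shape[1] != N_WEEKS:
            raise ClimateConfigError(
                f"weekly series must have shape (n_years, {N_WEEKS}), got {w.shape}"
            )
        if w.shape[0] != t.size:
            raise ClimateConfigError("one temperature per year is required")
        object.__setattr__(self, "weekly_net_rainfall_cm", w)
        object.__setattr__(self, "temperature_c", t)

    @property
    def n_years(self) -> int:
        return self.weekly_net_rainfall_cm.shape[0]

    @property
    def annual_net_rainfall_cm(self) -> np.ndarray:
        return self.weekly_net_rainfall_cm.sum(axis=1)


def derive_seasonal_pattern(weekly_observations) -> SeasonalPattern:
    """Build a seasonal pattern from one observed year of 52 weekly depths.

    Each weight is the week's share of the annual total, so multiplying an
    annual value by the 52 weights reproduces a year whose weekly depths sum
    to that value.
    """
    obs = np.asarray(weekly_observations, dtype=float)
    if obs.shape != (N_WEEKS,):
        raise InvalidPatternError(
            f"expected {N_WEEKS} weekly observations, got shape {obs.shape}"
        )
    if not np.all(np.isfinite(obs)):
        raise InvalidPatternError("weekly observations must be finite")
    total = obs.sum()
    if total == 0.0:
        raise InvalidPatternError("weekly observations sum to zero; cannot normalise")
    return SeasonalPattern(obs / total)


def sinusoidal_pattern(amplitude: float = DEFAULT_SEASONAL_AMPLITUDE) -> SeasonalPattern:
    """Parameterised stand-in pattern: winter surplus, summer deficit.

    weight_w = (1 + a cos(2 pi (w - 0.5) / 52)) / 52 for w = 1..52, with the
    cosine peak in the first week of January.  Amplitudes above 1 make the
    mid-summer weeks negative (net evapotranspiration loss).  The weights are
    renormalised so they sum to one at machine precision.
    """
    if not np.isfinite(amplitude):
        raise InvalidPatternError("amplitude must be finite")
    w = np.arange(N_WEEKS)
    weights = (1.0 + amplitude * np.cos(2.0 * np.pi * (w + 0.5) / N_WEEKS)) / N_WEEKS
    return SeasonalPattern(weights / weights.sum())


def annual_to_weekly(annual_value: float, pattern: SeasonalPattern) -> np.ndarray:
    """Distribute one annual depth into 52 weekly depths via the pattern."""
    return annual_value * pattern.weights


def _ar1(n: int, autocorr: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = innov[0] / np.sqrt(1.0 - autocorr**2)
    for i in range(1, n):
        x[i] = autocorr * x[i - 1] + innov[i]
    return x


def _rescaled_ar1(
    n: int, mean: float, sd: float, autocorr: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) draw affinely rescaled to the exact target sample mean and sd."""
    if sd == 0.0:
        return np.full(n, mean)
    x = _ar1(n, autocorr, rng)
    s = x.std()
    if s == 0.0:  # pragma: no cover - degenerate draw
        return np.full(n, mean)
    return mean + sd * (x - x.mean()) / s


def generate_annual_series(
    n_years: int = DEFAULT_N_YEARS,
    mean_rain: float = DEFAULT_MEAN_NET_RAINFALL_CM,
    rain_sd: float = DEFAULT_RAIN_SD_CM,
    rain_autocorr: float = DEFAULT_RAIN_AUTOCORR,
    mean_temp: float = DEFAULT_MEAN_TEMPERATURE_C,
    temp_sd: float = DEFAULT_TEMP_SD_C,
    temp_autocorr: float = DEFAULT_TEMP_AUTOCORR,
    seed: int = 0,
) -> AnnualClimateSeries:
    """Generate the synthetic annual climate reconstruction.

    Both variables are AR(1) processes rescaled so the sample mean equals the
    target mean exactly (and the sample sd the target sd), mimicking the use
    of one fixed reconstruction whose long-term means are known.
    """
    if n_years < 1:
        raise ClimateConfigError("n_years must be >= 1")
    if rain_sd < 0 or temp_sd < 0:
        raise ClimateConfigError("standard deviations must be >= 0")
    if not (abs(rain_autocorr) < 1 and abs(temp_autocorr) < 1):
        raise ClimateConfigError("autocorrelations must satisfy |rho| < 1")
    if n_years == 1:
        # A single year is its own mean.
        return AnnualClimateSeries(np.array([mean_rain]), np.array([mean_temp]))
    rng = np.random.default_rng(seed)
    rain = _rescaled_ar1(n_years, mean_rain, rain_sd, rain_autocorr, rng)
    temp = _rescaled_ar1(n_years, mean_temp, temp_sd, temp_autocorr, rng)
    return AnnualClimateSeries(rain, temp)


def disaggregate(
    annual: AnnualClimateSeries, pattern: SeasonalPattern
) -> WeeklyClimateSeries:
    """Apply the same seasonal pattern to every year of an annual series."""
    weekly = annual.net_rainfall_cm[:, None] * pattern.weights[None, :]
    return WeeklyClimateSeries(weekly, annual.temperature_c, pattern)


def default_weekly_climate(
    n_years: int = DEFAULT_N_YEARS,
    seed: int = 0,
    amplitude: float = DEFAULT_SEASONAL_AMPLITUDE,
    **kwargs,
) -> WeeklyClimateSeries:
    """Default driver: rescaled AR(1) annual series + sinusoidal weekly pattern."""
    annual = generate_annual_series(n_years=n_years, seed=seed, **kwargs)
    return disaggregate(annual, sinusoidal_pattern(amplitude))


def write_weekly_csv(series: WeeklyClimateSeries, path) -> None:
    """Write the weekly driver as CSV (year, week, net_rainfall_cm, temperature_C)."""
    n = series.n_years
    df = pd.DataFrame(
        {
            "year": np.repeat(np.arange(1, n + 1), N_WEEKS),
            "week": np.tile(np.arange(1, N_WEEKS + 1), n),
            "net_rainfall_cm": series.weekly_net_rainfall_cm.ravel(),
            "temperature_C": np.repeat(series.temperature_c, N_WEEKS),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_weekly_csv(path) -> WeeklyClimateSeries:
    """Read a weekly driver CSV written by :func:`write_weekly_csv`."""
    df = pd.read_csv(path)
    required = {"year", "week", "net_rainfall_cm", "temperature_C"}
    missing = required - set(df.columns)
    if missing:
        raise ClimateConfigError(f"climate CSV missing columns: {sorted(missing)}")
    df = df.sort_values(["year", "week"])
    years = df["year"].unique()
    n = years.size
    if len(df) != n * N_WEEKS:
        raise ClimateConfigError("climate CSV must contain 52 weeks for every year")
    weekly = df["net_rainfall_cm"].to_numpy().reshape(n, N_WEEKS)
    temp = df.groupby("year", sort=True)["temperature_C"].first().to_numpy()
    return WeeklyClimateSeries(weekly, temp)
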