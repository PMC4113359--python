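"""Stochastic daily weather generator for a wet-temperate rainforest site.

Rainfall is a marked point process: intervals between events are
exponential with seasonal mean ``1/lambda`` (days) and each event carries
an exponential depth with seasonal mean ``eta`` (mm).  Because exponential
inter-arrivals make the event process Poisson, daily totals are generated
exactly (and fast) as Gamma(N_d, eta) with N_d ~ Poisson(lambda) per day;
an explicit event-level simulator is kept for diagnostics.  Daily mean
temperature is Gaussian per season; daily global radiation is Gaussian
conditioned on the season and on whether the day is wet (P_d >= 1 mm),
truncated at zero.

Simulated seasonal rainfall is normalized, in expectation, to prescribed
long-run seasonal sums so the generator does not overestimate annual
rainfall; the within-season event structure and interannual variability
are preserved (a single multiplicative factor per season).

Drought scenarios rescale the event-depth mean (``eta_factor`` <= 1) and
the inter-arrival mean (``lambda_factor`` >= 1) of the affected (growing)
seasons; prescribed seasonal sums are rescaled consistently by
eta_factor/lambda_factor so normalization does not undo the drought
signal.  A warming scenario adds offsets to the seasonal temperature
means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "SeasonalClimateParams",
    "ClimateParams",
    "ScenarioSpec",
    "WeatherGenerator",
    "apply_scenario",
    "default_climate",
    "season_of_day",
    "WET_DAY_MM",
    "DAYS_PER_YEAR",
]

SEASONS = ("DJF", "MAM", "JJA", "SON")

#: wet/dry classification threshold for radiation conditioning (mm day-1);
#: a day with P_d >= 1 mm counts as wet.
WET_DAY_MM = 1.0

#: fixed-length no-leap year
DAYS_PER_YEAR = 365

_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MONTH_SEASON = ("DJF", "DJF", "MAM", "MAM", "MAM", "JJA", "JJA", "JJA",
                 "SON", "SON", "SON", "DJF")


def _season_index_by_day() -> np.ndarray:
    """Season index (into SEASONS) for Julian days 1..365, Jan 1 = day 1."""
    idx = np.empty(DAYS_PER_YEAR, dtype=np.int64)
    d = 0
    for month, length in enumerate(_MONTH_LENGTHS):
        idx[d:d + length] = SEASONS.index(_MONTH_SEASON[month])
        d += length
    return idx


_SEASON_IDX = _season_index_by_day()
#: number of calendar days per season in a 365-day year
SEASON_DAYS = {s: int(np.sum(_SEASON_IDX == i)) for i, s in enumerate(SEASONS)}


def season_of_day(julian_day: int | np.ndarray) -> np.ndarray | str:
    """Season tag for Julian day(s) 1..365 (calendar-month assignment)."""
    j = np.asarray(julian_day)
    if np.any((j < 1) | (j > DAYS_PER_YEAR)):
        raise ValueError("julian_day must be in 1..365")
    tags = np.asarray(SEASONS)[_SEASON_IDX[j - 1]]
    return tags if tags.ndim else tags.item()


@dataclass(frozen=True)
class SeasonalClimateParams:
    """Weather-generator parameters for one season.

    mean_interval is the mean time between rainfall events, 1/lambda (days);
    mean_event_depth is the mean depth per event, eta (mm).  prescribed_rain
    is the long-run mean seasonal rainfall sum (mm) that normalization
    targets.  Radiation means/sds are conditioned on dry (P_d < 1 mm) vs
    wet days, in umol photons m-2 s-1.
    """

    season: str
    mean_interval: float
    mean_event_depth: float
    prescribed_rain: float
    temp_mu: float
    temp_sigma: float
    rg_mu_dry: float
    rg_sigma_dry: float
    rg_mu_wet: float
    rg_sigma_wet: float

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if not self.mean_interval > 0:
            raise ValueError(
                f"{self.season}: mean_interval (1/lambda) must be > 0")
        # eta = 0 is permitted as the degenerate no-rain limit
        if self.mean_event_depth < 0:
            raise ValueError(
                f"{self.season}: mean_event_depth (eta) must be >= 0")
        if self.prescribed_rain < 0:
            raise ValueError(f"{self.season}: prescribed_rain must be >= 0")
        for name in ("temp_sigma", "rg_sigma_dry", "rg_sigma_wet"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.season}: {name} must be >= 0")

    @property
    def events_per_day(self) -> float:
        """Poisson event rate lambda (events day-1)."""
        return 1.0 / self.mean_interval

    def expected_raw_season_sum(self) -> float:
        """Expected un-normalized rainfall sum over one season (mm)."""
        return SEASON_DAYS[self.season] * self.events_per_day * self.mean_event_depth


@dataclass(frozen=True)
class ClimateParams:
    """Full seasonal parameter set (exactly one block per season)."""

    seasons: Mapping[str, SeasonalClimateParams]

    def __post_init__(self) -> None:
        missing = [s for s in SEASONS if s not in self.seasons]
        if missing:
            raise ValueError(f"missing seasons: {missing}")
        for tag, p in self.seasons.items():
            if p.season != tag:
                raise ValueError(f"season key {tag!r} holds params for {p.season!r}")

    def __getitem__(self, season: str) -> SeasonalClimateParams:
        return self.seasons[season]

    def per_day(self, attr: str) -> np.ndarray:
        """Value of a seasonal attribute for each Julian day 1..365."""
        vals = np.array([getattr(self.seasons[s], attr) for s in SEASONS])
        return vals[_SEASON_IDX]


# Current-climate parameterization for the north Chiloe study site
# (weather-station records 1998-2009).
_CURRENT = {
    # season: (1/lambda, eta, prescribed sum, T_mu, T_sigma,
    #          Rg_mu_dry, Rg_sd_dry, Rg_mu_wet, Rg_sd_wet)
    "DJF": (0.90, 8.3, 284.6, 12.5, 2.6, 1413.9, 317.0, 986.9, 378.2),
    "MAM": (0.55, 12.8, 543.6, 10.1, 3.6, 701.2, 294.1, 398.8, 261.6),
    "JJA": (0.29, 16.0, 813.4, 8.4, 4.4, 408.9, 159.1, 229.7, 139.4),
    "SON": (0.54, 9.5, 424.5, 9.8, 3.3, 1065.5, 348.7, 640.8, 320.1),
}

#: seasonal mean-temperature offsets (degC) of the 2100 warming scenario
WARMING_2100 = {"DJF": 4.0, "MAM": 3.0, "JJA": 2.0, "SON": 2.0}

#: seasons whose rainfall the drought scenarios modify (growing season)
GROWING_SEASONS = ("DJF", "SON")


def default_climate() -> ClimateParams:
    """Current-climate parameter set for the study site."""
    return ClimateParams({
        s: SeasonalClimateParams(s, *_CURRENT[s]) for s in SEASONS
    })


@dataclass(frozen=True)
class ScenarioSpec:
    """Multiplicative drought factors and optional warming offsets.

    The documented drought grid spans eta_factor in [0.5, 1.0] and
    lambda_factor in [1.0, 1.5]; values outside that range are accepted
    with a warning (they remain meaningful, just unexplored).
    """

    eta_factor: float = 1.0
    lambda_factor: float = 1.0
    warming_offsets: Mapping[str, float] | None = None
    affected_seasons: tuple[str, ...] = GROWING_SEASONS

    def __post_init__(self) -> None:
        if self.eta_factor < 0 or self.lambda_factor <= 0:
            raise ValueError("scenario factors must be positive")
        for s in self.affected_seasons:
            if s not in SEASONS:
                raise ValueError(f"unknown season {s!r} in affected_seasons")

    @property
    def is_baseline(self) -> bool:
        return (self.eta_factor == 1.0 and self.lambda_factor == 1.0
                and not self.warming_offsets)


def apply_scenario(climate: ClimateParams, scenario: ScenarioSpec) -> ClimateParams:
    """Return new climate parameters with the scenario applied.

    eta and 1/lambda of the affected seasons are multiplied by the scenario
    factors, and the prescribed seasonal sums are rescaled by the implied
    change in expected raw rainfall (eta_factor / lambda_factor) so that
    normalization preserves the drought signal.  Warming offsets shift the
    seasonal temperature means of every season they name.
    """
    import warnings

    if not (0.5 <= scenario.eta_factor <= 1.0 and
            1.0 <= scenario.lambda_factor <= 1.5):
        warnings.warn(
            "scenario factors outside the documented grid "
            f"(eta_factor={scenario.eta_factor}, "
            f"lambda_factor={scenario.lambda_factor})", stacklevel=2)
    new = {}
    offsets = scenario.warming_offsets or {}
    for tag in SEASONS:
        p = climate[tag]
        if tag in scenario.affected_seasons:
            p = replace(
                p,
                mean_event_depth=p.mean_event_depth * scenario.eta_factor,
                mean_interval=p.mean_interval * scenario.lambda_factor,
                prescribed_rain=p.prescribed_rain
                * scenario.eta_factor / scenario.lambda_factor,
            )
        if tag in offsets:
            p = replace(p, temp_mu=p.temp_mu + offsets[tag])
        new[tag] = p
    return ClimateParams(new)


class NormalizationError(ValueError):
    """A season generates no rain but has a positive prescribed sum."""


class WeatherGenerator:
    """Daily weather series generator.

    Parameters
    ----------
    climate
        Seasonal parameter set (see :func:`default_climate`).
    normalize
        Rescale each season's rainfall so the long-run mean seasonal sum
        equals the prescribed value (single analytic factor per season).
    """

    def __init__(self, climate: ClimateParams | None = None,
                 normalize: bool = True) -> None:
        self.climate = climate if climate is not None else default_climate()
        self.normalize = normalize

    # -- normalization -------------------------------------------------

    def normalization_factors(self) -> dict[str, float]:
        """Per-season multiplicative factor prescribed/expected-raw."""
        factors = {}
        for tag in SEASONS:
            p = self.climate[tag]
            raw = p.expected_raw_season_sum()
            if raw <= 0:
                if p.prescribed_rain > 0:
                    raise NormalizationError(
                        f"{tag}: zero expected rainfall cannot be normalized "
                        f"to prescribed sum {p.prescribed_rain} mm")
                factors[tag] = 1.0
            else:
                factors[tag] = p.prescribed_rain / raw
        return factors

    @staticmethod
    def normalize_seasonal_rainfall(rain: np.ndarray,
                                    factors: Mapping[str, float]) -> np.ndarray:
        """Apply per-season multiplicative factors to a daily rainfall series."""
        rain = np.asarray(rain, dtype=float)
        n_years, rem = divmod(rain.size, DAYS_PER_YEAR)
        if rem:
            raise ValueError("rainfall series length must be a multiple of 365")
        fac = np.array([factors[s] for s in SEASONS])[_SEASON_IDX]
        return rain * np.tile(fac, n_years)

    # -- generation ----------------------------------------------------

    def generate_rainfall(self, n_years: int,
                          rng: np.random.Generator) -> np.ndarray:
        """Raw (un-normalized) daily rainfall for n_years x 365 days.

        Daily totals are Gamma(N, eta) with N ~ Poisson(lambda); multiple
        events within one day accumulate into a single P_d.
        """
        if n_years < 1:
            raise ValueError("n_years must be >= 1")
        lam = np.tile(self.climate.per_day("events_per_day"), n_years)
        eta = np.tile(self.climate.per_day("mean_event_depth"), n_years)
        counts = rng.poisson(lam)
        return rng.standard_gamma(counts) * eta

    def generate_temperature(self, n_years: int,
                             rng: np.random.Generator) -> np.ndarray:
        """Daily mean temperature, Normal(T_mu, T_sigma) of the day's season."""
        mu = np.tile(self.climate.per_day("temp_mu"), n_years)
        sd = np.tile(self.climate.per_day("temp_sigma"), n_years)
        return mu + sd * rng.standard_normal(mu.size)

    def generate_radiation(self, rain: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
        """Daily global radiation conditioned on wet/dry status, floored at 0."""
        rain = np.asarray(rain, dtype=float)
        n_years, rem = divmod(rain.size, DAYS_PER_YEAR)
        if rem:
            raise ValueError("rainfall series length must be a multiple of 365")
        wet = rain >= WET_DAY_MM
        mu = np.where(wet, np.tile(self.climate.per_day("rg_mu_wet"), n_years),
                      np.tile(self.climate.per_day("rg_mu_dry"), n_years))
        sd = np.where(wet, np.tile(self.climate.per_day("rg_sigma_wet"), n_years),
                      np.tile(self.climate.per_day("rg_sigma_dry"), n_years))
        # one Gaussian draw per day regardless of wet/dry keeps scenario
        # runs coupled under common random numbers
        return np.clip(mu + sd * rng.standard_normal(mu.size), 0.0, None)

    def generate(self, n_years: int,
                 seed: int | np.random.Generator | np.random.SeedSequence = 0,
                 ) -> pd.DataFrame:
        """Generate a full daily weather series.

        Returns a DataFrame with columns year, julian_day, season, rain_mm,
        temp_c, rg_umol_m2_s.  Identical (climate, seed) gives an identical
        series.
        """
        rng = np.random.default_rng(seed)
        rain = self.generate_rainfall(n_years, rng)
        if self.normalize:
            rain = self.normalize_seasonal_rainfall(
                rain, self.normalization_factors())
        temp = self.generate_temperature(n_years, rng)
        rg = self.generate_radiation(rain, rng)
        jd = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
        return pd.DataFrame({
            "year": np.repeat(np.arange(1, n_years + 1), DAYS_PER_YEAR),
            "julian_day": jd,
            "season": np.asarray(SEASONS)[np.tile(_SEASON_IDX, n_years)],
            "rain_mm": rain,
            "temp_c": temp,
            "rg_umol_m2_s": rg,
        })

    # -- event-level diagnostics ----------------------------------------

    def rain_events(self, n_events: int, rng: np.random.Generator,
                    start_day: float = 0.0) -> pd.DataFrame:
        """Simulate individual rainfall events (for diagnostics/fixtures).

        Event times advance by exponential inter-arrival intervals with the
        mean 1/lambda of the season the event lands in; each event carries
        an exponential depth with that season's mean eta.  Returns columns
        time_d, season, interval_d, depth_mm.
        """
        interval_by_day = self.climate.per_day("mean_interval")
        eta_by_day = self.climate.per_day("mean_event_depth")
        t = float(start_day)
        times, seasons, intervals, depths = [], [], [], []
        for _ in range(n_events):
            day = int(t) % DAYS_PER_YEAR
            tau = rng.exponential(interval_by_day[day])
            t += tau
            day = int(t) % DAYS_PER_YEAR
            depth = rng.exponential(eta_by_day[day]) if eta_by_day[day] > 0 else 0.0
            times.append(t)
            seasons.append(SEASONS[_SEASON_IDX[day]])
            intervals.append(tau)
            depths.append(depth)
        return pd.DataFrame({"time_d": times, "season": seasons,
                             "interval_d": intervals, "depth_mm": depths})


def seasonal_sums(weather: pd.DataFrame) -> pd.DataFrame:
    """Rainfall sum per (year, season) from a generated weather frame."""
    return (weather.groupby(["year", "season"], observed=True)["rain_mm"]
            .sum().reset_index())
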