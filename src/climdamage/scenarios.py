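"""Synthetic probabilistic socioeconomic and emissions ensembles.

This module generates RFF-SP-like ensembles: paired annual trajectories of
global greenhouse-gas emissions (CO2, CH4, N2O), US GDP and US population on
the 2020-2300 grid, plus the disaggregation of national population to the
seven CONUS damage regions.

The generator is a stand-in for the real expert-elicitation product, built
from three coupled stochastic blocks:

* **Per-capita GDP growth** -- each trajectory draws a long-run growth path
  ``mu_i(t)`` that relaxes exponentially from an initial to an asymptotic
  per-scenario mean, plus persistent AR(1) noise.  This produces fan-shaped
  growth uncertainty whose ensemble-average time-averaged growth declines
  from ~1.5 %/yr (2020-2100) to ~0.9 %/yr (2020-2300).
* **Population** -- a peak-and-decline process: the annual population growth
  rate declines linearly from a stochastic initial rate through zero at a
  stochastic peak year; after the peak the decline rate itself relaxes back
  toward zero, so trajectories shrink and then stabilise over the
  multi-century horizon rather than decaying exponentially forever.
* **Emissions** -- CO2 = GDP x carbon intensity, where intensity follows a
  stochastic exponential decline that may cross zero (net-negative
  emissions).  CH4 and N2O scale with the same latent decarbonisation
  factor, so all three gases are positively correlated, but stay
  non-negative.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
instance, so a given ``(n, seed, calibration)`` triple is reproducible
bit-for-bit across runs and platforms.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError, InvalidCalibrationError
from .trajectories import Trajectory, default_years

__all__ = [
    "GeneratorCalibration",
    "Scenario",
    "ScenarioSet",
    "RegionalShares",
    "generate_scenario_set",
    "disaggregate_population",
    "default_regional_shares",
    "read_scenarios",
    "write_scenarios",
]

#: CONUS damage regions, in canonical order.
REGIONS = (
    "Midwest",
    "Northeast",
    "Northern Plains",
    "Northwest",
    "Southeast",
    "Southern Plains",
    "Southwest",
)

_SCENARIO_COLUMNS = ("scenario_id", "year", "co2_gtc", "ch4_mt",
                     "n2o_mt", "gdp", "population")


@dataclass(frozen=True)
class GeneratorCalibration:
    """Hyperparameters of the synthetic ensemble generator.

    Defaults are calibrated so that a 10 000-member ensemble reproduces the
    published summary moments of the scenario set it emulates (population
    mean/CI in 2100 and 2300; time-averaged per-capita GDP growth to 2100
    and 2300).  Units: rates are fractional per year, population in
    persons, GDP in constant 2015 USD, emissions in GtC (CO2) or Mt of
    gas (CH4, N2O).
    """

    # --- initial conditions (2020) ---
    pop0: float = 331.5e6               # US population, persons
    gdppc0: float = 58_000.0            # US GDP per capita, 2015 USD
    co2_0: float = 10.2                 # global CO2 emissions, GtC/yr
    ch4_0: float = 380.0                # global CH4 emissions, Mt/yr
    n2o_0: float = 10.0                 # global N2O emissions, Mt/yr

    # --- per-capita GDP growth process ---
    mu0_mean: float = 0.0185            # initial long-run growth mean
    mu0_sd: float = 0.011               # across-scenario dispersion
    mu_inf_mean: float = 0.004          # asymptotic long-run growth mean
    mu_inf_beta: float = 0.5            # regression of mu_inf on mu0
    mu_tau: float = 120.0               # e-folding of mu(t), years
    ar1_phi: float = 0.9                # AR(1) persistence of annual noise
    ar1_sd: float = 0.01                # stationary sd of annual noise

    # --- population peak-and-decline process ---
    pop_g0_mean: float = 0.0058         # initial population growth rate
    pop_g0_sd: float = 0.0025
    pop_peak_mean: float = 2088.0       # peak year
    pop_peak_sd: float = 45.0
    pop_decline_max: float = 0.007      # initial post-peak decline rate
                                        # (drawn U(0, max) per scenario)
    pop_decline_tau: float = 60.0      # e-folding (years) of the decline
                                        # rate after the peak: populations
                                        # stabilise rather than shrink
                                        # exponentially forever

    # --- emissions intensity process ---
    intensity_decline_mean: float = 0.018   # initial intensity decline rate /yr
    intensity_decline_sd: float = 0.009
    intensity_rate_tau: float = 200.0       # e-folding (years) of the decline
                                            # rate itself: decarbonisation
                                            # decelerates over centuries
    intensity_floor_scale: float = 0.02     # mean of the (exponential)
                                            # net-negative asymptote draw,
                                            # as a fraction of initial
                                            # intensity
    emissions_gdp_elasticity: float = 0.4   # d ln E / d ln GDP at fixed
                                            # intensity decline: richer
                                            # economies decarbonise, so
                                            # emissions grow sub-linearly
                                            # with output
    cdr_cap_max: float = 3.0                # per-scenario cap on net CO2
                                            # removal, GtC/yr (drawn
                                            # U(0, max))
    ch4_co2_coupling: float = 1.0           # exponent tying CH4 to the
    n2o_co2_coupling: float = 0.7           # ... and N2O to the latent
                                            # decarbonisation factor

    def validate(self) -> None:
        vals = asdict(self)
        for name, v in vals.items():
            if not np.isfinite(v):
                raise InvalidCalibrationError(f"hyperparameter {name} is not finite")
        for name in ("mu0_sd", "ar1_sd", "pop_g0_sd", "pop_peak_sd",
                     "pop_decline_max", "intensity_decline_sd",
                     "intensity_floor_scale"):
            if vals[name] < 0:
                raise InvalidCalibrationError(f"dispersion {name} must be >= 0")
        if not (0 <= self.ar1_phi < 1):
            raise InvalidCalibrationError("ar1_phi must be in [0, 1)")
        for name in ("pop0", "gdppc0", "co2_0", "ch4_0", "n2o_0"):
            if vals[name] <= 0:
                raise InvalidCalibrationError(f"initial condition {name} must be > 0")


@dataclass(frozen=True)
class Scenario:
    """One paired emissions/GDP/population trajectory."""

    id: str
    co2: Trajectory          # GtC/yr, may be negative
    ch4: Trajectory          # Mt/yr, >= 0
    n2o: Trajectory          # Mt/yr, >= 0
    gdp: Trajectory          # 2015 USD/yr, > 0
    population: Trajectory   # persons, > 0

    def __post_init__(self):
        grids = [self.co2, self.ch4, self.n2o, self.gdp, self.population]
        for t in grids[1:]:
            if not grids[0].same_grid(t):
                raise InvalidArgumentError(
                    f"scenario {self.id}: trajectories on different year grids")
        if np.any(self.population.values <= 0):
            raise InvalidArgumentError(f"scenario {self.id}: population must be > 0")
        if np.any(self.gdp.values <= 0):
            raise InvalidArgumentError(f"scenario {self.id}: gdp must be > 0")
        if np.any(self.ch4.values < 0) or np.any(self.n2o.values < 0):
            raise InvalidArgumentError(
                f"scenario {self.id}: CH4/N2O emissions must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return self.co2.years


class ScenarioSet:
    """Ordered ensemble of scenarios on a common year grid.

    Data are stored as dense ``(n, n_years)`` arrays; per-scenario
    :class:`Scenario` views are materialised on access.  This keeps
    10 000-member ensembles cheap to generate and to feed to the
    vectorised climate emulator.
    """

    def __init__(self, ids: Sequence[str], years: np.ndarray,
                 co2: np.ndarray, ch4: np.ndarray, n2o: np.ndarray,
                 gdp: np.ndarray, population: np.ndarray,
                 seed: int | None = None,
                 calibration: GeneratorCalibration | None = None):
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise InvalidArgumentError("scenario ids must be unique")
        self.years = np.asarray(years, dtype=int)
        arrays = {"co2": co2, "ch4": ch4, "n2o": n2o,
                  "gdp": gdp, "population": population}
        for name, a in arrays.items():
            a = np.asarray(a, dtype=float)
            if a.shape != (len(self.ids), len(self.years)):
                raise InvalidArgumentError(
                    f"{name} array has shape {a.shape}, expected "
                    f"({len(self.ids)}, {len(self.years)})")
            arrays[name] = a
        self.co2 = arrays["co2"]
        self.ch4 = arrays["ch4"]
        self.n2o = arrays["n2o"]
        self.gdp = arrays["gdp"]
        self.population = arrays["population"]
        self.seed = seed
        self.calibration = calibration

    def __len__(self) -> int:
        return len(self.ids)

    def scenario(self, i: int) -> Scenario:
        mk = lambda a, u: Trajectory(self.years, a[i], units=u)
        return Scenario(
            id=self.ids[i],
            co2=mk(self.co2, "GtC/yr"),
            ch4=mk(self.ch4, "Mt/yr"),
            n2o=mk(self.n2o, "Mt/yr"),
            gdp=mk(self.gdp, "2015 USD/yr"),
            population=mk(self.population, "persons"),
        )

    def __iter__(self) -> Iterator[Scenario]:
        return (self.scenario(i) for i in range(len(self)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScenarioSet):
            return NotImplemented
        return (self.ids == other.ids
                and np.array_equal(self.years, other.years)
                and all(np.array_equal(getattr(self, k), getattr(other, k))
                        for k in ("co2", "ch4", "n2o", "gdp", "population")))


def generate_scenario_set(
    n: int,
    seed: int,
    calib: GeneratorCalibration | None = None,
) -> ScenarioSet:
    """Draw ``n`` paired emissions/GDP/population trajectories, 2020-2300.

    Identical ``(n, seed, calib)`` produce identical output.  See the
    module docstring for the generative model.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    calib = calib or GeneratorCalibration()
    calib.validate()
    rng = np.random.default_rng(seed)
    years = default_years()
    T = len(years)
    t_rel = np.arange(T)  # years since 2020

    # ---- per-capita GDP growth -------------------------------------
    mu0 = rng.normal(calib.mu0_mean, calib.mu0_sd, size=n)
    mu_inf = calib.mu_inf_mean + calib.mu_inf_beta * (mu0 - calib.mu0_mean)
    decay = np.exp(-t_rel / calib.mu_tau)                       # (T,)
    mu = mu_inf[:, None] + (mu0 - mu_inf)[:, None] * decay[None, :]

    eps = np.empty((n, T))
    innov_sd = calib.ar1_sd * np.sqrt(1.0 - calib.ar1_phi ** 2)
    eps[:, 0] = rng.normal(0.0, calib.ar1_sd, size=n)
    shocks = rng.normal(0.0, innov_sd, size=(n, T - 1))
    for t in range(1, T):
        eps[:, t] = calib.ar1_phi * eps[:, t - 1] + shocks[:, t - 1]
    growth = mu + eps                                           # g_t, (n, T)
    # growth[:, t] is the growth applied from year t-1 to t; the 2020 column
    # is kept for reporting but gdppc(2020) is the anchor value.
    log_gdppc = np.cumsum(np.log1p(np.clip(growth, -0.5, None)), axis=1)
    log_gdppc -= log_gdppc[:, [0]]
    gdppc = calib.gdppc0 * np.exp(log_gdppc)

    # ---- population ------------------------------------------------
    g0 = rng.normal(calib.pop_g0_mean, calib.pop_g0_sd, size=n)
    peak = rng.normal(calib.pop_peak_mean, calib.pop_peak_sd, size=n)
    peak = np.clip(peak, 2030.0, 2290.0)
    decline = rng.uniform(0.0, calib.pop_decline_max, size=n)
    span = peak[:, None] - 2020.0
    rate = g0[:, None] * (peak[:, None] - years[None, :]) / span
    # post-peak floor: a decline rate that itself relaxes to zero, so
    # populations stabilise over the multi-century horizon
    past_peak = np.maximum(years[None, :] - peak[:, None], 0.0)
    floor = -decline[:, None] * np.exp(-past_peak / calib.pop_decline_tau)
    # declining-from-the-start draws (g0 < 0) flatten out at zero growth
    # instead of turning the peak year into a trough
    rate = np.clip(rate, floor, np.maximum(g0, 0.0)[:, None])
    log_pop = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(rate[:, :-1], axis=1)], axis=1)
    population = calib.pop0 * np.exp(log_pop)

    gdp = gdppc * population

    # ---- emissions -------------------------------------------------
    r_dec = rng.normal(calib.intensity_decline_mean,
                       calib.intensity_decline_sd, size=n)
    floor = rng.exponential(calib.intensity_floor_scale, size=n)
    cdr_cap = rng.uniform(0.0, calib.cdr_cap_max, size=n)
    # decarbonisation decelerates: the exponent saturates on a multi-century
    # timescale instead of growing linearly forever
    s_t = calib.intensity_rate_tau * (
        1.0 - np.exp(-t_rel / calib.intensity_rate_tau))
    latent = np.exp(-np.maximum(r_dec, 0.0)[:, None] * s_t[None, :])
    # intensity relative to 2020; may cross zero when floor > 0
    rel_intensity = (1.0 + floor[:, None]) * np.exp(
        -r_dec[:, None] * s_t[None, :]) - floor[:, None]
    gdp0 = calib.gdppc0 * calib.pop0
    i0 = calib.co2_0 / gdp0
    # intensity also falls as output grows (decoupling): the GDP factor in
    # emissions enters with elasticity < 1
    phi = calib.emissions_gdp_elasticity
    intensity = i0 * (gdp / gdp0) ** (phi - 1.0) * rel_intensity
    # net removal is bounded by a per-scenario carbon-dioxide-removal
    # capacity rather than scaling indefinitely with GDP
    co2 = np.maximum(gdp * intensity, -cdr_cap[:, None])
    ch4 = calib.ch4_0 * latent ** calib.ch4_co2_coupling
    n2o = calib.n2o_0 * latent ** calib.n2o_co2_coupling

    ids = [f"s{i:05d}" for i in range(n)]
    return ScenarioSet(ids, years, co2, ch4, n2o, gdp, population,
                       seed=seed, calibration=calib)


# ----------------------------------------------------------------------
# Regional disaggregation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RegionalShares:
    """Share of national population in each of the seven regions per year.

    Shares cover 2020-2090; the last available year's shares are reused
    for later years (regional proportions held constant after 2090).
    """

    regions: tuple
    years: np.ndarray                  # (m,), 2020..2090
    shares: np.ndarray                 # (7, m), columns sum to 1

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "shares", np.asarray(self.shares, dtype=float))
        if len(self.regions) != 7:
            raise InvalidArgumentError(
                f"exactly 7 regions required, got {len(self.regions)}")
        if self.shares.shape != (7, len(self.years)):
            raise InvalidArgumentError("share matrix shape mismatch")
        if np.any(self.shares < 0):
            raise InvalidArgumentError("shares must be >= 0")
        col = self.shares.sum(axis=0)
        if np.any(np.abs(col - 1.0) > 1e-9):
            raise InvalidArgumentError("regional shares must sum to 1 each year")

    def share_matrix(self, years: np.ndarray) -> np.ndarray:
        """Shares aligned to an arbitrary year grid, holding the final
        year's shares constant beyond the table."""
        idx = np.clip(np.searchsorted(self.years, years), 0, len(self.years) - 1)
        # searchsorted gives the insertion point; for years present in the
        # table it is exact, for later years it saturates at the last column
        exact = np.isin(years, self.years)
        idx = np.where(exact, idx, len(self.years) - 1)
        return self.shares[:, idx]


# Endpoint shares used for the packaged default table: a coarse rendering
# of observed 2020 regional population distribution drifting modestly
# toward the South and West by 2090.
_SHARES_2020 = np.array([0.2094, 0.1773, 0.0162, 0.0424,
                         0.2632, 0.1041, 0.1874])
_SHARES_2090 = np.array([0.1780, 0.1550, 0.0150, 0.0500,
                         0.2950, 0.1200, 0.1870])


def default_regional_shares() -> RegionalShares:
    """Packaged default share table (linear drift 2020->2090)."""
    yrs = np.arange(2020, 2091)
    w = (yrs - 2020) / 70.0
    shares = (_SHARES_2020[:, None] * (1 - w[None, :])
              + _SHARES_2090[:, None] * w[None, :])
    shares /= shares.sum(axis=0, keepdims=True)
    return RegionalShares(REGIONS, yrs, shares)


def read_regional_shares(path) -> RegionalShares:
    """Read a long-format CSV with columns region, year, share."""
    df = pd.read_csv(path)
    for col in ("region", "year", "share"):
        if col not in df.columns:
            raise FormatError(f"regional shares file missing column {col!r}")
    wide = df.pivot(index="region", columns="year", values="share")
    if wide.isna().any().any():
        raise FormatError("regional shares table has gaps")
    regions = tuple(wide.index)
    return RegionalShares(regions, wide.columns.to_numpy(dtype=int),
                          wide.to_numpy())


def disaggregate_population(
    national: Trajectory, shares: RegionalShares
) -> dict[str, Trajectory]:
    """Split a national population trajectory across the seven regions.

    Regional populations sum to the national series in every year; beyond
    the share table's last year (2090) the final shares are reused.
    """
    mat = shares.share_matrix(national.years)        # (7, T)
    regional = mat * national.values[None, :]
    return {
        region: Trajectory(national.years, regional[i], units=national.units)
        for i, region in enumerate(shares.regions)
    }


# ----------------------------------------------------------------------
# CSV round-trip
# ----------------------------------------------------------------------

def write_scenarios(sset: ScenarioSet, path) -> None:
    """Write a ScenarioSet as long-format CSV (full float precision)."""
    n, T = len(sset), len(sset.years)
    df = pd.DataFrame({
        "scenario_id": np.repeat(sset.ids, T),
        "year": np.tile(sset.years, n),
        "co2_gtc": sset.co2.ravel(),
        "ch4_mt": sset.ch4.ravel(),
        "n2o_mt": sset.n2o.ravel(),
        "gdp": sset.gdp.ravel(),
        "population": sset.population.ravel(),
    })
    # %.17g guarantees binary round-trip of float64 through text
    df.to_csv(path, index=False, float_format="%.17g")


def read_scenarios(path) -> ScenarioSet:
    """Read a long-format scenario CSV written by :func:`write_scenarios`.

    Raises :class:`FormatError` for missing columns, NaN cells, or
    non-annual year grids (naming the offending scenario and row).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _SCENARIO_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"scenario file missing column {col!r}")
    value_cols = [c for c in _SCENARIO_COLUMNS if c != "scenario_id"]
    na = df[value_cols].isna()
    if na.any().any():
        row = int(np.argwhere(na.to_numpy().any(axis=1))[0][0])
        raise FormatError(f"NaN value in scenario file at row {row}")

    ids = list(dict.fromkeys(df["scenario_id"]))
    groups = df.groupby("scenario_id", sort=False)
    years = None
    arrays = {c: [] for c in value_cols if c != "year"}
    for sid in ids:
        g = groups.get_group(sid).sort_values("year")
        yrs = g["year"].to_numpy(dtype=int)
        gaps = np.flatnonzero(np.diff(yrs) != 1)
        if gaps.size:
            missing = yrs[gaps[0]] + 1
            raise FormatError(
                f"scenario {sid!r}: year grid not annual (gap after "
                f"{yrs[gaps[0]]}, missing {missing})")
        if years is None:
            years = yrs
        elif not np.array_equal(years, yrs):
            raise FormatError(f"scenario {sid!r}: year grid differs from first")
        for c in arrays:
            arrays[c].append(g[c].to_numpy(dtype=float))
    stacked = {c: np.vstack(v) for c, v in arrays.items()}
    return ScenarioSet(ids, years, stacked["co2_gtc"], stacked["ch4_mt"],
                       stacked["n2o_mt"], stacked["gdp"],
                       stacked["population"])
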