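"""Reduced-complexity emissions -> temperature -> sea-level emulator.

The emulator follows the structure of finite-amplitude impulse-response
climate models:

* **CO2**: a four-pool impulse-response carbon cycle.  Pool ``i`` holds a
  fraction ``a_i`` of each year's emissions and decays with timescale
  ``tau_i``.  All timescales are rescaled each year by a common factor
  ``alpha`` chosen so that the 100-year integrated airborne fraction
  (iIRF100) tracks its feedback law ``r0 + rc * G_u + rt * T`` (carbon
  uptake saturates as cumulative uptake ``G_u`` and warming ``T`` grow).
  ``alpha`` is obtained from the standard analytic inversion
  ``alpha = g0 * exp(iIRF100 / g1)``.
* **CH4 / N2O**: one-box decay toward the pre-industrial concentration
  with a fixed lifetime; anthropogenic emissions are the source term and
  natural fluxes are implicit in the pre-industrial equilibrium.
* **Forcing**: logarithmic in CO2 (``F2x * ln(C/C0)/ln 2``),
  square-root-difference forms for CH4 and N2O, plus a prescribed
  exogenous series standing in for every non-modelled species (aerosols,
  halocarbons, ozone, ...).
* **Temperature**: a two-box (surface/deep-ocean) energy balance,
  advanced with the exact matrix-exponential solution for piecewise
  constant annual forcing.  The equilibrium of the coupled system under
  constant forcing F is F / lambda.
* **Sea level**: the semi-empirical rate law ``dS/dt = a * (T - T0)``
  integrated with the trapezoid rule on the annual grid.

Within a year, emissions and forcing are held constant and ``alpha`` is
frozen at its start-of-year value, so the annual update of each linear
subsystem is exact; temperature enters the carbon feedback with a one-year
lag.  Scenario runs are spun up from pre-industrial conditions in 1850
using packaged historical emissions/forcing fixtures, which also define
the offset between the 1850-1900 and 1986-2005 temperature baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np

from .errors import (InvalidArgumentError, InvalidCalibrationError,
                     InvalidStateError, ConfigurationError)
from .scenarios import Scenario, ScenarioSet
from .trajectories import (BASELINE_MODERN, BASELINE_PREINDUSTRIAL,
                           GMSLTrajectory, TemperatureTrajectory, Trajectory)

__all__ = [
    "ClimateParams", "ClimateParamEnsemble", "ClimateParamPriors",
    "EmulatorConfig", "sample_climate_params", "run_gas_cycles",
    "compute_forcing", "run_thermal", "rebaseline", "conus_from_global",
    "gmsl_from_temperature", "run_climate", "run_climate_ensemble",
    "compute_baseline_offset", "default_historical_emissions",
    "default_exogenous_forcing", "read_exogenous_forcing",
]

HISTORY_START = 1850

# Unit conversions (atmospheric burden per unit mixing ratio)
GTC_PER_PPM = 2.124        # GtC per ppm CO2
MT_PER_PPB_CH4 = 2.844     # Mt CH4 per ppb
MT_PER_PPB_N2O = 7.80      # Mt N2O per ppb


# ----------------------------------------------------------------------
# Parameters
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ClimateParams:
    """One calibrated parameter set of the emulator.

    Carbon-pool partitions/timescales and the iIRF100 feedback constants
    follow the usual impulse-response calibration; thermal parameters are
    the two-box heat capacities (W yr m-2 K-1), the climate feedback
    ``lam`` and the box heat-exchange coefficient ``gamma_heat``
    (W m-2 K-1).  The implied equilibrium climate sensitivity is
    ``f2x / lam``.
    """

    a: tuple = (0.2173, 0.2240, 0.2824, 0.2763)
    tau: tuple = (1.0e9, 394.4, 36.54, 4.304)    # yr
    r0: float = 35.0          # pre-industrial iIRF100, yr
    rc: float = 0.019         # iIRF100 sensitivity to cumulative uptake, yr/GtC
    rt: float = 4.165         # iIRF100 sensitivity to warming, yr/K
    ch4_lifetime: float = 9.3     # yr
    n2o_lifetime: float = 121.0   # yr
    co2_pi: float = 278.0     # ppm
    ch4_pi: float = 722.0     # ppb
    n2o_pi: float = 270.0     # ppb
    f2x: float = 3.93         # W m-2 at doubled CO2
    ch4_forcing_coeff: float = 0.036   # W m-2 ppb^-1/2
    n2o_forcing_coeff: float = 0.12    # W m-2 ppb^-1/2
    c_upper: float = 8.2      # W yr m-2 K-1
    c_deep: float = 109.0     # W yr m-2 K-1
    lam: float = 1.31         # W m-2 K-1
    gamma_heat: float = 0.9   # W m-2 K-1

    def validate(self) -> None:
        if abs(sum(self.a) - 1.0) > 1e-9:
            raise InvalidCalibrationError("carbon pool fractions must sum to 1")
        if any(t <= 0 for t in self.tau):
            raise InvalidCalibrationError("pool timescales must be > 0")
        if self.lam <= 0 or self.c_upper <= 0 or self.c_deep <= 0:
            raise InvalidCalibrationError("thermal parameters must be > 0")
        if self.gamma_heat <= 0:
            raise InvalidCalibrationError("box heat exchange must be > 0")
        ecs = self.f2x / self.lam
        if not np.isfinite(ecs) or ecs <= 0:
            raise InvalidCalibrationError("implied ECS must be finite and > 0")
        for name in ("ch4_lifetime", "n2o_lifetime", "co2_pi", "ch4_pi",
                     "n2o_pi", "f2x"):
            if getattr(self, name) <= 0:
                raise InvalidCalibrationError(f"{name} must be > 0")

    @property
    def ecs(self) -> float:
        """Equilibrium climate sensitivity, degC."""
        return self.f2x / self.lam


class ClimateParamEnsemble:
    """Collection of sampled :class:`ClimateParams`, stored as arrays."""

    _FIELDS = ("r0", "rc", "rt", "ch4_lifetime", "n2o_lifetime", "co2_pi",
               "ch4_pi", "n2o_pi", "f2x", "ch4_forcing_coeff",
               "n2o_forcing_coeff", "c_upper", "c_deep", "lam", "gamma_heat")

    def __init__(self, members: list[ClimateParams], seed: int | None = None):
        if not members:
            raise InvalidArgumentError("ensemble must have >= 1 member")
        for m in members:
            m.validate()
        self.members = list(members)
        self.seed = seed

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i: int) -> ClimateParams:
        return self.members[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClimateParamEnsemble):
            return NotImplemented
        return self.members == other.members

    def field_array(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.members])


@dataclass(frozen=True)
class ClimateParamPriors:
    """Priors for :func:`sample_climate_params`.

    The sensitivity-controlling parameter is the implied ECS, drawn
    lognormally (analytic median ``exp(ecs_mu)``); the remaining sampled
    parameters use normals truncated to their physical support.  Carbon
    pool partitions and timescales are held at their calibrated values.
    """

    ecs_mu: float = float(np.log(3.0))   # log degC
    ecs_sigma: float = 0.28
    c_upper_mean: float = 8.2
    c_upper_sd: float = 1.0
    c_deep_mean: float = 109.0
    c_deep_sd: float = 30.0
    gamma_mean: float = 0.9
    gamma_sd: float = 0.15
    r0_mean: float = 35.0
    r0_sd: float = 3.0
    rc_mean: float = 0.019
    rc_sd: float = 0.005
    rt_mean: float = 4.165
    rt_sd: float = 1.0
    ch4_lifetime_mean: float = 9.3
    ch4_lifetime_sd: float = 0.8

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not np.isfinite(v):
                raise InvalidCalibrationError(f"prior {name} is not finite")
            if name.endswith(("_sd", "_sigma")) and v < 0:
                raise InvalidCalibrationError(f"prior {name} must be >= 0")

    @property
    def ecs_median(self) -> float:
        return float(np.exp(self.ecs_mu))


def _truncated_normal(rng, mean, sd, low, size):
    """Rejection-sampled truncated normal (vectorised, deterministic)."""
    out = rng.normal(mean, sd, size=size)
    bad = out <= low
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    return out


def sample_climate_params(
    n: int, seed: int, priors: ClimateParamPriors | None = None
) -> ClimateParamEnsemble:
    """Draw ``n`` parameter sets from the documented priors."""
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    priors = priors or ClimateParamPriors()
    priors.validate()
    rng = np.random.default_rng(seed)
    base = ClimateParams()
    ecs = np.exp(rng.normal(priors.ecs_mu, priors.ecs_sigma, size=n))
    cu = _truncated_normal(rng, priors.c_upper_mean, priors.c_upper_sd, 2.0, n)
    cd = _truncated_normal(rng, priors.c_deep_mean, priors.c_deep_sd, 20.0, n)
    gam = _truncated_normal(rng, priors.gamma_mean, priors.gamma_sd, 0.2, n)
    r0 = _truncated_normal(rng, priors.r0_mean, priors.r0_sd, 15.0, n)
    rc = _truncated_normal(rng, priors.rc_mean, priors.rc_sd, 0.0, n)
    rt = _truncated_normal(rng, priors.rt_mean, priors.rt_sd, 0.0, n)
    ch4_tau = _truncated_normal(rng, priors.ch4_lifetime_mean,
                                priors.ch4_lifetime_sd, 4.0, n)
    members = [
        replace(base, lam=base.f2x / ecs[i], c_upper=cu[i], c_deep=cd[i],
                gamma_heat=gam[i], r0=r0[i], rc=rc[i], rt=rt[i],
                ch4_lifetime=ch4_tau[i])
        for i in range(n)
    ]
    return ClimateParamEnsemble(members, seed=seed)


# ----------------------------------------------------------------------
# Config and packaged fixtures
# ----------------------------------------------------------------------

def default_historical_emissions() -> dict[str, np.ndarray]:
    """Synthetic historical (1850-2019) anthropogenic emissions.

    Smooth analytic stand-ins for the observed record, calibrated so that
    cumulative CO2 emissions, the 2019 emission rates and the implied 2019
    concentrations land near their observed values.  Units: CO2 GtC/yr,
    CH4/N2O Mt of gas per yr.
    """
    y = np.arange(HISTORY_START, 2020)
    co2 = 0.55 + 10.7 / (1.0 + np.exp(-(y - 1973.0) / 22.0))
    ch4 = 390.0 / (1.0 + np.exp(-(y - 1965.0) / 28.0))
    n2o = 10.5 / (1.0 + np.exp(-(y - 1980.0) / 35.0))
    return {"years": y, "co2": co2, "ch4": ch4, "n2o": n2o}


def default_exogenous_forcing(years: np.ndarray) -> np.ndarray:
    """Synthetic non-modelled-species forcing (W m-2) on ``years``.

    Two smooth components: a growing positive term for other greenhouse
    gases and tropospheric ozone, and a negative aerosol term that deepens
    through the late 20th century and then recovers as air quality
    improves (mid-range-pathway-like).  Volcanic and solar variability are
    out of scope.
    """
    y = np.asarray(years, dtype=float)
    other = 0.55 / (1.0 + np.exp(-(y - 1980.0) / 22.0))
    aerosol_rise = 1.0 / (1.0 + np.exp(-(y - 1955.0) / 18.0))
    aerosol_recovery = 1.0 / (1.0 + np.exp(-(y - 2050.0) / 18.0))
    aerosol = -0.95 * aerosol_rise * (1.0 - 0.8 * aerosol_recovery)
    return other + aerosol


def read_exogenous_forcing(path) -> Trajectory:
    """Read an exogenous-forcing CSV with columns ``year, wm2``."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("year", "wm2"):
        if col not in df.columns:
            raise ConfigurationError(
                f"exogenous forcing file missing column {col!r}")
    df = df.sort_values("year")
    return Trajectory(df["year"].to_numpy(dtype=int),
                      df["wm2"].to_numpy(dtype=float), units="W/m2")


@dataclass(frozen=True)
class EmulatorConfig:
    """Emulator settings shared across ensemble members.

    ``baseline_offset`` is the warming of the 1986-2005 reference period
    over 1850-1900.  ``None`` (the default inside :func:`run_climate`)
    derives it from each run's own history, which is the self-consistent
    choice for sampled parameters; a fixed value can be supplied for
    standalone rebaselining (:func:`compute_baseline_offset` reproduces
    the central-parameter value).
    """

    conus_scale: float = 1.42          # CONUS warming per degC global
    baseline_offset: float | None = None   # degC; None -> derive from run
    slr_a: float = 0.34                # cm yr-1 K-1
    slr_t0: float = -0.15              # degC vs 1850-1900
    slr_initial_cm: float = 6.5        # cm above 2000 datum at first scenario year
    exogenous_forcing: Trajectory | None = None  # overrides packaged default

    def __post_init__(self):
        if self.conus_scale <= 0:
            raise InvalidCalibrationError("conus_scale must be > 0")
        if self.slr_a < 0:
            raise InvalidCalibrationError("slr rate coefficient must be >= 0")

    def exogenous_on(self, years: np.ndarray) -> np.ndarray:
        if self.exogenous_forcing is None:
            return default_exogenous_forcing(years)
        f = self.exogenous_forcing
        idx0 = years[0] - f.years[0]
        if idx0 < 0 or years[-1] > f.years[-1]:
            raise ConfigurationError(
                "exogenous forcing does not cover the run years "
                f"[{years[0]}, {years[-1]}]")
        return f.values[idx0: idx0 + len(years)]


# ----------------------------------------------------------------------
# Core integration kernel
# ----------------------------------------------------------------------

class _ParamArrays:
    """Per-member parameter arrays broadcast to ensemble shape (n,)."""

    def __init__(self, source: ClimateParams | ClimateParamEnsemble, n: int):
        if isinstance(source, ClimateParams):
            source.validate()
            get = lambda f: np.full(n, getattr(source, f))
            self.a = np.asarray(source.a)[:, None] * np.ones((1, n))
            self.tau = np.asarray(source.tau)[:, None] * np.ones((1, n))
        else:
            if len(source) != n:
                raise InvalidArgumentError(
                    f"ensemble size {len(source)} != scenario count {n}")
            get = source.field_array
            self.a = np.stack([np.asarray(m.a) for m in source.members],
                              axis=1)
            self.tau = np.stack([np.asarray(m.tau) for m in source.members],
                                axis=1)
        for f in ClimateParamEnsemble._FIELDS:
            setattr(self, f, get(f))

        # analytic alpha inversion constants
        x = 100.0 / self.tau
        self.g1 = np.sum(self.a * self.tau * (1.0 - (1.0 + x) * np.exp(-x)),
                         axis=0)
        self.g0 = np.exp(-np.sum(self.a * self.tau * (1.0 - np.exp(-x)),
                                 axis=0) / self.g1)

        # two-box exact annual propagator: x_{t+1} = M x_t + q * F_t
        lam, gam, cu, cd = self.lam, self.gamma_heat, self.c_upper, self.c_deep
        a11, a12 = -(lam + gam) / cu, gam / cu
        a21, a22 = gam / cd, -gam / cd
        tr, det = a11 + a22, a11 * a22 - a12 * a21
        disc = np.sqrt(tr * tr - 4.0 * det)
        mu1, mu2 = (tr + disc) / 2.0, (tr - disc) / 2.0
        # spectral projectors P1 = (A - mu2 I)/(mu1-mu2), P2 = I - P1
        dmu = mu1 - mu2
        p1 = np.stack([(a11 - mu2) / dmu, a12 / dmu,
                       a21 / dmu, (a22 - mu2) / dmu])
        ident = np.stack([np.ones_like(a11), np.zeros_like(a11),
                          np.zeros_like(a11), np.ones_like(a11)])
        p2 = ident - p1
        e1, e2 = np.exp(mu1), np.exp(mu2)
        self.M = e1 * p1 + e2 * p2                       # (4, n) flat 2x2
        # q = A^{-1}(M - I) b with b = [1/cu, 0]
        phi1, phi2 = (e1 - 1.0) / mu1, (e2 - 1.0) / mu2
        q_mat = phi1 * p1 + phi2 * p2
        self.q_u = q_mat[0] / cu          # forcing multiplier, upper box
        self.q_d = q_mat[2] / cu          # forcing multiplier, deep box


def _integrate(years: np.ndarray, e_co2: np.ndarray, e_ch4: np.ndarray,
               e_n2o: np.ndarray, f_exog: np.ndarray, p: _ParamArrays,
               collect_alpha: bool = False) -> dict[str, np.ndarray]:
    """Annual forward integration of the coupled gas/forcing/thermal system.

    All emission arrays have shape ``(n, T)``; returns concentration,
    forcing and temperature arrays of the same shape.  Temperature is the
    upper-box anomaly over the run's initial (pre-industrial) state.
    """
    n, T = e_co2.shape
    pools = np.zeros((4, n))              # GtC in each pool
    cum_e = np.zeros(n)                   # cumulative CO2 emissions, GtC
    t_up = np.zeros(n)
    t_deep = np.zeros(n)
    ch4 = p.ch4_pi.copy()
    n2o = p.n2o_pi.copy()

    conc_co2 = np.empty((n, T))
    conc_ch4 = np.empty((n, T))
    conc_n2o = np.empty((n, T))
    forcing = np.empty((n, T))
    temp = np.empty((n, T))
    alphas = np.empty((n, T)) if collect_alpha else None

    sqrt_ch4_pi = np.sqrt(p.ch4_pi)
    sqrt_n2o_pi = np.sqrt(p.n2o_pi)
    log2 = np.log(2.0)
    # forcing at the run's initial state (gas anomalies are zero)
    f_prev = np.broadcast_to(f_exog[0], (n,)).astype(float)

    def _alpha_from(uptake, warming):
        iirf = np.clip(p.r0 + p.rc * uptake + p.rt * warming, 0.0, 97.0)
        return np.clip(p.g0 * np.exp(iirf / p.g1), 1e-3, 1e3)

    def _pool_step(alpha, t):
        atau = alpha[None, :] * p.tau
        decay = np.exp(-1.0 / atau)
        return (pools * decay
                + p.a * e_co2[None, :, t] * atau * (1.0 - decay))

    for t in range(T):
        # -- carbon cycle.  alpha tracks the iIRF100 feedback law; a
        # predictor-corrector pass (alpha from the start-of-year state,
        # then averaged with its end-of-year estimate) keeps the annual
        # step second-order against the continuously-varying system.
        # Warming enters with a one-year lag.
        uptake0 = cum_e - pools.sum(axis=0)
        alpha0 = _alpha_from(uptake0, t_up)
        provisional = _pool_step(alpha0, t)
        cum_e = cum_e + e_co2[:, t]
        uptake1 = cum_e - provisional.sum(axis=0)
        alpha = 0.5 * (alpha0 + _alpha_from(uptake1, t_up))
        if collect_alpha:
            alphas[:, t] = alpha
        pools = _pool_step(alpha, t)
        co2 = p.co2_pi + pools.sum(axis=0) / GTC_PER_PPM
        conc_co2[:, t] = co2

        # -- one-box CH4 / N2O
        d4 = np.exp(-1.0 / p.ch4_lifetime)
        ch4 = (p.ch4_pi + (ch4 - p.ch4_pi) * d4
               + e_ch4[:, t] / MT_PER_PPB_CH4 * p.ch4_lifetime * (1.0 - d4))
        dn = np.exp(-1.0 / p.n2o_lifetime)
        n2o = (p.n2o_pi + (n2o - p.n2o_pi) * dn
               + e_n2o[:, t] / MT_PER_PPB_N2O * p.n2o_lifetime * (1.0 - dn))
        conc_ch4[:, t] = ch4
        conc_n2o[:, t] = n2o

        # -- forcing
        if np.any(co2 <= 0):
            raise InvalidStateError("non-positive CO2 concentration")
        f = (p.f2x * np.log(co2 / p.co2_pi) / log2
             + p.ch4_forcing_coeff * (np.sqrt(ch4) - sqrt_ch4_pi)
             + p.n2o_forcing_coeff * (np.sqrt(n2o) - sqrt_n2o_pi)
             + f_exog[t])
        forcing[:, t] = f

        # -- two-box thermal, exact annual step.  Within the year the
        # forcing evolves with the concentrations; its midpoint estimate
        # (average of start- and end-of-year values) keeps the annual
        # scheme second-order accurate against the continuous system.
        f_mid = 0.5 * (f_prev + f)
        t_up, t_deep = (p.M[0] * t_up + p.M[1] * t_deep + p.q_u * f_mid,
                        p.M[2] * t_up + p.M[3] * t_deep + p.q_d * f_mid)
        temp[:, t] = t_up
        f_prev = f

    out = {"co2": conc_co2, "ch4": conc_ch4, "n2o": conc_n2o,
           "forcing": forcing, "temperature": temp}
    if collect_alpha:
        out["alpha"] = alphas
    return out


# ----------------------------------------------------------------------
# Public single-scenario operations
# ----------------------------------------------------------------------

def _require_annual(traj: Trajectory) -> None:
    if not np.all(np.diff(traj.years) == 1):
        raise InvalidArgumentError("annual year grid required")


def run_gas_cycles(
    scenario: Scenario, params: ClimateParams,
    initial: Mapping[str, float] | None = None,
) -> dict[str, Trajectory]:
    """Concentrations (CO2 ppm, CH4/N2O ppb) for one scenario.

    Pools start at pre-industrial equilibrium unless the run is embedded
    in a longer history via :func:`run_climate`.  The temperature entering
    the carbon feedback is computed internally by the coupled kernel.
    """
    params.validate()
    _require_annual(scenario.co2)
    years = scenario.years
    p = _ParamArrays(params, 1)
    res = _integrate(years, scenario.co2.values[None, :],
                     scenario.ch4.values[None, :],
                     scenario.n2o.values[None, :],
                     np.zeros(len(years)), p)
    return {
        "co2": Trajectory(years, res["co2"][0], units="ppm"),
        "ch4": Trajectory(years, res["ch4"][0], units="ppb"),
        "n2o": Trajectory(years, res["n2o"][0], units="ppb"),
    }


def compute_forcing(
    concentrations: Mapping[str, Trajectory],
    params: ClimateParams,
    config: EmulatorConfig | None = None,
) -> Trajectory:
    """Total radiative forcing from concentration trajectories."""
    params.validate()
    co2 = concentrations["co2"]
    ch4 = concentrations["ch4"]
    n2o = concentrations["n2o"]
    years = co2.years
    for other in (ch4, n2o):
        if not co2.same_grid(other):
            raise InvalidArgumentError("concentrations on different grids")
    if np.any(co2.values <= 0):
        raise InvalidStateError("non-positive CO2 concentration")
    f = (params.f2x * np.log(co2.values / params.co2_pi) / np.log(2.0)
         + params.ch4_forcing_coeff * (np.sqrt(ch4.values)
                                       - np.sqrt(params.ch4_pi))
         + params.n2o_forcing_coeff * (np.sqrt(n2o.values)
                                       - np.sqrt(params.n2o_pi)))
    if config is not None:
        f = f + config.exogenous_on(years)
    return Trajectory(years, f, units="W/m2")


def run_thermal(forcing: Trajectory, params: ClimateParams,
                ) -> TemperatureTrajectory:
    """Two-box energy-balance response to a forcing trajectory.

    Starts from zero anomaly; output is labelled with the pre-industrial
    baseline.
    """
    params.validate()
    p = _ParamArrays(params, 1)
    f = forcing.values
    t_up = np.zeros(1)
    t_deep = np.zeros(1)
    out = np.empty(len(f))
    for t in range(len(f)):
        t_up, t_deep = (p.M[0] * t_up + p.M[1] * t_deep + p.q_u * f[t],
                        p.M[2] * t_up + p.M[3] * t_deep + p.q_d * f[t])
        out[t] = t_up[0]
    return TemperatureTrajectory(forcing.years, out,
                                 baseline=BASELINE_PREINDUSTRIAL,
                                 domain="global")


def rebaseline(traj: TemperatureTrajectory,
               config: EmulatorConfig | float) -> TemperatureTrajectory:
    """Re-reference a pre-industrial-baselined anomaly to 1986-2005."""
    if traj.baseline != BASELINE_PREINDUSTRIAL:
        raise InvalidStateError(
            f"trajectory already baselined to {traj.baseline!r}")
    offset = config if isinstance(config, (int, float)) else config.baseline_offset
    if offset is None:
        raise ConfigurationError(
            "baseline_offset is unset; compute it with "
            "compute_baseline_offset() or supply it in the config")
    return TemperatureTrajectory(traj.years, traj.values - offset,
                                 baseline=BASELINE_MODERN, domain=traj.domain)


def conus_from_global(traj: TemperatureTrajectory,
                      config: EmulatorConfig | None = None,
                      ) -> TemperatureTrajectory:
    """Scale a modern-baselined global anomaly to CONUS."""
    config = config or EmulatorConfig()
    if traj.domain != "global":
        raise InvalidStateError("input must be a global trajectory")
    if traj.baseline != BASELINE_MODERN:
        raise InvalidStateError(
            "CONUS scaling is defined for 1986-2005-baselined input")
    return TemperatureTrajectory(traj.years, traj.values * config.conus_scale,
                                 baseline=BASELINE_MODERN, domain="CONUS")


def gmsl_from_temperature(traj: TemperatureTrajectory,
                          config: EmulatorConfig) -> GMSLTrajectory:
    """Semi-empirical sea level: trapezoidal integral of a*(T - T0).

    ``traj`` must be global and pre-industrial-baselined (the rate law's
    equilibrium temperature is referenced to 1850-1900); the series is
    anchored at ``config.slr_initial_cm`` in its first year.
    """
    if traj.domain != "global":
        raise InvalidStateError("sea level is driven by global temperature")
    if config.slr_a is None or config.slr_t0 is None:
        raise ConfigurationError("slr parameters missing")
    rate = config.slr_a * (traj.values - config.slr_t0)
    increments = 0.5 * (rate[1:] + rate[:-1])
    level = config.slr_initial_cm + np.concatenate(
        [[0.0], np.cumsum(increments)])
    return GMSLTrajectory(traj.years, level)


def compute_baseline_offset(params: ClimateParams | None = None,
                            config: EmulatorConfig | None = None) -> float:
    """Warming of 1986-2005 over 1850-1900 in the emulator's own
    historical run (packaged emissions + exogenous forcing)."""
    params = params or ClimateParams()
    config = config or EmulatorConfig()
    hist = default_historical_emissions()
    years = hist["years"]
    p = _ParamArrays(params, 1)
    res = _integrate(years, hist["co2"][None, :], hist["ch4"][None, :],
                     hist["n2o"][None, :], config.exogenous_on(years), p)
    temp = res["temperature"][0]
    sel = lambda lo, hi: temp[(years >= lo) & (years <= hi)].mean()
    return float(sel(1986, 2005) - sel(1850, 1900))


# ----------------------------------------------------------------------
# Full-chain runs
# ----------------------------------------------------------------------

def _full_run(years_scen, e_co2, e_ch4, e_n2o, params_source, config,
              n: int) -> dict[str, np.ndarray]:
    """History + scenario integration; returns scenario-grid arrays."""
    hist = default_historical_emissions()
    hy = hist["years"]
    if years_scen[0] != hy[-1] + 1:
        raise InvalidArgumentError(
            f"scenario must start in {hy[-1] + 1} to follow the packaged "
            f"history, got {years_scen[0]}")
    years = np.concatenate([hy, years_scen])
    ones = np.ones((n, 1))
    full_co2 = np.concatenate([hist["co2"][None, :] * ones, e_co2], axis=1)
    full_ch4 = np.concatenate([hist["ch4"][None, :] * ones, e_ch4], axis=1)
    full_n2o = np.concatenate([hist["n2o"][None, :] * ones, e_n2o], axis=1)
    p = _ParamArrays(params_source, n)
    res = _integrate(years, full_co2, full_ch4, full_n2o,
                     config.exogenous_on(years), p)
    temp = res["temperature"]
    pre = ((years >= 1850) & (years <= 1900))
    mod = ((years >= 1986) & (years <= 2005))
    t_pre = temp - temp[:, pre].mean(axis=1, keepdims=True)
    if config.baseline_offset is None:
        offset = temp[:, mod].mean(axis=1) - temp[:, pre].mean(axis=1)
    else:
        offset = np.full(n, float(config.baseline_offset))
    scen = years >= years_scen[0]
    return {
        "years": years_scen,
        "global_pi": t_pre[:, scen],
        "offset": offset,
        "co2": res["co2"][:, scen],
        "ch4": res["ch4"][:, scen],
        "n2o": res["n2o"][:, scen],
        "forcing": res["forcing"][:, scen],
    }


def run_climate(scenario: Scenario, params: ClimateParams,
                config: EmulatorConfig | None = None) -> dict:
    """Full chain for one scenario: global and CONUS temperature plus
    global mean sea level, spun up from 1850.

    Returns a dict with keys ``global`` (1986-2005 baseline), ``conus``,
    ``gmsl``, ``global_preindustrial`` and ``baseline_offset``.
    """
    config = config or EmulatorConfig()
    params.validate()
    _require_annual(scenario.co2)
    res = _full_run(scenario.years, scenario.co2.values[None, :],
                    scenario.ch4.values[None, :],
                    scenario.n2o.values[None, :], params, config, 1)
    g_pi = TemperatureTrajectory(res["years"], res["global_pi"][0],
                                 baseline=BASELINE_PREINDUSTRIAL,
                                 domain="global")
    g_mod = rebaseline(g_pi, float(res["offset"][0]))
    conus = conus_from_global(g_mod, config)
    gmsl = gmsl_from_temperature(g_pi, config)
    return {"global": g_mod, "conus": conus, "gmsl": gmsl,
            "global_preindustrial": g_pi,
            "baseline_offset": float(res["offset"][0])}


def run_climate_ensemble(scenario_set: ScenarioSet,
                         ensemble: ClimateParamEnsemble | ClimateParams,
                         config: EmulatorConfig | None = None,
                         ) -> dict[str, np.ndarray]:
    """Vectorised full chain: scenario ``i`` is paired with ensemble
    member ``i`` (identical pairing in baseline and pulse runs).

    Returns arrays of shape ``(n, T)`` on the scenario year grid:
    ``global_modern``, ``conus``, ``gmsl``, ``global_pi``, plus the
    per-member ``offset``.
    """
    config = config or EmulatorConfig()
    n = len(scenario_set)
    res = _full_run(scenario_set.years, scenario_set.co2, scenario_set.ch4,
                    scenario_set.n2o, ensemble, config, n)
    g_mod = res["global_pi"] - res["offset"][:, None]
    conus = g_mod * config.conus_scale
    rate = config.slr_a * (res["global_pi"] - config.slr_t0)
    increments = 0.5 * (rate[:, 1:] + rate[:, :-1])
    gmsl = config.slr_initial_cm + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(increments, axis=1)], axis=1)
    return {"years": res["years"], "global_pi": res["global_pi"],
            "global_modern": g_mod, "conus": conus, "gmsl": gmsl,
            "offset": res["offset"]}
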