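"""Temperature-binned and sea-level-driven sectoral damage engine.

A sector's response to warming is stored as a set of anchor points
(impact at discrete CONUS warming levels over the 1986-2005 baseline) and
evaluated by piecewise-linear interpolation, with linear extrapolation
beyond the calibrated range using the nearest segment's slope.  Sea-level
sectors instead carry a year x height impact grid interpolated across
height at the query year.  Impacts are defined at reference
socioeconomics and rescaled to each scenario-year via regional population
(proportional exposure) and national GDP per capita (constant-elasticity
valuation; mortality-type endpoints are monetised with a value of a
statistical life whose GDP-per-capita elasticity defaults to 1).
Per-GCM functions are averaged arithmetically, sectors and regions are
additive, and zero warming with zero sea-level rise yields exactly zero
damages because every anchor set passes through the origin.

The packaged registry is a seeded synthetic stand-in with 20 sectors in
seven regions, grouped into six categories, with adaptation variants for
the infrastructure sectors and a beneficial (negative) air-quality
response in the Midwest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, FormatError, InvalidArgumentError)
from .scenarios import REGIONS, RegionalShares, Scenario, default_regional_shares
from .trajectories import (GMSLTrajectory, TemperatureTrajectory, Trajectory,
                           require_same_grid)

__all__ = [
    "DamageFunction", "SLRSurface", "SectorRegistry", "DamageTable",
    "eval_temp_damage", "eval_slr_damage", "scale_impacts", "gcm_average",
    "run_damages", "damages_share_of_gdp", "synth_damage_registry",
    "registry_to_json", "registry_from_json", "CATEGORIES",
    "VARIANT_NO_ADAPT", "VARIANT_REACTIVE", "VARIANT_ANTICIPATED",
    "VARIANT_PROACTIVE",
]

VARIANT_NO_ADAPT = "no additional adaptation"
VARIANT_REACTIVE = "reactive"
VARIANT_ANTICIPATED = "reasonably anticipated adaptation"
VARIANT_PROACTIVE = "proactive"

CATEGORIES = ("health", "infrastructure", "labor", "electricity",
              "agriculture", "ecosystems and recreation")

MAX_ANCHOR_TEMP = 10.0   # degC CONUS; calibration range of the binning


def _interp_with_slope_extrapolation(x, xs, ys):
    """Piecewise-linear interpolation; outside the anchor range the
    nearest segment's slope is continued."""
    x = np.asarray(x, dtype=float)
    out = np.interp(x, xs, ys)
    lo, hi = xs[0], xs[-1]
    below = x < lo
    if np.any(below):
        s = (ys[1] - ys[0]) / (xs[1] - xs[0])
        out = np.where(below, ys[0] + s * (x - lo), out)
    above = x > hi
    if np.any(above):
        s = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out = np.where(above, ys[-1] + s * (x - hi), out)
    return out


@dataclass(frozen=True)
class DamageFunction:
    """Binned impact response of one sector x region x variant x GCM.

    ``anchor_impacts`` are annual impacts at reference socioeconomics —
    2015 USD/yr for monetary sectors, physical units/yr when
    ``endpoint_unit`` is set (monetised via ``unit_value`` 2015 USD/unit
    at reference GDP per capita, scaled with elasticity
    ``unit_value_elasticity``).
    """

    sector: str
    region: str
    variant: str
    gcm: str
    anchor_temps: np.ndarray      # degC CONUS over 1986-2005, first == 0
    anchor_impacts: np.ndarray    # first == 0
    population_proportional: bool = True
    gdppc_elasticity: float = 0.0
    endpoint_unit: str | None = None
    unit_value: float | None = None
    unit_value_elasticity: float = 1.0

    def __post_init__(self):
        at = np.asarray(self.anchor_temps, dtype=float)
        ai = np.asarray(self.anchor_impacts, dtype=float)
        object.__setattr__(self, "anchor_temps", at)
        object.__setattr__(self, "anchor_impacts", ai)
        if len(at) < 2 or len(at) != len(ai):
            raise InvalidArgumentError(
                f"{self.sector}/{self.region}: need >= 2 paired anchors")
        if at[0] != 0.0 or ai[0] != 0.0:
            raise InvalidArgumentError(
                f"{self.sector}/{self.region}: first anchor must be (0, 0)")
        if np.any(np.diff(at) <= 0):
            raise InvalidArgumentError(
                f"{self.sector}/{self.region}: anchor temps must increase")
        if at[-1] > MAX_ANCHOR_TEMP:
            raise InvalidArgumentError(
                f"{self.sector}/{self.region}: anchors beyond "
                f"{MAX_ANCHOR_TEMP} degC")
        if self.endpoint_unit is not None and self.unit_value is None:
            raise InvalidArgumentError(
                f"{self.sector}/{self.region}: endpoint needs a unit value")


@dataclass(frozen=True)
class SLRSurface:
    """Year x sea-level-height impact grid for one sector x region x
    variant x GCM (2015 USD/yr at reference socioeconomics)."""

    sector: str
    region: str
    variant: str
    gcm: str
    years: np.ndarray             # annual grid
    heights: np.ndarray           # cm, strictly increasing, includes 0
    values: np.ndarray            # (len(years), len(heights))
    population_proportional: bool = True
    gdppc_elasticity: float = 1.0
    endpoint_unit: str | None = None
    unit_value: float | None = None
    unit_value_elasticity: float = 1.0

    def __post_init__(self):
        ys = np.asarray(self.years, dtype=int)
        hs = np.asarray(self.heights, dtype=float)
        vs = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", ys)
        object.__setattr__(self, "heights", hs)
        object.__setattr__(self, "values", vs)
        if np.any(np.diff(hs) <= 0):
            raise InvalidArgumentError(
                f"{self.sector}/{self.region}: heights must increase")
        if 0.0 not in hs:
            raise InvalidArgumentError(
                f"{self.sector}/{self.region}: height grid must include 0")
        if vs.shape != (len(ys), len(hs)):
            raise InvalidArgumentError(
                f"{self.sector}/{self.region}: surface grid shape mismatch")
        if not np.all(np.isfinite(vs)):
            raise InvalidArgumentError(
                f"{self.sector}/{self.region}: surface has gaps")


def eval_temp_damage(func: DamageFunction, conus_t) -> np.ndarray | float:
    """Impact at reference socioeconomics for CONUS warming ``conus_t``.

    Linear between anchors; beyond the last anchor the final segment's
    slope is continued (and symmetrically below zero warming).
    """
    if np.any(~np.isfinite(np.asarray(conus_t, dtype=float))):
        raise InvalidArgumentError("non-finite temperature")
    out = _interp_with_slope_extrapolation(conus_t, func.anchor_temps,
                                           func.anchor_impacts)
    return float(out) if np.isscalar(conus_t) else out


def eval_slr_damage(surface: SLRSurface, year: int, gmsl_cm) -> np.ndarray | float:
    """Impact at reference socioeconomics for sea level ``gmsl_cm`` in
    ``year`` (linear across the height axis at that year; heights above
    the grid extrapolate the last segment; below the no-rise floor the
    floor value applies)."""
    idx = np.searchsorted(surface.years, year)
    if idx >= len(surface.years) or surface.years[idx] != year:
        raise InvalidArgumentError(
            f"year {year} outside surface grid "
            f"[{surface.years[0]}, {surface.years[-1]}]")
    row = surface.values[idx]
    h = np.asarray(gmsl_cm, dtype=float)
    out = np.interp(h, surface.heights, row)
    above = h > surface.heights[-1]
    if np.any(above):
        s = (row[-1] - row[-2]) / (surface.heights[-1] - surface.heights[-2])
        out = np.where(above, row[-1] + s * (h - surface.heights[-1]), out)
    return float(out) if np.isscalar(gmsl_cm) else out


def scale_impacts(ref_impact, ref_pop: float, ref_gdppc: float,
                  pop, gdppc, scaling: Mapping) -> np.ndarray | float:
    """Rescale a reference-socioeconomics impact to current conditions:
    ``impact * (pop/ref_pop)^[proportional] * (gdppc/ref_gdppc)^elasticity``.
    """
    if ref_pop <= 0 or ref_gdppc <= 0:
        raise InvalidArgumentError("reference socioeconomics must be > 0")
    out = np.asarray(ref_impact, dtype=float)
    if scaling.get("population_proportional", False):
        out = out * (np.asarray(pop, dtype=float) / ref_pop)
    elasticity = scaling.get("gdppc_elasticity", 0.0)
    if elasticity != 0.0:
        out = out * (np.asarray(gdppc, dtype=float) / ref_gdppc) ** elasticity
    return float(out) if np.isscalar(ref_impact) else out


def gcm_average(impacts: Sequence) -> np.ndarray | float:
    """Arithmetic mean across the GCM ensemble members present."""
    impacts = list(impacts)
    if not impacts:
        raise InvalidArgumentError("empty GCM set")
    return sum(np.asarray(i, dtype=float) for i in impacts) / len(impacts)


# ----------------------------------------------------------------------
# Registry
# ----------------------------------------------------------------------

class SectorRegistry:
    """All damage functions and SLR surfaces, plus sector metadata.

    ``entries`` maps (sector, region, variant) -> list over GCMs of
    DamageFunction or SLRSurface.  Reference socioeconomics (national GDP
    per capita and regional populations the anchors were calibrated at)
    live here because they are shared by all entries.
    """

    def __init__(self, entries: Sequence[DamageFunction | SLRSurface],
                 category_map: Mapping[str, str],
                 default_variant: Mapping[str, str],
                 ref_gdppc: float, ref_region_pop: Mapping[str, float],
                 expected_sectors: int = 20):
        self._by_key: dict[tuple, list] = {}
        for e in entries:
            self._by_key.setdefault((e.sector, e.region, e.variant), []).append(e)
        self.category_map = dict(category_map)
        self.default_variant = dict(default_variant)
        self.ref_gdppc = float(ref_gdppc)
        self.ref_region_pop = dict(ref_region_pop)
        self.expected_sectors = expected_sectors
        self.validate()

    @property
    def sectors(self) -> tuple:
        return tuple(sorted({k[0] for k in self._by_key}))

    @property
    def entries(self) -> list:
        return [e for v in self._by_key.values() for e in v]

    def validate(self) -> None:
        sectors = self.sectors
        if self.expected_sectors and len(sectors) != self.expected_sectors:
            raise ConfigurationError(
                f"registry has {len(sectors)} sectors, expected "
                f"{self.expected_sectors}")
        for s in sectors:
            regions = {k[1] for k in self._by_key if k[0] == s}
            if regions != set(REGIONS):
                raise ConfigurationError(
                    f"sector {s!r} missing regions {set(REGIONS) - regions}")
            if s not in self.category_map:
                raise ConfigurationError(f"sector {s!r} not in category map")
            if self.category_map[s] not in CATEGORIES:
                raise ConfigurationError(
                    f"sector {s!r} maps to unknown category "
                    f"{self.category_map[s]!r}")
            if s not in self.default_variant:
                raise ConfigurationError(f"sector {s!r} has no default variant")

    def variants_for(self, sector: str) -> tuple:
        return tuple(sorted({k[2] for k in self._by_key if k[0] == sector}))

    def lookup(self, sector: str, region: str, variant: str) -> list:
        key = (sector, region, variant)
        if key not in self._by_key:
            raise ConfigurationError(
                f"no entry for sector {sector!r} region {region!r} variant "
                f"{variant!r}; available variants: "
                f"{self.variants_for(sector)}")
        return self._by_key[key]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SectorRegistry):
            return NotImplemented
        return registry_to_json(self) == registry_to_json(other)


# ----------------------------------------------------------------------
# Evaluation
# ----------------------------------------------------------------------

@dataclass
class DamageTable:
    """Long-format impacts: scenario x year x sector x region.

    ``usd2015`` is the monetised impact per year; physical endpoints are
    carried alongside where a sector has them.
    """

    data: pd.DataFrame
    ref_gdppc: float
    ref_region_pop: dict

    COLUMNS = ("scenario_id", "year", "sector", "region", "variant",
               "usd2015", "physical_value", "physical_unit")

    def national_total(self) -> Trajectory:
        """Total monetised damages per year, summed over sectors/regions."""
        s = self.data.groupby("year")["usd2015"].sum().sort_index()
        return Trajectory(s.index.to_numpy(), s.to_numpy(), units="2015 USD/yr")

    def regional_totals(self) -> pd.DataFrame:
        return (self.data.groupby(["year", "region"])["usd2015"].sum()
                .unstack("region"))

    def sector_totals(self) -> pd.DataFrame:
        return (self.data.groupby(["year", "sector"])["usd2015"].sum()
                .unstack("sector"))

    def category_totals(self, category_map: Mapping[str, str]) -> pd.DataFrame:
        df = self.data.copy()
        df["category"] = df["sector"].map(category_map)
        return df.groupby(["year", "category"])["usd2015"].sum().unstack()

    def physical_totals(self) -> pd.DataFrame:
        phys = self.data.dropna(subset=["physical_unit"])
        return (phys.groupby(["year", "sector", "physical_unit"])
                ["physical_value"].sum().reset_index())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def run_damages(scenario: Scenario,
                conus_traj: TemperatureTrajectory,
                gmsl_traj: GMSLTrajectory,
                registry: SectorRegistry,
                variant_selection: Mapping[str, str] | None = None,
                shares: RegionalShares | None = None) -> DamageTable:
    """Evaluate every sector x region for one scenario.

    For each year: evaluate the driver-appropriate response at the
    selected adaptation variant, scale by that year's regional population
    and national GDP per capita, and average across GCMs.  National
    totals equal the sum over regions and sectors by construction.
    """
    if conus_traj.domain != "CONUS":
        raise InvalidArgumentError("damage functions take CONUS warming")
    years = require_same_grid(scenario.gdp, conus_traj, gmsl_traj)
    shares = shares or default_regional_shares()
    variant_selection = dict(variant_selection or {})

    pop_regional = shares.share_matrix(years) * scenario.population.values
    gdppc = scenario.gdp.values / scenario.population.values
    gdppc_ratio = gdppc / registry.ref_gdppc

    records = []
    for sector in registry.sectors:
        variant = variant_selection.get(sector,
                                        registry.default_variant[sector])
        for ir, region in enumerate(REGIONS):
            entries = registry.lookup(sector, region, variant)
            raw = gcm_average([
                eval_temp_damage(e, conus_traj.values)
                if isinstance(e, DamageFunction)
                else np.array([eval_slr_damage(e, int(y), g)
                               for y, g in zip(years, gmsl_traj.values)])
                for e in entries
            ])
            proto = entries[0]
            ref_pop = registry.ref_region_pop[region]
            scaled = scale_impacts(
                raw, ref_pop, registry.ref_gdppc,
                pop_regional[ir], gdppc,
                {"population_proportional": proto.population_proportional,
                 "gdppc_elasticity": proto.gdppc_elasticity})
            if proto.endpoint_unit is not None:
                physical = scaled
                usd = (physical * proto.unit_value
                       * gdppc_ratio ** proto.unit_value_elasticity)
                records.append(pd.DataFrame({
                    "scenario_id": scenario.id, "year": years,
                    "sector": sector, "region": region, "variant": variant,
                    "usd2015": usd, "physical_value": physical,
                    "physical_unit": proto.endpoint_unit}))
            else:
                records.append(pd.DataFrame({
                    "scenario_id": scenario.id, "year": years,
                    "sector": sector, "region": region, "variant": variant,
                    "usd2015": scaled, "physical_value": np.nan,
                    "physical_unit": None}))
    if records:
        data = pd.concat(records, ignore_index=True)
    else:
        data = pd.DataFrame(columns=list(DamageTable.COLUMNS))
    return DamageTable(data, registry.ref_gdppc, dict(registry.ref_region_pop))


def evaluate_national_ensemble(
    registry: SectorRegistry,
    years: np.ndarray,
    conus: np.ndarray,          # (n, T)
    gmsl: np.ndarray,           # (n, T)
    population: np.ndarray,     # (n, T) national
    gdp: np.ndarray,            # (n, T)
    variant_selection: Mapping[str, str] | None = None,
    shares: RegionalShares | None = None,
) -> np.ndarray:
    """Vectorised national total monetised damages, shape (n, T).

    Same arithmetic as :func:`run_damages` summed over sectors and
    regions; used by the pulse experiments where only the national
    stream matters.
    """
    shares = shares or default_regional_shares()
    variant_selection = dict(variant_selection or {})
    share_mat = shares.share_matrix(years)            # (7, T)
    gdppc = gdp / population
    gdppc_ratio = gdppc / registry.ref_gdppc
    total = np.zeros_like(conus)
    for sector in registry.sectors:
        variant = variant_selection.get(sector,
                                        registry.default_variant[sector])
        for ir, region in enumerate(REGIONS):
            entries = registry.lookup(sector, region, variant)
            raws = []
            for e in entries:
                if isinstance(e, DamageFunction):
                    raws.append(_interp_with_slope_extrapolation(
                        conus, e.anchor_temps, e.anchor_impacts))
                else:
                    raws.append(_eval_surface_grid(e, years, gmsl))
            raw = gcm_average(raws)
            proto = entries[0]
            pop_r = share_mat[ir][None, :] * population
            scaled = raw
            if proto.population_proportional:
                scaled = scaled * (pop_r / registry.ref_region_pop[region])
            if proto.gdppc_elasticity != 0.0:
                scaled = scaled * gdppc_ratio ** proto.gdppc_elasticity
            if proto.endpoint_unit is not None:
                scaled = (scaled * proto.unit_value
                          * gdppc_ratio ** proto.unit_value_elasticity)
            total = total + scaled
    return total


def _eval_surface_grid(surface: SLRSurface, years: np.ndarray,
                       gmsl: np.ndarray) -> np.ndarray:
    """Vectorised surface evaluation for (n, T) sea-level paths; ``years``
    may be any subset of the surface's (annual) year grid."""
    row_idx = np.asarray(years, dtype=int) - int(surface.years[0])
    if np.any(row_idx < 0) or np.any(row_idx >= len(surface.years)):
        raise InvalidArgumentError("years outside surface grid")
    rows = surface.values[row_idx]                    # (T, H)
    h = surface.heights
    out = np.empty_like(gmsl)
    for t in range(len(years)):
        row = rows[t]
        v = np.interp(gmsl[:, t], h, row)
        above = gmsl[:, t] > h[-1]
        if np.any(above):
            s = (row[-1] - row[-2]) / (h[-1] - h[-2])
            v = np.where(above, row[-1] + s * (gmsl[:, t] - h[-1]), v)
        out[:, t] = v
    return out


def damages_share_of_gdp(table: DamageTable, gdp: Trajectory) -> Trajectory:
    """National damages as a fraction of GDP per year."""
    total = table.national_total()
    if not total.same_grid(gdp):
        raise InvalidArgumentError("damage table and GDP on different grids")
    if np.any(gdp.values == 0):
        raise InvalidArgumentError("zero GDP")
    return Trajectory(gdp.years, total.values / gdp.values, units="fraction")


# ----------------------------------------------------------------------
# Synthetic registry
# ----------------------------------------------------------------------

# sector name, category, driver, endpoint unit (None = direct USD),
# national scale at 3 degC CONUS (physical units or billion 2015 USD),
# curvature exponent, variants available, regional bias
_SECTOR_SPECS = [
    ("temperature mortality", "health", "temp", "deaths", 35_000.0, 1.9,
     (VARIANT_NO_ADAPT,), None),
    ("air quality mortality", "health", "temp", "deaths", 3_600.0, 1.6,
     (VARIANT_NO_ADAPT,), "midwest_benefit"),
    ("wildfire", "health", "temp", "deaths", 800.0, 1.8,
     (VARIANT_NO_ADAPT,), "west"),
    ("southwest dust", "health", "temp", "deaths", 280.0, 1.5,
     (VARIANT_NO_ADAPT,), "southwest"),
    ("valley fever", "health", "temp", "deaths", 210.0, 1.7,
     (VARIANT_NO_ADAPT,), "southwest"),
    ("crime", "health", "temp", "incidents", 3_300.0, 1.2,
     (VARIANT_NO_ADAPT,), None),
    ("high-tide flooding transportation", "infrastructure", "slr", None,
     50.0, 1.2, (VARIANT_REACTIVE, VARIANT_NO_ADAPT), "coastal"),
    ("coastal properties", "infrastructure", "slr", None, 6.5, 1.3,
     (VARIANT_REACTIVE, VARIANT_NO_ADAPT, VARIANT_PROACTIVE), "coastal"),
    ("rail", "infrastructure", "temp", None, 7.0, 1.5,
     (VARIANT_REACTIVE, VARIANT_NO_ADAPT, VARIANT_PROACTIVE), None),
    ("roads", "infrastructure", "temp", None, 6.5, 1.5,
     (VARIANT_REACTIVE, VARIANT_NO_ADAPT, VARIANT_PROACTIVE), None),
    ("urban drainage", "infrastructure", "temp", None, 2.0, 1.6,
     (VARIANT_ANTICIPATED, VARIANT_NO_ADAPT), None),
    ("tropical storm wind damage", "infrastructure", "temp", None, 10.0,
     1.4, (VARIANT_NO_ADAPT,), "coastal"),
    ("labor", "labor", "temp", "hours", 320.0e6, 1.4,
     (VARIANT_NO_ADAPT,), "south"),
    ("electricity demand", "electricity", "temp", None, 5.5, 1.5,
     (VARIANT_NO_ADAPT,), None),
    ("electricity supply", "electricity", "temp", None, 2.5, 1.5,
     (VARIANT_NO_ADAPT,), None),
    ("agriculture", "agriculture", "temp", None, 2.2, 1.6,
     (VARIANT_NO_ADAPT,), None),
    ("water quality", "ecosystems and recreation", "temp", None, 0.55,
     1.4, (VARIANT_NO_ADAPT,), None),
    ("winter recreation", "ecosystems and recreation", "temp", None, 0.45,
     1.3, (VARIANT_NO_ADAPT,), "north"),
    ("freshwater fish", "ecosystems and recreation", "temp", None, 0.30,
     1.4, (VARIANT_NO_ADAPT,), "north"),
    ("coral reefs", "ecosystems and recreation", "temp", None, 0.25, 1.2,
     (VARIANT_NO_ADAPT,), "coastal"),
]

_UNIT_VALUES = {"deaths": 10.05e6, "hours": 36.0, "incidents": 28_000.0}

# adaptation damps damages; ordering no-adapt >= reactive/anticipated >=
# proactive is preserved at every temperature because it is a pure scaling
_VARIANT_FACTOR = {VARIANT_NO_ADAPT: 1.0, VARIANT_REACTIVE: 0.55,
                   VARIANT_ANTICIPATED: 0.60, VARIANT_PROACTIVE: 0.44}

_REGION_BIAS = {
    None: {},
    "west": {"Northwest": 3.0, "Southwest": 3.0, "Northern Plains": 1.5},
    "southwest": {"Southwest": 8.0},
    "coastal": {"Southeast": 3.2, "Northeast": 1.8, "Southern Plains": 1.4,
                "Midwest": 0.15, "Northern Plains": 0.05},
    "south": {"Southeast": 2.2, "Southern Plains": 1.8, "Southwest": 1.4},
    "north": {"Northeast": 2.0, "Midwest": 2.0, "Northern Plains": 1.6,
              "Northwest": 1.6},
    "midwest_benefit": {},
}


def synth_damage_registry(seed: int, spec: Sequence | None = None,
                          n_gcms: int = 3,
                          slr_years: np.ndarray | None = None,
                          ) -> SectorRegistry:
    """Seeded synthetic 20-sector registry.

    Anchors are convex and increasing for most sectors; the air-quality
    sector is beneficial (negative) in the Midwest; two sectors are
    driven by sea level (year x height surfaces); every sector has 2+
    GCM variants of its response.  Same seed -> identical registry.
    """
    spec = spec if spec is not None else _SECTOR_SPECS
    if not spec:
        raise InvalidArgumentError("empty registry spec")
    for row in spec:
        if row[1] not in CATEGORIES:
            raise InvalidArgumentError(
                f"sector {row[0]!r} has unknown category {row[1]!r}")
    rng = np.random.default_rng(seed)
    slr_years = (np.arange(2020, 2301) if slr_years is None
                 else np.asarray(slr_years, dtype=int))
    gcms = [f"gcm{i:02d}" for i in range(n_gcms)]
    shares2020 = default_regional_shares().share_matrix(np.array([2020]))[:, 0]
    ref_region_pop = {r: 331.5e6 * s for r, s in zip(REGIONS, shares2020)}
    ref_gdppc = 58_000.0

    anchor_temps = np.array([0.0, 1.0, 2.0, 3.0, 4.5, 6.0, 8.0, 10.0])
    entries: list = []
    category_map: dict[str, str] = {}
    default_variant: dict[str, str] = {}

    for (sector, category, driver, unit, scale3c, curve, variants,
         bias) in spec:
        category_map[sector] = category
        default_variant[sector] = variants[0]
        weights = np.array([_REGION_BIAS[bias].get(r, 1.0) for r in REGIONS])
        weights = weights * rng.uniform(0.75, 1.25, size=len(REGIONS))
        weights = weights / weights.sum()
        usd_scale = 1e9 if unit is None else 1.0
        for ir, region in enumerate(REGIONS):
            sign = 1.0
            if bias == "midwest_benefit" and region == "Midwest":
                sign = -1.0   # beneficial impact under warming
            base = sign * scale3c * usd_scale * weights[ir]
            for variant in variants:
                vf = _VARIANT_FACTOR[variant]
                for gcm in gcms:
                    gf = rng.uniform(0.8, 1.2)
                    if driver == "temp":
                        impacts = (base * vf * gf
                                   * (anchor_temps / 3.0) ** curve)
                        entries.append(DamageFunction(
                            sector=sector, region=region, variant=variant,
                            gcm=gcm, anchor_temps=anchor_temps,
                            anchor_impacts=impacts,
                            population_proportional=True,
                            gdppc_elasticity=(1.0 if unit is None else 0.0),
                            endpoint_unit=unit,
                            unit_value=_UNIT_VALUES.get(unit),
                        ))
                    else:
                        heights = np.array([0.0, 10.0, 25.0, 50.0, 100.0,
                                            200.0, 350.0])
                        growth = 1.0 + 0.002 * (slr_years - slr_years[0])
                        prof = (heights / 50.0) ** curve
                        values = (base * vf * gf
                                  * growth[:, None] * prof[None, :])
                        entries.append(SLRSurface(
                            sector=sector, region=region, variant=variant,
                            gcm=gcm, years=slr_years, heights=heights,
                            values=values,
                            population_proportional=True,
                            gdppc_elasticity=1.0,
                        ))
    return SectorRegistry(entries, category_map, default_variant,
                          ref_gdppc, ref_region_pop,
                          expected_sectors=len(spec))


# ----------------------------------------------------------------------
# JSON round-trip
# ----------------------------------------------------------------------

def registry_to_json(registry: SectorRegistry) -> dict:
    """Serialisable dict form of a registry."""
    items = []
    for e in sorted(registry.entries,
                    key=lambda e: (e.sector, e.region, e.variant, e.gcm)):
        common = {
            "sector": e.sector, "region": e.region, "variant": e.variant,
            "gcm": e.gcm, "category": registry.category_map[e.sector],
            "scaling": {"population_proportional": e.population_proportional,
                        "gdppc_elasticity": e.gdppc_elasticity},
        }
        if e.endpoint_unit is not None:
            common["endpoint"] = {"unit": e.endpoint_unit,
                                  "unit_value": e.unit_value,
                                  "elasticity": e.unit_value_elasticity}
        if isinstance(e, DamageFunction):
            common["driver"] = "temp"
            common["anchors"] = [[float(t), float(i)] for t, i in
                                 zip(e.anchor_temps, e.anchor_impacts)]
        else:
            common["driver"] = "slr"
            common["surface"] = {"years": e.years.tolist(),
                                 "heights": e.heights.tolist(),
                                 "values": e.values.tolist()}
        items.append(common)
    return {
        "entries": items,
        "default_variant": registry.default_variant,
        "ref_gdppc": registry.ref_gdppc,
        "ref_region_pop": registry.ref_region_pop,
        "expected_sectors": registry.expected_sectors,
    }


def registry_from_json(doc: Mapping) -> SectorRegistry:
    """Inverse of :func:`registry_to_json`."""
    entries: list = []
    category_map: dict[str, str] = {}
    for item in doc["entries"]:
        try:
            scaling = item["scaling"]
            endpoint = item.get("endpoint")
            kw = dict(
                sector=item["sector"], region=item["region"],
                variant=item["variant"], gcm=item["gcm"],
                population_proportional=scaling["population_proportional"],
                gdppc_elasticity=scaling["gdppc_elasticity"],
                endpoint_unit=endpoint["unit"] if endpoint else None,
                unit_value=endpoint["unit_value"] if endpoint else None,
                unit_value_elasticity=(endpoint["elasticity"] if endpoint
                                       else 1.0),
            )
            category_map[item["sector"]] = item["category"]
            if item["driver"] == "temp":
                anchors = np.asarray(item["anchors"], dtype=float)
                entries.append(DamageFunction(
                    anchor_temps=anchors[:, 0], anchor_impacts=anchors[:, 1],
                    **kw))
            else:
                s = item["surface"]
                entries.append(SLRSurface(
                    years=np.asarray(s["years"], dtype=int),
                    heights=np.asarray(s["heights"], dtype=float),
                    values=np.asarray(s["values"], dtype=float), **kw))
        except KeyError as exc:
            raise FormatError(f"registry entry missing key {exc}") from exc
    return SectorRegistry(entries, category_map, doc["default_variant"],
                          doc["ref_gdppc"], doc["ref_region_pop"],
                          expected_sectors=doc.get("expected_sectors", 20))


def write_registry(registry: SectorRegistry, path) -> None:
    with open(path, "w") as fh:
        json.dump(registry_to_json(registry), fh)


def read_registry(path) -> SectorRegistry:
    with open(path) as fh:
        return registry_from_json(json.load(fh))
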