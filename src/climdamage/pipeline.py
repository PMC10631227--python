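"""End-to-end Monte Carlo orchestration.

One master seed drives the whole chain.  Child seeds for the scenario
generator, the climate-parameter sampler and the synthetic damage
registry are derived by ``numpy.random.SeedSequence(master).generate_state``
(documented, platform-stable), so baseline and pulse runs share climate
parameters exactly and a rerun with the same config reproduces identical
artifacts.

Artifacts written to the output directory:

* ``scenarios.csv`` -- the generated ensemble (long format)
* ``temperature_global.csv`` / ``temperature_conus.csv`` / ``gmsl.csv``
* ``damages.csv`` -- per scenario x year x sector x region (optional,
  heavy for large n)
* ``summary_categories.csv`` / ``summary_sectors.csv`` /
  ``summary_regions.csv`` -- means, medians and 5-95 / 1-99 bands at the
  report years; regional tables include per-capita damages
* ``summary_physical.csv`` -- physical endpoints at the report years
* ``share_of_gdp.csv`` -- mean/median/band trajectory of damages/GDP
* ``sv_results.csv`` -- group rates and differential risk at the last
  report year
* ``pulse_<gas>.csv`` + ``pulse_summary.json`` -- per-tonne results
* ``manifest.json`` -- config hash, derived seeds, package version
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .climate import (ClimateParamPriors, EmulatorConfig,
                      run_climate_ensemble, sample_climate_params)
from .damages import (SectorRegistry, run_damages, synth_damage_registry,
                      evaluate_national_ensemble,
                      _interp_with_slope_extrapolation, _eval_surface_grid,
                      DamageFunction, gcm_average)
from .errors import ConfigurationError, InvalidArgumentError
from .scenarios import (REGIONS, GeneratorCalibration, default_regional_shares,
                        generate_scenario_set, write_scenarios)
from .trajectories import TemperatureTrajectory, GMSLTrajectory
from .valuation import (DiscountSpec, PulseSpec, run_pulse_experiment,
                        usd_convert, summarize_distribution)
from .vulnerability import allocate_group_impacts, default_group_shares

log = logging.getLogger("climdamage")

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclass
class RunConfig:
    """Settings for one full pipeline run."""

    n_scenarios: int = 100
    seed: int = 1
    out_dir: str = "climdamage-run"
    report_years: tuple = (2050, 2070, 2090)
    calibration: GeneratorCalibration = field(
        default_factory=GeneratorCalibration)
    priors: ClimateParamPriors = field(default_factory=ClimateParamPriors)
    emulator: EmulatorConfig = field(default_factory=EmulatorConfig)
    registry_seed: int = 7
    variant_selection: dict = field(default_factory=dict)
    discounts: Sequence[DiscountSpec] = (DiscountSpec(),)
    pulses: Sequence[PulseSpec] = ()
    write_damage_table: bool = True
    run_sv: bool = True

    def validate(self, registry: SectorRegistry) -> None:
        if self.n_scenarios < 1:
            raise InvalidArgumentError("n_scenarios must be >= 1")
        for y in self.report_years:
            if not (2020 <= y <= 2300):
                raise InvalidArgumentError(f"report year {y} outside grid")
        for sector, variant in self.variant_selection.items():
            if sector not in registry.sectors:
                raise ConfigurationError(
                    f"unknown sector {sector!r}; known: {registry.sectors}")
            if variant not in registry.variants_for(sector):
                raise ConfigurationError(
                    f"sector {sector!r} has no variant {variant!r}; "
                    f"available: {registry.variants_for(sector)}")

    def child_seeds(self) -> dict[str, int]:
        """Derived sub-module seeds (stable under the master seed)."""
        state = np.random.SeedSequence(self.seed).generate_state(4)
        names = ("scenarios", "climate", "registry_jitter", "reserved")
        return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}


def _band_summary(values: np.ndarray, axis: int = 0) -> dict[str, np.ndarray]:
    """Mean/median and the 5-95 and 1-99 percentile bands."""
    return {
        "mean": values.mean(axis=axis),
        "median": np.percentile(values, 50, axis=axis),
        "p5": np.percentile(values, 5, axis=axis),
        "p95": np.percentile(values, 95, axis=axis),
        "p1": np.percentile(values, 1, axis=axis),
        "p99": np.percentile(values, 99, axis=axis),
    }


def _evaluate_report_slices(registry, years, idx, conus, gmsl, population,
                            gdp, shares, variant_selection):
    """usd (n, R, S, 7) and physical (n, R, S) at the report-year indices."""
    n = conus.shape[0]
    sectors = registry.sectors
    share_mat = shares.share_matrix(years)
    gdppc = gdp / population
    ratio = gdppc / registry.ref_gdppc
    usd = np.zeros((n, len(idx), len(sectors), len(REGIONS)))
    phys = np.full((n, len(idx), len(sectors)), np.nan)
    units = {}
    c_slice = conus[:, idx]
    g_slice = gmsl[:, idx]
    for js, sector in enumerate(sectors):
        variant = variant_selection.get(sector,
                                        registry.default_variant[sector])
        has_endpoint = False
        for ir, region in enumerate(REGIONS):
            entries = registry.lookup(sector, region, variant)
            raws = []
            for e in entries:
                if isinstance(e, DamageFunction):
                    raws.append(_interp_with_slope_extrapolation(
                        c_slice, e.anchor_temps, e.anchor_impacts))
                else:
                    raws.append(_eval_surface_grid(e, years[idx], g_slice))
            raw = gcm_average(raws)
            proto = entries[0]
            pop_r = share_mat[ir][None, idx] * population[:, idx]
            scaled = raw
            if proto.population_proportional:
                scaled = scaled * pop_r / registry.ref_region_pop[region]
            if proto.gdppc_elasticity != 0.0:
                scaled = scaled * ratio[:, idx] ** proto.gdppc_elasticity
            if proto.endpoint_unit is not None:
                has_endpoint = True
                units[sector] = proto.endpoint_unit
                if np.all(np.isnan(phys[:, :, js])):
                    phys[:, :, js] = 0.0
                phys[:, :, js] += scaled
                scaled = (scaled * proto.unit_value
                          * ratio[:, idx] ** proto.unit_value_elasticity)
            usd[:, :, js, ir] = scaled
        if not has_endpoint:
            phys[:, :, js] = np.nan
    return usd, phys, units


def run_full_pipeline(config: RunConfig) -> dict:
    """Run the whole chain and write artifacts; returns a result dict."""
    registry = synth_damage_registry(config.registry_seed)
    config.validate(registry)
    seeds = config.child_seeds()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shares = default_regional_shares()

    log.info("generating %d scenarios (seed %d)", config.n_scenarios,
             seeds["scenarios"])
    sset = generate_scenario_set(config.n_scenarios, seeds["scenarios"],
                                 config.calibration)
    write_scenarios(sset, out / "scenarios.csv")

    log.info("sampling %d climate parameter sets (seed %d)",
             config.n_scenarios, seeds["climate"])
    ens = sample_climate_params(config.n_scenarios, seeds["climate"],
                                config.priors)
    clim = run_climate_ensemble(sset, ens, config.emulator)
    years = sset.years
    n, T = clim["conus"].shape

    for name, arr in (("temperature_global", clim["global_modern"]),
                      ("temperature_conus", clim["conus"]),
                      ("gmsl", clim["gmsl"])):
        pd.DataFrame({
            "scenario_id": np.repeat(sset.ids, T),
            "year": np.tile(years, n),
            "value": arr.ravel(),
        }).to_csv(out / f"{name}.csv", index=False)

    log.info("evaluating damages for %d scenarios", n)
    national = evaluate_national_ensemble(
        registry, years, clim["conus"], clim["gmsl"], sset.population,
        sset.gdp, variant_selection=config.variant_selection, shares=shares)

    idx = np.array([int(y - years[0]) for y in config.report_years])
    usd, phys, units = _evaluate_report_slices(
        registry, years, idx, clim["conus"], clim["gmsl"], sset.population,
        sset.gdp, shares, config.variant_selection)
    # conservation check: report-year sector x region slices vs national
    slice_total = usd.sum(axis=(2, 3))
    if not np.allclose(slice_total, national[:, idx], rtol=1e-9, atol=1e-3):
        raise AssertionError("sector/region slices do not sum to national")

    if config.write_damage_table:
        frames = []
        for i in range(n):
            conus_i = TemperatureTrajectory(
                years, clim["conus"][i], baseline="1986-2005", domain="CONUS")
            gmsl_i = GMSLTrajectory(years, clim["gmsl"][i])
            frames.append(run_damages(
                sset.scenario(i), conus_i, gmsl_i, registry,
                variant_selection=config.variant_selection,
                shares=shares).data)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "damages.csv", index=False)

    sectors = registry.sectors
    cats = sorted({registry.category_map[s] for s in sectors})
    cat_idx = {c: [j for j, s in enumerate(sectors)
                   if registry.category_map[s] == c] for c in cats}

    def frame(summary: Mapping[str, np.ndarray], columns, year_list):
        rows = []
        for stat, arr in summary.items():
            for iy, y in enumerate(year_list):
                rows.append({"statistic": stat, "year": y,
                             **dict(zip(columns, np.atleast_2d(arr)[iy]))})
        return pd.DataFrame(rows)

    usd20 = usd_convert(usd, 2015, 2020)   # report in 2020 USD
    by_sector = usd20.sum(axis=3)
    by_region = usd20.sum(axis=2)
    by_cat = np.stack([by_sector[:, :, cat_idx[c]].sum(axis=2)
                       for c in cats], axis=2)
    by_cat = np.concatenate([by_cat, by_cat.sum(axis=2, keepdims=True)],
                            axis=2)
    frame(_band_summary(by_cat), cats + ["total"],
          list(config.report_years)).to_csv(
        out / "summary_categories.csv", index=False)
    frame(_band_summary(by_sector), list(sectors),
          list(config.report_years)).to_csv(
        out / "summary_sectors.csv", index=False)

    share_mat = shares.share_matrix(years)
    pop_regional = (share_mat[None, :, :] *
                    sset.population[:, None, :])[:, :, idx]  # (n, 7, R)
    percap = by_region / np.transpose(pop_regional, (0, 2, 1))
    reg_frame = frame(_band_summary(by_region), list(REGIONS),
                      list(config.report_years))
    reg_frame["kind"] = "total_usd2020"
    pc_frame = frame(_band_summary(percap), list(REGIONS),
                     list(config.report_years))
    pc_frame["kind"] = "usd2020_per_capita"
    pd.concat([reg_frame, pc_frame], ignore_index=True).to_csv(
        out / "summary_regions.csv", index=False)

    phys_rows = []
    for js, sector in enumerate(sectors):
        if sector not in units:
            continue
        stats = _band_summary(phys[:, :, js])
        for stat, arr in stats.items():
            for iy, y in enumerate(config.report_years):
                phys_rows.append({"sector": sector, "unit": units[sector],
                                  "statistic": stat, "year": y,
                                  "value": np.atleast_1d(arr)[iy]})
    pd.DataFrame(phys_rows).to_csv(out / "summary_physical.csv", index=False)

    share_gdp = national / sset.gdp
    sg = _band_summary(share_gdp)
    pd.DataFrame({"year": years, **{k: v for k, v in sg.items()}}).to_csv(
        out / "share_of_gdp.csv", index=False)

    sv_frame = None
    if config.run_sv:
        sv_year = config.report_years[-1]
        jy = list(config.report_years).index(sv_year)
        group_shares = default_group_shares()
        pop_by_region = {r: pop_regional[:, ir, jy].mean()
                         for ir, r in enumerate(REGIONS)}
        rows = []
        for js, sector in enumerate(sectors):
            if sector not in units:
                continue
            # mean regional physical impact across the ensemble
            imp = {}
            for ir, r in enumerate(REGIONS):
                entries = registry.lookup(
                    sector, r, config.variant_selection.get(
                        sector, registry.default_variant[sector]))
                raws = []
                for e in entries:
                    raws.append(_interp_with_slope_extrapolation(
                        clim["conus"][:, idx[jy]], e.anchor_temps,
                        e.anchor_impacts))
                raw = gcm_average(raws)
                proto = entries[0]
                val = raw
                if proto.population_proportional:
                    val = val * (pop_regional[:, ir, jy]
                                 / registry.ref_region_pop[r])
                imp[r] = float(np.mean(val))
            for axis, gs in group_shares.items():
                for res in allocate_group_impacts(imp, gs, pop_by_region):
                    rows.append({"sector": sector, "year": sv_year,
                                 "axis": axis, "group": res.group,
                                 "rate_per_100k": res.rate,
                                 "risk_ratio": res.risk_ratio,
                                 "rate_difference": res.rate_difference})
        sv_frame = pd.DataFrame(rows)
        sv_frame.to_csv(out / "sv_results.csv", index=False)

    pulse_summaries = {}
    for pulse in config.pulses:
        for disc in config.discounts:
            result = run_pulse_experiment(
                sset, ens, registry, pulse, disc,
                config=config.emulator, shares=shares,
                variant_selection=config.variant_selection)
            label = f"{pulse.gas}_{disc.mode}"
            pd.DataFrame({"scenario_id": sset.ids,
                          "usd2020_per_tonne": result.values}).to_csv(
                out / f"pulse_{label}.csv", index=False)
            pulse_summaries[label] = result.summary
    if pulse_summaries:
        with open(out / "pulse_summary.json", "w") as fh:
            json.dump(pulse_summaries, fh, indent=2)

    config_doc = json.dumps(_config_doc(config), sort_keys=True)
    manifest = {
        "package": "climdamage",
        "version": __version__,
        "master_seed": config.seed,
        "derived_seeds": seeds,
        "n_scenarios": config.n_scenarios,
        "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
        "monetary_units": "summaries in 2020 USD (engine-internal 2015 USD)",
        "deflator_2015_to_2020": usd_convert(1.0, 2015, 2020),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {"scenarios": sset, "climate": clim, "registry": registry,
            "national_usd2015": national, "manifest": manifest,
            "pulse_summaries": pulse_summaries, "sv": sv_frame}


def _config_doc(config: RunConfig) -> dict:
    doc = {
        "n_scenarios": config.n_scenarios,
        "seed": config.seed,
        "report_years": list(config.report_years),
        "calibration": asdict(config.calibration),
        "priors": asdict(config.priors),
        "registry_seed": config.registry_seed,
        "variant_selection": dict(config.variant_selection),
        "discounts": [asdict(d) for d in config.discounts],
        "pulses": [asdict(p) for p in config.pulses],
    }
    em = asdict(config.emulator)
    em.pop("exogenous_forcing", None)
    doc["emulator"] = em
    return doc
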