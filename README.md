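# climdamage

Probabilistic projections of climate-driven economic and physical damages
within the contiguous United States (CONUS), 2020–2300, and the
net-present damages per tonne of CO₂, CH₄ or N₂O — a within-US-borders
analog of the social cost of a greenhouse gas.

The package is aimed at climate-economics and impact-assessment
researchers who want a fully synthetic, end-to-end testable version of
the now-standard probabilistic damage pipeline: sampled socioeconomic and
emissions futures, a reduced-complexity climate emulator, a
temperature-binned sectoral damage model, demographic exposure
distribution, and Ramsey-discounted pulse valuation. Every stage runs
from seeds — no external data downloads — so the whole chain is
reproducible and unit-testable at desk scale.

## The pipeline

1. **Scenarios** (`climdamage.scenarios`) — 10 000 paired annual
   trajectories of global CO₂/CH₄/N₂O emissions, US GDP and US
   population on the 2020–2300 grid. Per-capita growth is a persistent
   stochastic process around per-scenario long-run means; population
   follows a stochastic peak-and-decline path; emissions couple to GDP
   through a stochastically declining carbon intensity that may cross
   zero. National population is disaggregated to seven CONUS regions via
   a share table (held constant after 2090).
2. **Climate** (`climdamage.climate`) — a finite-amplitude
   impulse-response emulator: a 4-pool carbon cycle whose timescales are
   rescaled each year so the 100-yr integrated airborne fraction tracks
   `r0 + rc·Gu + rt·T`; one-box CH₄/N₂O; forcing `F2x·ln(C/C0)/ln 2`
   plus square-root forms; a two-box energy balance (equilibrium
   `F/λ`); CONUS warming = 1.42 × global; semi-empirical sea level
   `dS/dt = a·(T − T0)`. Parameter ensembles are sampled from documented
   priors (lognormal ECS, median 3 °C).
3. **Damages** (`climdamage.damages`) — 20 sectors × 7 regions ×
   adaptation variants × GCMs. Temperature sectors are piecewise-linear
   in CONUS warming over the 1986–2005 baseline (linear extrapolation
   beyond the last anchor); sea-level sectors interpolate year × height
   impact surfaces. Impacts scale with regional population and national
   GDP per capita; mortality-type endpoints are monetised with a VSL
   whose GDP-per-capita elasticity is 1. Sectors and regions are
   additive.
4. **Vulnerability** (`climdamage.vulnerability`) — physical impacts are
   allocated across demographic groups by exposure shares; reports rates
   per 100 000 and risk ratios against the complement population.
5. **Valuation** (`climdamage.valuation`) — constant-rate NPV
   `Σ D(t)/(1+r)^(t−2020)` or Ramsey discounting `r_t = ρ + η·g_t` with
   damage-adjusted consumption growth and the saturation correction
   `D = D₀/(1 + D₀/GDP₀)`; emission-pulse experiments difference a
   baseline and a pulsed run of the full chain and normalise per tonne.

## Worked example

```python
import numpy as np
from climdamage import (generate_scenario_set, sample_climate_params,
                        run_climate_ensemble, synth_damage_registry,
                        run_pulse_experiment, PulseSpec, DiscountSpec,
                        usd_convert)
from climdamage.damages import evaluate_national_ensemble

sset = generate_scenario_set(n=500, seed=1)
ens = sample_climate_params(n=500, seed=2)
clim = run_climate_ensemble(sset, ens)
i90 = 2090 - 2020
print(f"GMST anomaly 2090 (vs 1986-2005): "
      f"{clim['global_modern'][:, i90].mean():.2f} degC")

registry = synth_damage_registry(seed=7)
national = evaluate_national_ensemble(
    registry, sset.years, clim["conus"], clim["gmsl"],
    sset.population, sset.gdp)
usd2020 = usd_convert(national[:, i90], 2015, 2020)
print(f"mean national damages 2090: {usd2020.mean() / 1e12:.2f} trillion "
      f"2020 USD ({100 * (national[:, i90] / sset.gdp[:, i90]).mean():.1f} % of GDP)")

result = run_pulse_experiment(sset, ens, registry,
                              PulseSpec(gas="CO2"), DiscountSpec())
s = result.summary
print(f"net-present damages per tonne CO2 (2 % Ramsey): "
      f"mean {s['mean']:.0f}, 95 % CI [{s['p2.5']:.0f}, {s['p97.5']:.0f}] 2020 USD")
```

prints

```
GMST anomaly 2090 (vs 1986-2005): 1.73 degC
mean national damages 2090: 1.85 trillion 2020 USD (2.0 % of GDP)
net-present damages per tonne CO2 (2 % Ramsey): mean 38, 95 % CI [11, 87] 2020 USD
```

The first line is the ensemble-mean warming entering the damage
functions; the second is total monetised damages across all 20 sectors
in 2090 under the synthetic registry; the third is the discounted
marginal damage of one extra tonne of CO₂ emitted in 2020, with the
spread across socioeconomic and climate-parameter uncertainty. (The
registry is a seeded synthetic calibration, so damage magnitudes are
illustrative; the climate and socioeconomic stages are calibrated to
documented ensemble moments.)

A command-line interface mirrors the library:

```
climdamage run --n 100 --seed 1 --out my-run      # full chain
climdamage generate / climate / damages / npv / pulse / fixtures
```

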