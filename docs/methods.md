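# Methods

This note documents the models behind `climdamage`, the choices made
where the design was genuinely open, and what the synthetic data do and
do not establish.

## Scenario generator

The generator emulates the structure of large probabilistic
socioeconomic ensembles: 10 000 equally likely paired trajectories of
global emissions, US GDP and US population, 2020–2300, with coupled
uncertainty between growth and emissions. It is calibrated so that a
10 000-member ensemble with the default hyperparameters reproduces a set
of documented summary moments — mean US population of ≈390 million in
2100 (95 % CI ≈[260, 520] million) and ≈370 million in 2300, and mean
time-averaged per-capita GDP growth of ≈1.5 %/yr to 2100 falling to
≈0.9 %/yr to 2300 — which the test suite re-verifies at full size.

**Per-capita GDP growth.** `g_t = μ_i(t) + ε_t` with
`μ_i(t) = μ∞,i + (μ0,i − μ∞,i)·exp(−t/τ_μ)`; `μ0,i ~ N(1.85 %, 1.1 %)`,
`μ∞,i` regresses on `μ0,i` with slope 0.5 around a 0.4 % mean,
`τ_μ = 120 yr`, and `ε_t` is AR(1) with persistence 0.9 and stationary
sd 1 %/yr. The declining long-run mean is what makes the 2100 and 2300
time-averaged growth targets simultaneously attainable.

**Population.** The annual growth rate declines linearly from a
stochastic initial value `g0,i ~ N(0.58 %, 0.25 %)` through zero at a
stochastic peak year `~N(2088, 45)`, then is floored at a decline rate
`~U(0, 0.7 %)` that itself relaxes to zero with a 60-yr e-folding:
trajectories peak, shrink, and stabilise. Two modelling points were
forced by multi-century behaviour rather than taste: (i) a *constant*
post-peak decline floor cannot match the 2100 moments and a
2300 mean within ~5 % of the 2100 mean at the same time — the main mass
decays too far — hence the relaxing floor (long-run demographic
stabilisation, as in long-horizon UN-style projections); (ii) draws with
negative initial growth flatten at zero growth after their nominal peak
year instead of following the linear rule, which would otherwise turn
the peak into a trough and produce unbounded growth.

**Emissions.** `CO₂ = GDP × intensity`, with relative intensity
`(1+c_i)·exp(−r_i·s(t)) − c_i` (it may cross zero; `c_i ~ Exp(0.02)`),
`r_i ~ N(1.8 %, 0.9 %)/yr`, and a saturating exponent
`s(t) = τ_r(1 − e^(−t/τ_r))`, `τ_r = 200 yr` (decarbonisation
decelerates over centuries). Intensity additionally falls with output:
emissions carry a GDP elasticity of 0.4. Without the elasticity and the
saturation, rare high-growth/slow-decline draws produce emission paths
of order 10² GtC/yr by 2300 and dominate every ensemble mean. Net
removals are capped at a per-scenario CDR capacity `~U(0, 3) GtC/yr`
rather than scaling with GDP indefinitely. CH₄ and N₂O scale with the
shared decarbonisation factor `exp(−r_i·s(t))` (exponents 1 and 0.7), so
all gases are positively correlated and CH₄/N₂O stay non-negative.

**What the generator does not emulate.** Country-level detail, the
expert-elicitation machinery behind the real product, climate→economy
feedback in generation, and the extreme right tail of multi-century
population uncertainty (our 2300 spread is narrower than the published
CI even though the mean matches). Tests that pass on this ensemble
establish that the pipeline's *mechanics* are correct under realistic
magnitudes; they do not validate the real ensemble's tails.

## Climate emulator

A finite-amplitude impulse-response structure, deliberately small:

* **CO₂**: four pools with partitions `a = (0.217, 0.224, 0.282, 0.276)`
  and timescales `τ = (∞, 394.4, 36.5, 4.3) yr` (the standard published
  IRF calibration). Each year all timescales are scaled by `α` so the
  100-yr integrated airborne fraction tracks
  `r0 + rc·(cumulative uptake) + rt·(warming)`,
  `(r0, rc, rt) = (35, 0.019, 4.165)`; `α` comes from the analytic
  inversion `α = g0·exp(iIRF100/g1)`.
* **CH₄/N₂O**: one-box decay to pre-industrial with lifetimes 9.3 and
  121 yr; burden-per-mixing-ratio constants 2.844 Mt/ppb (CH₄),
  7.80 Mt/ppb (N₂O), 2.124 GtC/ppm (CO₂).
* **Forcing**: `F2x·ln(C/C₀)/ln2` with `F2x = 3.93 W m⁻²`; square-root
  difference forms for CH₄ (0.036) and N₂O (0.12 W m⁻² ppb^-1/2); plus a
  prescribed exogenous series for all non-modelled species.
* **Thermal**: two boxes with heat capacities 8.2 and 109 W yr m⁻² K⁻¹,
  feedback `λ = F2x/ECS`, exchange coefficient 0.9 W m⁻² K⁻¹. Central
  ECS 3.0 °C; the implied transient response of the central set is
  ≈1.9 °C (1 %/yr CO₂ run, computed in the tests).

No parity with any specific released emulator version is claimed; the
structure and headline behaviour (central ECS ≈3 °C, plausible
historical warming) are the design targets.

**Numerical scheme.** Explicit annual stepping, state carried per year,
no adaptive solver — chosen for bit-reproducibility and speed
(10 000 × 451-yr coupled runs in seconds). Each linear subsystem is
advanced with its exact solution for piecewise-constant annual inputs
(matrix exponential for the two boxes, scalar exponentials for the
pools). Two second-order corrections matter at annual resolution, and
both were added after direct comparison against tight continuous-time
integrations of the same equations: the thermal step is driven by the
average of start- and end-of-year forcing, and `α` is applied as the
mean of a predictor (start-of-year state) and corrector (provisional
end-of-year state) pass. With both, the annual solution tracks a
`solve_ivp` integration of the coupled system to within 0.1 % of peak
response (asserted in the acceptance suite); with neither, the error is
≈0.8 %. Warming enters the carbon feedback with a one-year lag.

**Spin-up and baselines.** Scenario runs are prepended with synthetic
historical (1850–2019) emissions — smooth logistic curves calibrated so
cumulative CO₂ (≈617 GtC), 2019 emission rates, 2019 concentrations
(≈415 ppm, ≈1780 ppb, ≈316 ppb) and 2019 total forcing (≈2.7 W m⁻²)
land near observed values — plus an exogenous-forcing curve whose
aerosol term deepens then recovers (mid-range-pathway-like). Anomalies
are referenced to the run's own 1850–1900 mean. The 1850–1900 →
1986–2005 baseline offset is **derived from each run's own history** by
default (`EmulatorConfig.baseline_offset = None`), which is the
self-consistent choice when thermal parameters are sampled: a
high-sensitivity member has a warmer 1986–2005 period and should be
rebaselined accordingly. `compute_baseline_offset()` returns the
central-parameter scalar (≈0.72 °C) for standalone use. CONUS warming is
1.42 × global (config), defined only for 1986–2005-baselined global
input, and enforced by trajectory labels.

**Sea level.** `dS/dt = a (T_global − T₀)` with defaults
`a = 0.34 cm yr⁻¹ K⁻¹`, `T₀ = −0.15 °C` (vs 1850–1900), anchored at
+6.5 cm (over the 2000 datum) in 2020; trapezoidal integration on the
annual grid. This is a single-coefficient reduction of richer
semi-empirical syntheses; coefficients are config.

**Priors.** ECS lognormal (median 3.0, σ_log 0.28); truncated normals
for heat capacities, exchange coefficient, carbon-feedback constants and
CH₄ lifetime. The prior median of the implied ECS is analytic, which
the tests exploit.

## Damage engine

Temperature-binned functions per sector × region × adaptation variant ×
GCM: anchors at CONUS warming levels (first anchor exactly (0, 0), so
zero anomaly ⇒ zero impact — an invariant, since impacts are defined
relative to the 1986–2005 baseline), piecewise-linear between anchors,
and **linear extrapolation with the nearest segment's slope** beyond the
calibrated range (≤10 °C) and below zero; no slope damping. Ties at
anchor boundaries are exact by construction (both segments agree at the
anchor). Sea-level sectors carry year × height surfaces, interpolated
linearly across height at the query year; above the height grid the last
segment extrapolates; below the zero-height floor the floor value
applies.

Scaling: impact × (regional population / reference) where exposure is
population-proportional, × (GDP per capita / reference)^elasticity for
monetary sectors. Physical endpoints (deaths, hours, incidents) scale
with population only and are monetised by per-unit values (VSL-type,
default 10.05 M 2015 USD/death) with GDP-per-capita elasticity 1. GCM
members are averaged arithmetically. Sectors and regions are additive;
every run asserts regions→national and sectors→categories→total
conservation at 1e-9 relative.

The packaged registry is a **seeded synthetic calibration**: 20 sectors
in six categories (health 6, infrastructure 6, labor, electricity 2,
agriculture, ecosystems+recreation 4), convex increasing anchors, an
explicitly beneficial (negative) air-quality response in the Midwest,
two sea-level-driven sectors (coastal properties; high-tide flooding
transportation), ordered adaptation variants (no additional ≥ reactive ≥
proactive, as a pure scaling, so the ordering holds at every
temperature), and 2+ GCM labels per function. Magnitudes were sized so
a typical warming path yields health-dominated totals of the right
order, but the registry is a stand-in, not a calibration to any
underlying sectoral study; the sector list and category map are
editable config.

## Vulnerability distribution

Tract-level exposure arithmetic is linear, so it is coarsened without
error to region × group share matrices: group impact =
Σ_regions impact × impact_share(group, region); rates per 100 000 group
members; risk ratio and difference against the complement of the group
by default (configurable to the total population). Shares are constant
over time. The packaged fixture covers four axes (race/ethnicity,
income, age, educational attainment) with mild documented differentials;
it is synthetic and illustrative.

## Valuation

Constant-rate NPV discounts from the 2020 base year with the base-year
term undiscounted. Ramsey discounting uses `r_t = ρ + η·g_t` with the
printed 2 % near-term calibration (ρ = 0.2 %, η = 1.24) as default; the
1.5 % and 2.5 % pairs shipped in `RAMSEY_CALIBRATIONS` are this
package's own placeholders (flagged `published: False`). The product
defining the time-varying discount factor runs from the year *after*
the base year, so the base-year factor is exactly 1 and a
constant-growth Ramsey stream reduces to the constant-rate formula —
the alternative reading (product from the base year) double-discounts
year one and breaks that reduction.

Growth is damage-adjusted: `c_t = (GDP_t − D_t)/pop_t`,
`g_t = c_t/c_{t−1} − 1`, with the base-year entry copied from the first
pair and non-positive consumption reported as an error, never clipped.
Damages are first passed through `D = D₀/(1 + D₀/GDP₀)`, which keeps
them below exogenous GDP and accounts for the damage–growth feedback.

Pulse experiments add one gas's pulse (defaults: 1 GtC CO₂; 1 Mt CH₄ or
N₂O — the per-gas sizes are config since results are normalised per
tonne and the responses are linear at these sizes, which the linearity
test checks at 1 vs 0.5 Gt) in 2020, rerun the identical
scenario/parameter pairs, difference the two NPVs — each case discounted
along its **own** damage-adjusted growth path (state-specific rates;
a toggleable choice) — normalise by pulse mass in tonnes of the emitted
gas (GtC × 44.009/12.011 for CO₂) and convert to 2020 USD with the
packaged GDP-deflator table (BEA implicit price deflators; the
2015→2020 factor is data, not code).

## Pipeline

One master seed; child seeds for the generator, the parameter sampler
and fixtures derive from `numpy.random.SeedSequence(master)`, so reruns
are bit-identical (hash-checked in the tests) and baseline/pulse pairs
share climate parameters exactly. All randomness uses
`numpy.random.default_rng` (PCG64). Ensemble state is held as
(n, years) arrays — memory is linear in ensemble size with no
per-sector × per-year × per-scenario materialisation except the optional
long-format damage CSV, which is intended for small n.

Default problem sizes: the acceptance script and moment tests use the
full n = 10 000 ensemble (seconds per stage); damage-table and pulse
tests use n between 3 and 500, where the Monte Carlo summaries they
assert are scale-independent identities or orderings.

## Known limitations

* The scenario generator's 2300 population spread is narrower than the
  published ensemble's; only the means are calibrated there.
* The damage registry is synthetic: absolute dollar results are
  illustrative. Reproducing published sectoral dollar values requires
  the real sectoral calibration data, which are deliberately not
  bundled.
* No aerosol chemistry, per-species halocarbon cycles,
  volcanic/solar variability, tipping elements, ice-sheet dynamics, or
  inter-sector interactions.
* Damages outside CONUS, equity weighting and certainty-equivalent
  discounting beyond the Ramsey form are out of scope.
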