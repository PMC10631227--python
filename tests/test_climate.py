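"""Climate emulator: gas cycles, forcing, thermal response, baselines,
sea level, parameter sampling."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from climdamage import (ClimateParamPriors, ClimateParams, EmulatorConfig,
                        Trajectory, TemperatureTrajectory, compute_forcing,
                        conus_from_global, gmsl_from_temperature, rebaseline,
                        run_climate, run_gas_cycles, run_thermal,
                        sample_climate_params, generate_scenario_set)
from climdamage.climate import (GTC_PER_PPM, _ParamArrays, _integrate,
                                compute_baseline_offset)
from climdamage.errors import (InvalidArgumentError, InvalidCalibrationError,
                               InvalidStateError)
from climdamage.scenarios import Scenario
from climdamage.trajectories import default_years


def _flat_scenario(co2=0.0, ch4=0.0, n2o=0.0, years=None):
    years = default_years() if years is None else years
    T = len(years)
    mk = lambda v: Trajectory(years, np.full(T, float(v)))
    arr = lambda v: (Trajectory(years, v) if isinstance(v, np.ndarray)
                     else mk(v))
    return Scenario(id="flat", co2=arr(co2), ch4=arr(ch4), n2o=arr(n2o),
                    gdp=mk(1e12), population=mk(3e8))


class TestGasCycles:
    def test_zero_emissions_stay_preindustrial(self, central_params):
        conc = run_gas_cycles(_flat_scenario(), central_params)
        np.testing.assert_allclose(conc["co2"].values,
                                   central_params.co2_pi, rtol=1e-12)
        np.testing.assert_allclose(conc["ch4"].values,
                                   central_params.ch4_pi, rtol=1e-12)
        np.testing.assert_allclose(conc["n2o"].values,
                                   central_params.n2o_pi, rtol=1e-12)

    def test_ch4_approaches_lifetime_balanced_steady_state(self,
                                                           central_params):
        e = 100.0   # Mt/yr held constant
        conc = run_gas_cycles(_flat_scenario(ch4=e), central_params)
        from climdamage.climate import MT_PER_PPB_CH4
        target = (central_params.ch4_pi
                  + e * central_params.ch4_lifetime / MT_PER_PPB_CH4)
        # monotone approach, and effectively at steady state long before 2300
        assert np.all(np.diff(conc["ch4"].values) >= -1e-9)
        assert conc["ch4"].values[-1] == pytest.approx(target, rel=1e-6)
        # once at steady state, concentration is constant year over year
        assert (conc["ch4"].values[-1]
                == pytest.approx(conc["ch4"].values[-2], rel=1e-9))

    def test_pulse_burden_matches_continuous_ode_oracle(self, central_params):
        """Annual stepping vs a fine-tolerance integration of the coupled
        pool/thermal ODEs with continuously-updated alpha."""
        years = np.arange(2020, 2121)
        co2 = np.zeros(len(years)); co2[0] = 1.0    # 1 GtC in 2020
        p = _ParamArrays(central_params, 1)
        res = _integrate(years, co2[None, :], np.zeros((1, len(years))),
                         np.zeros((1, len(years))), np.zeros(len(years)), p)
        burden_model = (res["co2"][0] - central_params.co2_pi) * GTC_PER_PPM

        pr = central_params
        a = np.array(pr.a); tau = np.array(pr.tau)
        g1 = float(p.g1[0]); g0 = float(p.g0[0])
        lam, gam, cu, cd = pr.lam, pr.gamma_heat, pr.c_upper, pr.c_deep

        def rhs(t, y):
            pools, cum_e, tu, td = y[:4], y[4], y[5], y[6]
            uptake = cum_e - pools.sum()
            iirf = np.clip(pr.r0 + pr.rc * uptake + pr.rt * tu, 0.0, 97.0)
            alpha = np.clip(g0 * np.exp(iirf / g1), 1e-3, 1e3)
            e = 1.0 if t < 1.0 else 0.0
            dpools = a * e - pools / (alpha * tau)
            conc = pr.co2_pi + pools.sum() / GTC_PER_PPM
            f = pr.f2x * np.log(conc / pr.co2_pi) / np.log(2.0)
            dtu = (f - lam * tu - gam * (tu - td)) / cu
            dtd = gam * (tu - td) / cd
            return [*dpools, e, dtu, dtd]

        sol = solve_ivp(rhs, (0.0, 100.0), np.zeros(7), rtol=1e-10,
                        atol=1e-12, dense_output=True, max_step=0.25)
        burden_oracle = np.array(
            [sol.sol(float(t + 1))[:4].sum() for t in range(len(years))])
        np.testing.assert_allclose(burden_model, burden_oracle, rtol=1e-3)

    def test_non_annual_grid_rejected(self, central_params):
        with pytest.raises(InvalidArgumentError):
            Trajectory(np.array([2020, 2022]), np.zeros(2))


class TestForcing:
    def test_preindustrial_concentrations_zero_forcing(self, central_params):
        years = default_years()
        conc = {g: Trajectory(years, np.full(281, v)) for g, v in
                (("co2", central_params.co2_pi),
                 ("ch4", central_params.ch4_pi),
                 ("n2o", central_params.n2o_pi))}
        f = compute_forcing(conc, central_params)
        np.testing.assert_allclose(f.values, 0.0, atol=1e-14)

    @pytest.mark.parametrize("mult,expected_f2x_units", [(2.0, 1.0), (4.0, 2.0)])
    def test_co2_doubling_definition(self, central_params, mult,
                                     expected_f2x_units):
        years = default_years()
        conc = {"co2": Trajectory(years,
                                  np.full(281, mult * central_params.co2_pi)),
                "ch4": Trajectory(years, np.full(281, central_params.ch4_pi)),
                "n2o": Trajectory(years, np.full(281, central_params.n2o_pi))}
        f = compute_forcing(conc, central_params)
        np.testing.assert_allclose(
            f.values, expected_f2x_units * central_params.f2x, rtol=1e-12)

    def test_nonpositive_co2_rejected(self, central_params):
        years = default_years()
        conc = {"co2": Trajectory(years, np.full(281, -1.0)),
                "ch4": Trajectory(years, np.full(281, central_params.ch4_pi)),
                "n2o": Trajectory(years, np.full(281, central_params.n2o_pi))}
        with pytest.raises(InvalidStateError):
            compute_forcing(conc, central_params)


class TestThermal:
    def test_zero_forcing_zero_anomaly(self, central_params):
        f = Trajectory(default_years(), np.zeros(281))
        t = run_thermal(f, central_params)
        np.testing.assert_allclose(t.values, 0.0, atol=1e-14)

    def test_constant_forcing_converges_to_f_over_lambda(self,
                                                         central_params):
        years = np.arange(2020, 2020 + 3000)
        f = Trajectory(years, np.full(3000, 3.0))
        t = run_thermal(f, central_params)
        assert t.values[-1] == pytest.approx(3.0 / central_params.lam,
                                             rel=0.01)

    def test_matches_fine_step_ode_oracle(self, central_params):
        rng = np.random.default_rng(5)
        years = np.arange(2020, 2120)
        forcing = np.cumsum(rng.normal(0.05, 0.15, 100))
        t = run_thermal(Trajectory(years, forcing), central_params)

        pr = central_params
        lam, gam, cu, cd = pr.lam, pr.gamma_heat, pr.c_upper, pr.c_deep
        sub = 400
        tu = td = 0.0
        oracle = np.empty(100)
        for i in range(100):
            for _ in range(sub):   # RK4 on the piecewise-constant system
                h = 1.0 / sub
                def deriv(tu_, td_):
                    return ((forcing[i] - lam * tu_ - gam * (tu_ - td_)) / cu,
                            gam * (tu_ - td_) / cd)
                k1 = deriv(tu, td)
                k2 = deriv(tu + h / 2 * k1[0], td + h / 2 * k1[1])
                k3 = deriv(tu + h / 2 * k2[0], td + h / 2 * k2[1])
                k4 = deriv(tu + h * k3[0], td + h * k3[1])
                tu += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                td += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            oracle[i] = tu
        peak = np.abs(oracle).max()
        assert np.max(np.abs(t.values - oracle)) < 1e-3 * peak


class TestBaselinesAndScaling:
    def test_rebaseline_subtracts_offset(self):
        t = TemperatureTrajectory(default_years(), np.full(281, 2.59))
        out = rebaseline(t, 0.69)
        np.testing.assert_allclose(out.values, 1.90, rtol=1e-12)
        assert out.baseline == "1986-2005"

    def test_rebaseline_zero_offset_is_identity_relabel(self):
        t = TemperatureTrajectory(default_years(), np.full(281, 1.0))
        out = rebaseline(t, 0.0)
        np.testing.assert_array_equal(out.values, t.values)
        assert out.baseline == "1986-2005"

    def test_rebaseline_twice_rejected(self):
        t = TemperatureTrajectory(default_years(), np.full(281, 1.0))
        once = rebaseline(t, 0.5)
        with pytest.raises(InvalidStateError):
            rebaseline(once, 0.5)

    @pytest.mark.parametrize("g,expected", [(2.0, 2.84), (0.0, 0.0),
                                            (-0.5, -0.71)])
    def test_conus_scaling(self, g, expected):
        t = TemperatureTrajectory(default_years(), np.full(281, g),
                                  baseline="1986-2005")
        out = conus_from_global(t)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        assert out.domain == "CONUS"

    def test_conus_requires_modern_baseline(self):
        t = TemperatureTrajectory(default_years(), np.full(281, 1.0))
        with pytest.raises(InvalidStateError):
            conus_from_global(t)


class TestSeaLevel:
    def test_equilibrium_temperature_gives_constant_level(self):
        cfg = EmulatorConfig(slr_t0=0.3, slr_initial_cm=5.0)
        t = TemperatureTrajectory(default_years(), np.full(281, 0.3))
        s = gmsl_from_temperature(t, cfg)
        np.testing.assert_allclose(s.values, 5.0, atol=1e-12)

    def test_linear_accumulation_one_degree_above_t0(self):
        cfg = EmulatorConfig(slr_a=0.34, slr_t0=0.0, slr_initial_cm=0.0)
        years = np.arange(2020, 2031)
        t = TemperatureTrajectory(years, np.ones(11))
        s = gmsl_from_temperature(t, cfg)
        assert s.values[-1] - s.values[0] == pytest.approx(3.4, rel=1e-12)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(9)
        cfg = EmulatorConfig(slr_a=0.34, slr_t0=-0.15, slr_initial_cm=0.0)
        years = np.arange(2020, 2121)
        temps = np.cumsum(rng.normal(0.02, 0.05, 101)) + 1.0
        s = gmsl_from_temperature(
            TemperatureTrajectory(years, temps), cfg)
        # fine-step quadrature of the rate law on the linear interpolant
        fine_t = np.linspace(0, 100, 100 * 50 + 1)
        fine_temp = np.interp(fine_t, years - 2020.0, temps)
        oracle = np.trapezoid(0.34 * (fine_temp - (-0.15)), fine_t)
        assert s.values[-1] == pytest.approx(oracle, rel=5e-3)


class TestParamSampling:
    def test_seeded_determinism(self):
        assert sample_climate_params(50, 3) == sample_climate_params(50, 3)

    def test_all_members_valid(self):
        ens = sample_climate_params(500, seed=21)
        for m in ens.members:
            m.validate()   # raises on violation

    def test_implied_ecs_median_matches_prior(self):
        priors = ClimateParamPriors()
        ens = sample_climate_params(4000, seed=5, priors=priors)
        med = np.median([m.ecs for m in ens.members])
        assert med == pytest.approx(priors.ecs_median, rel=0.05)

    def test_invalid_priors_rejected(self):
        with pytest.raises(InvalidCalibrationError):
            ClimateParamPriors(ecs_sigma=-1.0).validate()


class TestFullChain:
    def test_same_inputs_same_outputs(self, small_set, central_params):
        a = run_climate(small_set.scenario(0), central_params)
        b = run_climate(small_set.scenario(0), central_params)
        np.testing.assert_array_equal(a["conus"].values, b["conus"].values)
        np.testing.assert_array_equal(a["gmsl"].values, b["gmsl"].values)

    def test_zero_emissions_zero_exogenous_gives_zero_anomaly(
            self, central_params):
        scen = _flat_scenario()
        conc = run_gas_cycles(scen, central_params)
        cfg = EmulatorConfig(
            exogenous_forcing=Trajectory(default_years(), np.zeros(281)))
        f = compute_forcing(conc, central_params, cfg)
        t = run_thermal(f, central_params)
        np.testing.assert_allclose(t.values, 0.0, atol=1e-13)

    def test_positive_pulse_never_cools_any_later_year(self, central_params):
        scen = _flat_scenario(co2=5.0, ch4=200.0, n2o=8.0)
        co2 = scen.co2.values.copy()
        co2[10] += 2.0
        pulsed = _flat_scenario(co2=co2, ch4=200.0, n2o=8.0)
        base = run_thermal(compute_forcing(
            run_gas_cycles(scen, central_params), central_params),
            central_params)
        up = run_thermal(compute_forcing(
            run_gas_cycles(pulsed, central_params), central_params),
            central_params)
        assert np.all(up.values - base.values >= -1e-12)

    def test_small_pulse_linearity(self, central_params):
        scen = _flat_scenario(co2=5.0)
        responses = {}
        base = run_thermal(compute_forcing(
            run_gas_cycles(scen, central_params), central_params),
            central_params)
        for size in (1.0, 2.0):
            co2 = scen.co2.values.copy()
            co2[0] += size
            up = run_thermal(compute_forcing(
                run_gas_cycles(_flat_scenario(co2=co2), central_params),
                central_params), central_params)
            responses[size] = up.values - base.values
        ratio = responses[2.0][:50] / responses[1.0][:50]
        np.testing.assert_allclose(ratio, 2.0, rtol=0.01)

    def test_baseline_offset_positive_and_modest(self, central_params):
        off = compute_baseline_offset(central_params)
        assert 0.4 < off < 1.1
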