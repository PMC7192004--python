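"""TSEB-2T physics: radiation partitioning, resistances, flux closure."""

import math

import numpy as np
import pytest

from canopyflux.tseb import (
    STEFAN_BOLTZMANN, MeteoForcing, RadiationConfig, ResistanceConfig,
    aero_resistances, canopy_boundary_resistance, longwave_sources,
    net_radiation, partition_longwave, soil_heat_flux, solar_transmittance,
    solve_fluxes, _series_network, air_properties)


class TestLongwave:
    def test_identical_blackbodies(self):
        cfg = RadiationConfig(eps_c=1.0, eps_s=1.0)
        L_s, L_c, _ = longwave_sources(25.0, 25.0, 25.0, 1.4, cfg)
        assert L_s == pytest.approx(L_c)

    def test_soil_emission_value(self):
        # 310 K grey body at 0.95 emissivity
        cfg = RadiationConfig(eps_s=0.95)
        L_s, _, _ = longwave_sources(310.0 - 273.15, 20.0, 20.0, 1.4, cfg)
        assert L_s == pytest.approx(0.95 * STEFAN_BOLTZMANN * 310.0 ** 4,
                                    rel=1e-12)
        assert L_s == pytest.approx(497.1, abs=0.5)

    def test_cooler_canopy_emits_less(self):
        cfg = RadiationConfig(eps_c=0.95, eps_s=0.95)
        L_s, L_c, _ = longwave_sources(45.0, 30.0, 25.0, 1.4, cfg)
        assert L_c < L_s

    def test_nonphysical_temperature(self):
        with pytest.raises(ValueError):
            longwave_sources(-150.0, 20.0, 20.0, 1.4)


class TestLongwavePartition:
    CFG = RadiationConfig(k_L=0.95, omega=1.0)

    def test_bare_soil_limit(self):
        ln_c, ln_s = partition_longwave(0.0, self.CFG, 300.0, 450.0, 430.0)
        assert ln_c == 0.0
        assert ln_s == pytest.approx(300.0 - 450.0)

    def test_closed_canopy_limit(self):
        ln_c, ln_s = partition_longwave(60.0, self.CFG, 300.0, 450.0, 430.0)
        assert ln_c == pytest.approx(300.0 + 450.0 - 2 * 430.0, abs=1e-9)
        assert ln_s == pytest.approx(430.0 - 450.0, abs=1e-9)

    def test_worked_example_lai1(self):
        e = math.exp(-0.95)
        ln_c, ln_s = partition_longwave(1.0, self.CFG, 300.0, 450.0, 430.0)
        assert ln_c == pytest.approx((1 - e) * (300 + 450 - 2 * 430),
                                     rel=1e-12)
        assert ln_s == pytest.approx(e * 300 + (1 - e) * 430 - 450,
                                     rel=1e-12)
        assert ln_c == pytest.approx(-67.5, abs=0.1)
        assert ln_s == pytest.approx(-70.3, abs=0.1)


class TestShortwave:
    def test_no_canopy_transmits_all(self):
        assert solar_transmittance(0.0) == 1.0

    def test_monotone_decreasing_in_lai(self):
        taus = [solar_transmittance(lai) for lai in np.linspace(0, 6, 25)]
        assert all(b < a for a, b in zip(taus, taus[1:]))
        assert all(0 <= t <= 1 for t in taus)

    def test_spherical_extinction_near_half_at_nadir(self):
        # K_be(0) ~ 0.5 for the spherical distribution
        assert solar_transmittance(2.0, 1.0, 0.0) == pytest.approx(
            math.exp(-2.0 / 2.0013), rel=1e-3)

    def test_zenith_bound(self):
        with pytest.raises(ValueError):
            solar_transmittance(1.0, 1.0, 95.0)


class TestNetRadiation:
    def test_night(self):
        rn_c, rn_s, rn = net_radiation(-50.0, -30.0, 0.5, 0.0)
        assert (rn_c, rn_s) == (-50.0, -30.0)
        assert rn == rn_c + rn_s

    def test_opaque_canopy_shades_soil(self):
        rn_c, rn_s, _ = net_radiation(0.0, 0.0, 0.0, 800.0,
                                      RadiationConfig(alpha_c=0.2))
        assert rn_s == 0.0
        assert rn_c == pytest.approx(0.8 * 800.0)

    def test_worked_example(self):
        cfg = RadiationConfig(alpha_c=0.2, alpha_s=0.15)
        rn_c, rn_s, rn = net_radiation(-67.5, -70.3, 0.4, 800.0, cfg)
        assert rn_c == pytest.approx(-67.5 + 0.6 * 0.8 * 800.0)
        assert rn_c == pytest.approx(316.5, abs=0.01)
        assert rn == pytest.approx(rn_c + rn_s, abs=1e-12)


class TestSoilHeatFlux:
    def test_default_fraction(self):
        assert soil_heat_flux(200.0) == pytest.approx(60.0)

    def test_zero_fraction(self):
        assert soil_heat_flux(200.0, 0.0) == 0.0

    def test_nighttime_negative_passthrough(self):
        assert soil_heat_flux(-40.0) == pytest.approx(-12.0)


class TestResistances:
    def test_rx_value_and_scaling(self):
        r = canopy_boundary_resistance(2.0, 0.1, 1.0)
        assert r == pytest.approx(45.0 * math.sqrt(0.1), rel=1e-12)
        assert r == pytest.approx(14.23, abs=0.01)
        assert canopy_boundary_resistance(4.0, 0.1, 1.0) \
            == pytest.approx(r / 2)
        assert canopy_boundary_resistance(2.0, 0.1, 4.0) \
            == pytest.approx(r / 2)

    def test_rx_zero_lai_infinite(self):
        assert math.isinf(canopy_boundary_resistance(0.0, 0.1, 1.0))

    def test_neutral_ra_inverse_in_wind(self):
        f1 = MeteoForcing(Ta=25.0, u=2.0, S=0.0)
        f2 = MeteoForcing(Ta=25.0, u=4.0, S=0.0)
        _, ra1, _, _ = aero_resistances(f1, 2.2, math.inf, 1.5)
        _, ra2, _, _ = aero_resistances(f2, 2.2, math.inf, 1.5)
        assert ra1 == pytest.approx(2 * ra2, rel=1e-9)

    def test_neutral_matches_log_profile(self):
        f = MeteoForcing(Ta=25.0, u=2.0, S=0.0, z_u=5.0, z_T=5.0)
        h_c = 2.2
        d0, z0m = 0.65 * h_c, 0.125 * h_c
        assert (d0, z0m) == (pytest.approx(1.43), pytest.approx(0.275))
        u_star, ra, _, _ = aero_resistances(f, h_c, math.inf, 1.5)
        expect_ustar = 0.41 * 2.0 / math.log((5.0 - d0) / z0m)
        assert u_star == pytest.approx(expect_ustar, rel=1e-9)
        assert ra == pytest.approx(
            math.log((5.0 - d0) / z0m) / (0.41 * u_star), rel=1e-9)

    def test_measurement_below_canopy_rejected(self):
        f = MeteoForcing(Ta=25.0, u=2.0, S=0.0, z_u=2.0)
        with pytest.raises(ValueError):
            aero_resistances(f, 2.2, math.inf, 1.5)

    def test_air_density_reasonable(self):
        rho, cp = air_properties(25.0, 1.4, 101.3)
        assert rho == pytest.approx(1.17, abs=0.02)
        assert 1004 < cp < 1020


class TestSeriesNetwork:
    def test_hs_monotone_in_ts_at_fixed_resistances(self):
        rho_cp = 1.17 * 1010.0
        base = None
        for dt in np.linspace(0, 15, 16):
            _, _, h_s = _series_network(25.0 + dt, 27.0, 25.0,
                                        30.0, 20.0, 60.0, rho_cp)
            if base is not None:
                assert h_s >= base
            base = h_s

    def test_h_sum_consistent_with_ra(self):
        rho_cp = 1.17 * 1010.0
        t_ac, h_c, h_s = _series_network(42.0, 33.0, 30.0,
                                         30.0, 20.0, 60.0, rho_cp)
        assert h_c + h_s == pytest.approx(rho_cp * (t_ac - 30.0) / 30.0,
                                          rel=1e-9)


class TestSolveFluxes:
    F = MeteoForcing(Ta=30.0, u=2.0, S=800.0, ea=1.4, p=101.3)

    def test_no_gradient_means_no_sensible_heat(self):
        st = solve_fluxes(30.0, 30.0, 1.5, 2.2, 0.3, self.F)
        assert st.H == pytest.approx(0.0, abs=1e-9)
        assert st.LE == pytest.approx(st.Rn - st.G, abs=1e-9)
        assert st.converged

    def test_component_closure_exact(self):
        st = solve_fluxes(42.5, 33.75, 1.5, 2.2, 0.3, self.F)
        assert abs(st.Rn_s - st.G - st.H_s - st.LE_s) < 1e-6
        assert abs(st.Rn_c - st.H_c - st.LE_c) < 1e-6
        assert st.H == pytest.approx(st.H_c + st.H_s, abs=1e-9)
        assert st.LE == pytest.approx(st.LE_c + st.LE_s, abs=1e-9)
        assert st.Rn == pytest.approx(st.Rn_c + st.Rn_s, abs=1e-12)

    def test_hot_surfaces_drive_positive_h(self):
        st = solve_fluxes(42.5, 33.75, 1.5, 2.2, 0.3, self.F)
        assert st.converged and st.iterations < 100
        assert st.H > 0
        assert st.L_MO < 0  # unstable

    def test_deterministic(self):
        a = solve_fluxes(40.0, 32.0, 2.0, 2.2, 0.3, self.F)
        b = solve_fluxes(40.0, 32.0, 2.0, 2.2, 0.3, self.F)
        assert a == b

    def test_sparse_canopy_degenerates_to_soil_source(self):
        st = solve_fluxes(45.0, 30.0, 0.0, 2.2, 0.0, self.F)
        assert st.H_c == 0.0
        assert st.LE_c == pytest.approx(st.Rn_c)
        # canopy intercepts nothing at LAI = 0
        assert st.Rn_c == pytest.approx(0.0, abs=1e-9)

    def test_clamped_soil_evaporation_mode(self):
        # a strongly hot, dry soil can push LE_s negative; the clamp
        # zeroes it and rebalances H_s
        st = solve_fluxes(55.0, 31.0, 0.5, 2.2, 0.3,
                          MeteoForcing(Ta=30.0, u=0.7, S=150.0),
                          clamp_le_s=True)
        if "le_s_clamped" in st.flags:
            assert st.LE_s == 0.0
            assert st.H_s == pytest.approx(st.Rn_s - st.G, abs=1e-9)

    def test_energy_conservation_over_random_forcing(self, rng):
        unconverged = 0
        for _ in range(300):
            ta = rng.uniform(15, 40)
            ts = ta + rng.uniform(-2, 18)
            tc = ta + rng.uniform(-5, 8)
            f = MeteoForcing(Ta=ta, u=rng.uniform(0.5, 6),
                             S=rng.uniform(0, 1000),
                             ea=rng.uniform(0.5, 3.0))
            st = solve_fluxes(ts, tc, rng.uniform(0.2, 4),
                              rng.uniform(0.8, 2.5), 0.3, f)
            assert abs(st.Rn_s - st.G - st.H_s - st.LE_s) < 1e-6
            assert abs(st.Rn_c - st.H_c - st.LE_c) < 1e-6
            unconverged += not st.converged
        assert unconverged <= 3
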