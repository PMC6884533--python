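import numpy as np
import pandas as pd
import pytest
import xarray as xr

from wavecatch._time import SECONDS_PER_MONTH
from wavecatch.exceptions import DomainError, ResolutionError
from wavecatch.grid import KM_PER_DEG, TransectSpec
from wavecatch.rossby import (
    HovmollerDiagram,
    StratificationProfile,
    beta_parameter,
    build_hovmoller,
    coriolis,
    estimate_phase_speed,
    mixed_layer_depth,
    rossby_radius,
    theoretical_phase_speed,
    thermocline_depth,
)


def make_hovmoller(
    speed_cm_s,
    lat_ref=30.0,
    lags=range(0, 17),
    lons=np.arange(132.0, 168.5, 0.5),
    start_lon=160.0,
    sigma=1.5,
    amp=10.0,
    noise_sd=0.0,
    seed=0,
):
    """Analytic Hovmoller of a Gaussian translating westward at a known speed."""
    rng = np.random.default_rng(seed)
    km_per_deg = KM_PER_DEG * np.cos(np.deg2rad(lat_ref))
    deg_per_month = speed_cm_s / 100.0 * SECONDS_PER_MONTH / 1000.0 / km_per_deg
    rows = []
    lags = list(lags)
    for lag in lags:
        center = start_lon - deg_per_month * (max(lags) - lag)
        row = amp * np.exp(-((lons - center) ** 2) / (2 * sigma**2))
        if noise_sd:
            row = row + rng.normal(0, noise_sd, lons.size)
        rows.append(row)
    values = xr.DataArray(
        np.array(rows),
        coords={"lag": pd.Index(lags, name="lag"), "lon": lons},
        dims=("lag", "lon"),
    )
    spec = TransectSpec("zonal", lat_ref, (float(lons.min()), float(lons.max())))
    return HovmollerDiagram(values=values, transect=spec, n_events=1)


class TestBuildHovmoller:
    def test_stationary_anomaly_identical_rows(self):
        from wavecatch.stats_maps import detect_events

        from .conftest import make_field, winter_series

        da = make_field(n_time=72, start="2000-01", lats=(29.5, 30.0, 30.5),
                        lons=tuple(np.arange(130.0, 140.5, 0.5)))
        pattern = np.exp(-((da["lon"].values - 135.0) ** 2) / 4.0)
        da = da.copy(data=np.broadcast_to(pattern, da.shape).copy())
        ev = detect_events(winter_series([0, 0, 3.0, 0, 0, -0.1], first_winter=2000))
        spec = TransectSpec("zonal", 30.0, (130.0, 140.0))
        hov = build_hovmoller(da, ev, spec, lags=range(0, 6))
        for k in range(1, hov.values.shape[0]):
            np.testing.assert_allclose(hov.values.values[k], hov.values.values[0], atol=1e-12)

    def test_westward_packet_extremum_moves_west_toward_lag0(self, default_scenario):
        from wavecatch.anomaly import compute_anomalies
        from wavecatch.stats_maps import EventSet

        from .conftest import winter_series

        anoms = compute_anomalies(default_scenario.fields["ssh"])
        winters = default_scenario.truth["event_winters"]
        ev = EventSet(list(winters), [], 1.0, winter_series([0.0] * 3))
        spec = TransectSpec("zonal", 30.0, (132.0, 168.0))
        hov = build_hovmoller(anoms, ev, spec, lags=range(0, 11))
        peaks = {int(lag): float(hov.values.sel(lag=lag).idxmax("lon"))
                 for lag in (9, 6, 3)}
        assert peaks[9] > peaks[6] > peaks[3]

    def test_meridional_extremum_moves_north_toward_lag0(self, default_scenario):
        from wavecatch.anomaly import compute_anomalies
        from wavecatch.stats_maps import EventSet

        from .conftest import winter_series

        anoms = compute_anomalies(default_scenario.fields["ssh"])
        winters = default_scenario.truth["event_winters"]
        ev = EventSet(list(winters), [], 1.0, winter_series([0.0] * 3))
        spec = TransectSpec("meridional", 132.0, (28.0, 34.0))
        hov = build_hovmoller(anoms, ev, spec, lags=range(0, 4))
        lat2 = float(hov.values.sel(lag=2).idxmax("lat"))
        lat0 = float(hov.values.sel(lag=0).idxmax("lat"))
        assert lat0 > lat2


class TestEstimatePhaseSpeed:
    def test_noise_free_packet_within_one_percent(self):
        hov = make_hovmoller(8.0)
        est = estimate_phase_speed(hov, search=(132.0, 168.0))
        assert est.speed_cm_s == pytest.approx(8.0, rel=0.01)
        assert est.fit_r2 > 0.999

    def test_stationary_packet_speed_below_discretization(self):
        hov = make_hovmoller(0.0)
        est = estimate_phase_speed(hov, search=(132.0, 168.0))
        grid_bound = 0.5 * KM_PER_DEG * np.cos(np.deg2rad(30)) * 1000 / (16 * SECONDS_PER_MONTH)
        assert abs(est.speed_cm_s) < grid_bound * 100

    @pytest.mark.parametrize("speed", [2.0, 5.0, 10.0, 20.0])
    def test_exact_on_translating_packets(self, speed):
        hov = make_hovmoller(speed, start_lon=166.0, lons=np.arange(100.0, 168.5, 0.5))
        est = estimate_phase_speed(hov, search=(100.0, 168.0))
        assert est.speed_cm_s == pytest.approx(speed, rel=0.01)

    def test_noisy_packets_median_within_ten_percent(self):
        # row noise at the level of a 7-member composite of fields whose
        # red-noise SD is half the packet amplitude
        noise = 0.5 * 10.0 / np.sqrt(7)
        speeds = []
        for seed in range(20):
            hov = make_hovmoller(8.0, noise_sd=noise, seed=seed)
            est = estimate_phase_speed(hov, search=(132.0, 168.0))
            speeds.append(est.speed_cm_s)
        assert np.median(speeds) == pytest.approx(8.0, rel=0.10)


class TestRossbyTheory:
    def test_constant_N_closed_form(self):
        z = np.linspace(0, 4000, 81)
        N = 2.0e-3
        rho = 1025.0 * np.exp(N**2 / 9.81 * z)  # d(rho)/dz = rho0 N^2 / g approx
        # use exact linear density giving constant N^2 = g/rho0 * drho/dz
        drho_dz = 1025.0 * N**2 / 9.81
        rho = 1025.0 + drho_dz * z
        prof = StratificationProfile(depth=z, density=rho)
        Ld = rossby_radius(prof, 30.0)
        H = 4000.0
        f = coriolis(30.0)
        assert Ld == pytest.approx(N * H / (np.pi * abs(f)), rel=1e-6)
        assert Ld == pytest.approx(34.9e3, rel=0.01)

    def test_radius_linear_in_N(self):
        z = np.linspace(0, 1000, 51)
        rho1 = 1025.0 + 0.001 * z
        rho2 = 1025.0 + 0.004 * z  # 4x N^2 -> 2x N
        Ld1 = rossby_radius(StratificationProfile(depth=z, density=rho1), 30.0)
        Ld2 = rossby_radius(StratificationProfile(depth=z, density=rho2), 30.0)
        assert Ld2 == pytest.approx(2 * Ld1, rel=1e-9)

    def test_equatorial_latitude_rejected(self):
        z = np.linspace(0, 1000, 11)
        prof = StratificationProfile(depth=z, density=1025.0 + 0.001 * z)
        with pytest.raises(DomainError):
            rossby_radius(prof, 1.0)

    def test_phase_speed_at_30N_with_50km_radius(self):
        c = theoretical_phase_speed(50.0e3, 30.0)
        assert c == pytest.approx(beta_parameter(30.0) * (50.0e3) ** 2 * 100, rel=1e-12)
        assert round(c) == 5  # around 5 cm/s

    def test_zero_radius_zero_speed(self):
        assert theoretical_phase_speed(0.0, 30.0) == 0.0

    def test_speed_ratio_follows_beta(self):
        c30 = theoretical_phase_speed(50.0e3, 30.0)
        c60 = theoretical_phase_speed(50.0e3, 60.0)
        assert c60 / c30 == pytest.approx(np.cos(np.deg2rad(60)) / np.cos(np.deg2rad(30)), rel=1e-12)


class TestVerticalStructure:
    def test_two_layer_mld_at_jump(self):
        z = np.array([0.0, 40.0, 80.0, 120.0, 200.0])
        rho = np.array([1024.0, 1024.0, 1024.0, 1025.0, 1025.2])
        mld, met = mixed_layer_depth(StratificationProfile(depth=z, density=rho))
        assert met
        assert 80.0 < mld < 120.0
        # linear interpolation of the 0.125 crossing inside the jump layer
        expected = 80.0 + 0.125 / 1.0 * 40.0
        assert mld == pytest.approx(expected)

    def test_homogeneous_column_flagged(self):
        z = np.linspace(0, 500, 26)
        mld, met = mixed_layer_depth(StratificationProfile(depth=z, density=np.full(26, 1025.0)))
        assert not met and mld == 500.0

    def test_linear_ramp_closed_form(self):
        slope = 0.01  # kg m^-3 per m
        z = np.linspace(0, 100, 201)
        mld, met = mixed_layer_depth(StratificationProfile(depth=z, density=1025.0 + slope * z))
        assert met and mld == pytest.approx(0.125 / slope, rel=1e-6)

    def test_tanh_pycnocline_recovered(self):
        z = np.arange(0, 701, 10.0)
        rho = 1026.0 + 1.5 * np.tanh((z - 250.0) / 80.0)
        prof = StratificationProfile(depth=z, density=rho)
        assert thermocline_depth(prof) == pytest.approx(250.0, abs=5.0)

    def test_linear_profile_tie_breaks_shallow(self):
        z = np.arange(0, 701, 50.0)
        rho = 1024.0 + 0.01 * z  # MLD = 12.5 m; constant gradient below
        prof = StratificationProfile(depth=z, density=rho)
        mids = prof.mid_depth
        mld, _ = mixed_layer_depth(prof)
        expected = float(mids[mids > mld][0])
        assert thermocline_depth(prof) == expected

    def test_invariant_under_density_offset(self):
        z = np.arange(0, 701, 10.0)
        rho = 1026.0 + 1.5 * np.tanh((z - 230.0) / 90.0)
        d1 = thermocline_depth(StratificationProfile(depth=z, density=rho))
        d2 = thermocline_depth(StratificationProfile(depth=z, density=rho + 3.7))
        assert d1 == d2

    def test_too_few_levels_below_mld(self):
        z = np.array([0.0, 100.0, 200.0])
        rho = np.array([1024.0, 1025.0, 1026.0])
        with pytest.raises(ResolutionError):
            thermocline_depth(StratificationProfile(depth=z, density=rho))

    def test_heaved_profile_deepens_thermocline(self, default_scenario):
        cfg = default_scenario.config
        pc = cfg.profile
        z = pc.depths()
        base = StratificationProfile(depth=z, temperature=pc.mean_temperature(z))
        heaved = StratificationProfile(depth=z, temperature=pc.mean_temperature(z - 30.0))
        d0 = thermocline_depth(base)
        d1 = thermocline_depth(heaved)
        assert d1 - d0 == pytest.approx(30.0, abs=pc.depth_step)
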