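"""Synthetic scenario generator with closed-form truth for recovery tests.

Emulates the statistical structure the analysis pipeline assumes, at desk
scale: monthly gridded fields (SSH, T150, SST, SLP, wind stress) made of a
seasonal cycle, a linear trend, cell-wise AR(1) red noise, and — for SSH —
kinematic Gaussian anomaly packets that translate westward along a fixed
latitude and then northward along a coastal longitude into the index box,
arriving in December of each configured event winter.  Subsurface
temperature is slaved to SSH (thermocline heave), and winter CPUE is
linearly coupled to the box-mean T150 anomaly with a coefficient solved
from a target population correlation via the variance budget, which gives
the closed-form oracle :func:`expected_box_correlation`.

Packets are prescribed trajectories, not dynamics: the truth record carries
their exact per-lag positions so recovery tests never re-derive generator
internals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from ._time import SECONDS_PER_MONTH, anchor_period, season_periods, to_periods
from .cpue import CatchRecord
from .exceptions import ConfigError
from .grid import KM_PER_DEG, BoxSpec, box_average, monthly_axis, validate_field, write_field
from .rossby import StratificationProfile


@dataclass(frozen=True)
class GridConfig:
    """Regular lat/lon grid with a monthly axis (coarser than 1/12 for tests)."""

    lat_min: float = 26.0
    lat_max: float = 34.0
    lon_min: float = 128.0
    lon_max: float = 170.0
    spacing: float = 0.5
    start: str = "1993-01"
    months: int = 312  # 1993-2018

    def lats(self) -> np.ndarray:
        n = round((self.lat_max - self.lat_min) / self.spacing)
        if not np.isclose(self.lat_min + n * self.spacing, self.lat_max):
            raise ConfigError("grid spacing must divide the lat range")
        return self.lat_min + self.spacing * np.arange(n + 1)

    def lons(self) -> np.ndarray:
        n = round((self.lon_max - self.lon_min) / self.spacing)
        if not np.isclose(self.lon_min + n * self.spacing, self.lon_max):
            raise ConfigError("grid spacing must divide the lon range")
        return self.lon_min + self.spacing * np.arange(n + 1)

    def times(self) -> pd.DatetimeIndex:
        return monthly_axis(self.start, self.months)


@dataclass(frozen=True)
class WaveConfig:
    """Kinematics of the implanted westward-propagating SSH packets."""

    amplitude_cm: float = 12.0
    zonal_speed_cm_s: float = 10.0
    meridional_speed_cm_s: float = 5.0
    sigma_lon: float = 1.5
    sigma_lat: float = 1.5
    genesis_lon: float = 155.0
    genesis_winters: tuple[int, ...] = (1994, 1997, 2001, 2004, 2007, 2011, 2015)
    wave_lat: float = 30.0
    #: Months of e-folding decay after the December arrival.
    decay_months: float = 2.0


@dataclass(frozen=True)
class FieldBackground:
    """Seasonal amplitude, decadal trend, and AR(1) noise for one field."""

    seasonal_amp: float
    trend_per_decade: float
    noise_sd: float
    ar1: float = 0.5
    mean: float = 0.0


def _default_backgrounds() -> dict:
    return {
        "ssh": FieldBackground(seasonal_amp=6.0, trend_per_decade=1.0, noise_sd=3.0, mean=50.0),
        "t150": FieldBackground(seasonal_amp=2.0, trend_per_decade=0.2, noise_sd=0.3, mean=16.0),
        "sst": FieldBackground(seasonal_amp=6.0, trend_per_decade=0.2, noise_sd=0.5, mean=22.0),
        "slp": FieldBackground(seasonal_amp=4.0, trend_per_decade=0.0, noise_sd=2.0, mean=1015.0),
        "taux": FieldBackground(seasonal_amp=0.03, trend_per_decade=0.0, noise_sd=0.02, mean=0.05),
        "tauy": FieldBackground(seasonal_amp=0.02, trend_per_decade=0.0, noise_sd=0.02, mean=0.0),
    }


@dataclass(frozen=True)
class CouplingConfig:
    """Cross-field couplings: SSH->T150, SSH->thermocline heave, T150->CPUE."""

    gamma_degC_per_cm: float = 0.1
    alpha_m_per_cm: float = 2.0
    rho_target: float = 0.45
    #: Explicit CPUE coupling (kg per person-day per degC); overrides rho_target.
    coupling_b: float | None = None


@dataclass(frozen=True)
class CpueConfig:
    """Monthly CPUE climatology (kg per person-day) and noise level."""

    climatology: tuple[float, ...] = (60, 45, 35, 30, 25, 20, 20, 25, 30, 40, 70, 80)
    #: SD of the NDJ-mean CPUE noise, kg per person-day.
    winter_noise_sd: float = 6.0
    start: str = "2006-01"
    months: int = 156  # 2006-2018


@dataclass(frozen=True)
class EffortConfig:
    """Daily record synthesis: records per month and effort bounds."""

    records_per_month: int = 20
    effort_min: int = 1
    effort_max: int = 5
    n_regions: int = 2
    catch_dispersion: float = 0.3  # lognormal sigma of per-record weights


@dataclass(frozen=True)
class ProfileConfig:
    """Mean vertical temperature structure for the stratification profiles."""

    depth_max: float = 700.0
    depth_step: float = 10.0
    t_surface: float = 22.0
    t_deep: float = 3.0
    pycnocline_depth: float = 250.0
    pycnocline_width: float = 100.0

    def depths(self) -> np.ndarray:
        return np.arange(0.0, self.depth_max + self.depth_step / 2, self.depth_step)

    def mean_temperature(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.t_deep + (self.t_surface - self.t_deep) * 0.5 * (
            1.0 - np.tanh((z - self.pycnocline_depth) / self.pycnocline_width)
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one synthetic study scenario."""

    grid: GridConfig = dataclass_field(default_factory=GridConfig)
    wave: WaveConfig = dataclass_field(default_factory=WaveConfig)
    background: dict = dataclass_field(default_factory=_default_backgrounds)
    coupling: CouplingConfig = dataclass_field(default_factory=CouplingConfig)
    cpue: CpueConfig = dataclass_field(default_factory=CpueConfig)
    effort: EffortConfig = dataclass_field(default_factory=EffortConfig)
    profile: ProfileConfig = dataclass_field(default_factory=ProfileConfig)
    box: BoxSpec = dataclass_field(default_factory=lambda: BoxSpec(132.0, 132.5, 32.0, 32.5))
    seed: int = 0

    def validate(self) -> None:
        g = self.grid
        if not (g.lon_min <= self.wave.genesis_lon <= g.lon_max):
            raise ConfigError("packet genesis longitude outside the grid")
        if abs(self.coupling.rho_target) >= 1:
            raise ConfigError("|rho_target| must be < 1")
        if self.wave.amplitude_cm < 0:
            raise ConfigError("packet amplitude must be >= 0")
        periods = to_periods(g.times())
        for y in self.wave.genesis_winters:
            if anchor_period(y) not in set(periods):
                raise ConfigError(f"event winter {y}: December outside the time axis")

    @property
    def box_center(self) -> tuple[float, float]:
        return (
            0.5 * (self.box.lon_min + self.box.lon_max),
            0.5 * (self.box.lat_min + self.box.lat_max),
        )


# ---------------------------------------------------------------------------
# Packet kinematics (deterministic truth)


def _deg_per_month(speed_cm_s: float, km_per_deg: float) -> float:
    return speed_cm_s / 100.0 * SECONDS_PER_MONTH / 1000.0 / km_per_deg


def packet_position(config: ScenarioConfig, lag_months: float) -> tuple[float, float] | None:
    """Packet centre (lon, lat) at a fractional lag before December arrival.

    The trajectory runs westward along ``wave_lat`` from the genesis
    longitude, turns at the box longitude, and heads north to arrive at the
    box centre at lag 0.  Lags earlier than genesis return ``None``; negative
    lags (after arrival) continue northward.
    """
    w = config.wave
    lon_c, lat_c = config.box_center
    merid = _deg_per_month(w.meridional_speed_cm_s, KM_PER_DEG)
    zonal = _deg_per_month(w.zonal_speed_cm_s, KM_PER_DEG * np.cos(np.deg2rad(w.wave_lat)))
    t_turn = (lat_c - w.wave_lat) / merid if merid > 0 else 0.0
    if lag_months > genesis_lag(config) + 1.0:
        return None
    if lag_months <= t_turn:
        return (lon_c, lat_c - merid * lag_months)
    if zonal <= 0:
        return (lon_c, w.wave_lat)
    return (lon_c + zonal * (lag_months - t_turn), w.wave_lat)


def genesis_lag(config: ScenarioConfig) -> float:
    """Lag (months before December arrival) at which a packet is spawned."""
    w = config.wave
    lon_c, lat_c = config.box_center
    merid = _deg_per_month(w.meridional_speed_cm_s, KM_PER_DEG)
    zonal = _deg_per_month(w.zonal_speed_cm_s, KM_PER_DEG * np.cos(np.deg2rad(w.wave_lat)))
    t_turn = (lat_c - w.wave_lat) / merid if merid > 0 else 0.0
    if zonal <= 0:
        return t_turn
    return t_turn + (w.genesis_lon - lon_c) / zonal


def _packet_field(config: ScenarioConfig) -> np.ndarray:
    """Deterministic sum of all packet contributions, shape (time, lat, lon), cm."""
    g = config.grid
    w = config.wave
    lats = g.lats()
    lons = g.lons()
    periods = to_periods(g.times())
    out = np.zeros((len(periods), len(lats), len(lons)))
    if w.amplitude_cm == 0:
        return out
    lag_gen = genesis_lag(config)
    lon2d = lons[None, :]
    lat2d = lats[:, None]
    for y in w.genesis_winters:
        anchor = anchor_period(y)
        for it, p in enumerate(periods):
            lag = (anchor - p).n
            if lag > lag_gen + 1 or lag < -6:
                continue
            pos = packet_position(config, lag)
            if pos is None:
                continue
            amp = w.amplitude_cm
            # linear spin-up over the month after genesis, e-folding decay after arrival
            amp *= min(1.0, max(0.0, lag_gen + 1 - lag))
            if lag < 0:
                amp *= np.exp(lag / w.decay_months)
            if amp == 0:
                continue
            lonc, latc = pos
            out[it] += amp * np.exp(
                -((lon2d - lonc) ** 2) / (2 * w.sigma_lon**2)
                - ((lat2d - latc) ** 2) / (2 * w.sigma_lat**2)
            )
    return out


# ---------------------------------------------------------------------------
# Background components


def _ar1(rng: np.random.Generator, n: int, shape: tuple, sd: float, r: float) -> np.ndarray:
    """Stationary AR(1) noise along the leading (time) axis."""
    out = np.empty((n, *shape))
    if sd == 0:
        out[:] = 0.0
        return out
    out[0] = rng.normal(0.0, sd, shape)
    innov_sd = sd * np.sqrt(1.0 - r**2)
    for t in range(1, n):
        out[t] = r * out[t - 1] + rng.normal(0.0, innov_sd, shape)
    return out


def _background(
    rng: np.random.Generator, bg: FieldBackground, times: pd.DatetimeIndex, shape: tuple
) -> np.ndarray:
    months = times.month.values
    t = np.arange(len(times), dtype=float)
    seasonal = bg.seasonal_amp * np.cos(2 * np.pi * (months - 1) / 12.0)
    trend = bg.trend_per_decade * t / 120.0
    base = bg.mean + seasonal + trend
    noise = _ar1(rng, len(times), shape, bg.noise_sd, bg.ar1)
    return base[:, None, None] + noise


def _winter_mean_ar1_factor(r: float, n_months: int = 3) -> float:
    """Variance ratio var(mean of n consecutive AR(1) samples) / var(sample)."""
    total = 0.0
    for i in range(n_months):
        for j in range(n_months):
            total += r ** abs(i - j)
    return total / n_months**2


def _box_weight_factor(config: ScenarioConfig) -> float:
    """Sum(w^2)/Sum(w)^2 for the cos-lat weights of the index-box cells."""
    lats = config.grid.lats()
    lons = config.grid.lons()
    in_lat = (lats >= config.box.lat_min) & (lats <= config.box.lat_max)
    in_lon = (lons >= config.box.lon_min) & (lons <= config.box.lon_max)
    w = np.repeat(np.cos(np.deg2rad(lats[in_lat])), int(in_lon.sum()))
    if w.size == 0:
        raise ConfigError("index box contains no grid cells")
    return float(np.sum(w**2) / np.sum(w) ** 2)


# ---------------------------------------------------------------------------
# Variance budget and the CPUE coupling


def _cpue_winters(config: ScenarioConfig) -> list[int]:
    """Winters with a majority of NDJ months inside the CPUE record."""
    cp = config.cpue
    periods = to_periods(monthly_axis(cp.start, cp.months))
    pset = set(periods)
    return [
        y
        for y in range(periods[0].year - 1, periods[-1].year + 1)
        if sum(p in pset for p in season_periods(y)) > 1.5
    ]


def _packet_winter_box_means(config: ScenarioConfig) -> pd.Series:
    """Deterministic NDJ box-mean packet SSH (cm) per CPUE winter."""
    g = config.grid
    packet = _packet_field(config)
    da = xr.DataArray(
        packet,
        coords={"time": g.times(), "lat": g.lats(), "lon": g.lons()},
        dims=("time", "lat", "lon"),
    )
    series = box_average(da, config.box).to_series()
    series.index = to_periods(series.index)
    out = {}
    for y in _cpue_winters(config):
        vals = [series.get(p, np.nan) for p in season_periods(y)]
        out[y] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
    return pd.Series(out)


def _variance_budget(config: ScenarioConfig) -> dict:
    """Closed-form components of the winter box-mean T150 anomaly variance."""
    gamma = config.coupling.gamma_degC_per_cm
    p = gamma * _packet_winter_box_means(config)
    var_packet = float(p.var(ddof=1)) if p.notna().sum() > 1 else 0.0
    wfac = _box_weight_factor(config)
    bg_ssh = config.background["ssh"]
    bg_t = config.background["t150"]
    var_stoch = wfac * (
        gamma**2 * bg_ssh.noise_sd**2 * _winter_mean_ar1_factor(bg_ssh.ar1)
        + bg_t.noise_sd**2 * _winter_mean_ar1_factor(bg_t.ar1)
    )
    return {"var_packet": var_packet, "var_stoch": var_stoch, "sigma_T": np.sqrt(var_packet + var_stoch)}


def _coupling_b(config: ScenarioConfig) -> float:
    """CPUE-on-T150 slope solved from the target correlation (variance budget)."""
    if config.coupling.coupling_b is not None:
        return float(config.coupling.coupling_b)
    rho = config.coupling.rho_target
    sigma_T = _variance_budget(config)["sigma_T"]
    if sigma_T == 0:
        raise ConfigError("winter T150 variance is zero; cannot set coupling from rho_target")
    sigma_eps = config.cpue.winter_noise_sd
    if sigma_eps == 0:
        raise ConfigError("set coupling_b explicitly when CPUE noise is zero")
    return rho / np.sqrt(1.0 - rho**2) * sigma_eps / sigma_T


def expected_box_correlation(config: ScenarioConfig) -> float:
    """Closed-form population correlation between winter CPUE and box T150.

    rho = b sigma_T / sqrt(b^2 sigma_T^2 + sigma_eps^2) with sigma_T from the
    scenario's variance budget; when the coupling was solved from
    ``rho_target`` this returns ``rho_target`` exactly (tuning inversion).
    """
    b = _coupling_b(config)
    sigma_T = _variance_budget(config)["sigma_T"]
    sigma_eps = config.cpue.winter_noise_sd
    denom = b**2 * sigma_T**2 + sigma_eps**2
    if denom == 0:
        raise ConfigError("zero total CPUE variance: correlation undefined")
    return float(b * sigma_T / np.sqrt(denom))


def expected_sample_correlation(config: ScenarioConfig, n_winters: int | None = None) -> float:
    """Expected value of the n-winter sample correlation (small-sample bias).

    The sample Pearson r is biased toward zero: to first order
    E[r] = rho (1 - (1 - rho^2) / (2 (n - 1))).  Recovery tests that average
    estimated correlations over many scenario realizations should compare
    against this, not the population value.
    """
    rho = expected_box_correlation(config)
    n = n_winters if n_winters is not None else len(_cpue_winters(config))
    if n < 3:
        raise ConfigError("need >= 3 winters for a sample correlation")
    return float(rho * (1.0 - (1.0 - rho**2) / (2.0 * (n - 1))))


# ---------------------------------------------------------------------------
# Scenario output


@dataclass
class ScenarioOutput:
    """All generated inputs plus the truth record for recovery scoring."""

    fields: dict  # name -> xr.DataArray
    catch: pd.DataFrame
    records: list[CatchRecord]
    monthly_cpue_true: pd.Series
    box_t150_anom_true: pd.Series
    profiles: list[tuple[pd.Period, StratificationProfile]]
    truth: dict
    config: ScenarioConfig


_UNITS = {"ssh": "cm", "t150": "degC", "sst": "degC", "slp": "hPa", "taux": "N m-2", "tauy": "N m-2"}


def generate(config: ScenarioConfig | None = None) -> ScenarioOutput:
    """Generate a full scenario, deterministically for a given ``config.seed``."""
    config = config or ScenarioConfig()
    config.validate()
    g = config.grid
    times = g.times()
    lats, lons = g.lats(), g.lons()
    coords = {"time": times, "lat": lats, "lon": lons}
    shape = (len(lats), len(lons))
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("ssh", "t150", "sst", "slp", "taux", "tauy", "cpue", "effort"),
            np.random.SeedSequence(config.seed).spawn(8),
        )
    }

    packet = _packet_field(config)  # SSH anomaly, cm
    ssh_noise = _ar1(streams["ssh"], len(times), shape, config.background["ssh"].noise_sd,
                     config.background["ssh"].ar1)
    bg_ssh = config.background["ssh"]
    months = times.month.values
    t_idx = np.arange(len(times), dtype=float)
    ssh_base = (
        bg_ssh.mean
        + bg_ssh.seasonal_amp * np.cos(2 * np.pi * (months - 1) / 12.0)
        + bg_ssh.trend_per_decade * t_idx / 120.0
    )
    ssh_anom = packet + ssh_noise
    ssh = ssh_base[:, None, None] + ssh_anom

    gamma = config.coupling.gamma_degC_per_cm
    bg_t = config.background["t150"]
    t_noise = _ar1(streams["t150"], len(times), shape, bg_t.noise_sd, bg_t.ar1)
    t150_base = (
        bg_t.mean
        + bg_t.seasonal_amp * np.cos(2 * np.pi * (months - 1) / 12.0)
        + bg_t.trend_per_decade * t_idx / 120.0
    )
    t150_anom = gamma * ssh_anom + t_noise
    t150 = t150_base[:, None, None] + t150_anom

    fields = {}
    for name, arr in (("ssh", ssh), ("t150", t150)):
        da = xr.DataArray(arr, coords=coords, dims=("time", "lat", "lon"), name=name)
        da.attrs["units"] = _UNITS[name]
        fields[name] = validate_field(da)

    fields["sst"] = _plain_field("sst", streams, config, times, shape, coords)
    slp_patch, curl_tau = _atmospheric_anomalies(config)
    slp = _background(streams["slp"], config.background["slp"], times, shape) + slp_patch
    fields["slp"] = _as_field("slp", slp, coords)
    taux = _background(streams["taux"], config.background["taux"], times, shape) + curl_tau[0]
    tauy = _background(streams["tauy"], config.background["tauy"], times, shape) + curl_tau[1]
    fields["taux"] = _as_field("taux", taux, coords)
    fields["tauy"] = _as_field("tauy", tauy, coords)

    # True box-mean T150 anomaly series (monthly)
    t150_anom_da = xr.DataArray(t150_anom, coords=coords, dims=("time", "lat", "lon"))
    box_t = box_average(t150_anom_da, config.box).to_series()
    box_t.index = to_periods(box_t.index)

    ssh_anom_da = xr.DataArray(ssh_anom, coords=coords, dims=("time", "lat", "lon"))
    box_ssh = box_average(ssh_anom_da, config.box).to_series()
    box_ssh.index = to_periods(box_ssh.index)

    cpue_true, catch_df, records = _cpue_and_catch(config, box_t, streams)
    profiles = _monthly_profiles(config, box_ssh)

    lag_positions = {
        int(lag): packet_position(config, lag) for lag in range(0, int(np.ceil(genesis_lag(config))) + 1)
    }
    truth = {
        "event_winters": list(config.wave.genesis_winters),
        "packet_positions_by_lag": {k: v for k, v in lag_positions.items() if v is not None},
        "zonal_speed_cm_s": config.wave.zonal_speed_cm_s,
        "meridional_speed_cm_s": config.wave.meridional_speed_cm_s,
        "genesis_lag_months": genesis_lag(config),
        "expected_box_correlation": expected_box_correlation(config)
        if config.cpue.winter_noise_sd > 0 or config.coupling.coupling_b is not None
        else None,
        "coupling_b": _coupling_b(config)
        if (config.cpue.winter_noise_sd > 0 or config.coupling.coupling_b is not None)
        else None,
        "seed": config.seed,
    }
    return ScenarioOutput(
        fields=fields,
        catch=catch_df,
        records=records,
        monthly_cpue_true=cpue_true,
        box_t150_anom_true=box_t,
        profiles=profiles,
        truth=truth,
        config=config,
    )


def _as_field(name: str, arr: np.ndarray, coords) -> xr.DataArray:
    da = xr.DataArray(arr, coords=coords, dims=("time", "lat", "lon"), name=name)
    da.attrs["units"] = _UNITS[name]
    return validate_field(da)


def _plain_field(name, streams, config, times, shape, coords) -> xr.DataArray:
    arr = _background(streams[name], config.background[name], times, shape)
    return _as_field(name, arr, coords)


def _atmospheric_anomalies(config: ScenarioConfig) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """SLP highs and anticyclonic stress anomalies preceding event winters.

    A positive SLP Gaussian (and a rotational stress anomaly with negative
    curl, from a streamfunction of the same shape) sits near the genesis
    longitude during the NDJ season one year before each event winter.
    These are statistically plausible patterns for exercising the
    compositing code; no dynamical consistency is claimed.
    """
    g = config.grid
    w = config.wave
    lats, lons = g.lats(), g.lons()
    periods = to_periods(g.times())
    slp = np.zeros((len(periods), len(lats), len(lons)))
    taux = np.zeros_like(slp)
    tauy = np.zeros_like(slp)
    lon2d = lons[None, :]
    lat2d = lats[:, None]
    sig = 4.0  # degrees
    shape2d = np.exp(-((lon2d - w.genesis_lon) ** 2 + (lat2d - w.wave_lat) ** 2) / (2 * sig**2))
    # tau = k x grad(psi): psi < 0 gives clockwise (anticyclonic, NH) rotation
    deg_m = KM_PER_DEG * 1000.0
    psi_amp = -8.0e3  # N m^-1 scale such that |tau| ~ 0.05 N m^-2
    dpsi_dy = psi_amp * shape2d * (-(lat2d - w.wave_lat) / sig**2) / deg_m
    dpsi_dx = psi_amp * shape2d * (-(lon2d - w.genesis_lon) / sig**2) / (
        deg_m * np.cos(np.deg2rad(lat2d))
    )
    active = set()
    for y in w.genesis_winters:
        for p in season_periods(y, lag_months=12):
            active.add(p)
    for it, p in enumerate(periods):
        if p in active:
            slp[it] = 4.0 * shape2d  # hPa
            taux[it] = -dpsi_dy
            tauy[it] = dpsi_dx
    return slp, (taux, tauy)


def _cpue_and_catch(config: ScenarioConfig, box_t: pd.Series, streams) -> tuple:
    """Monthly CPUE coupled to the box T150 anomaly, plus daily records.

    Monthly CPUE = climatology + b * T'_box + noise, with the monthly noise
    SD scaled by sqrt(3) so the NDJ-mean noise has the configured winter SD.
    Daily catches are drawn with lognormal dispersion and rescaled so the
    pooled monthly ratio reproduces the monthly CPUE exactly.
    """
    cp = config.cpue
    ef = config.effort
    rng_c = streams["cpue"]
    rng_e = streams["effort"]
    periods = to_periods(monthly_axis(cp.start, cp.months))
    b = 0.0
    if config.coupling.coupling_b is not None or cp.winter_noise_sd > 0:
        b = _coupling_b(config)
    sigma_month = cp.winter_noise_sd * np.sqrt(3.0)
    values = {}
    for p in periods:
        clim = cp.climatology[p.month - 1]
        t_anom = float(box_t.get(p, 0.0))
        val = clim + b * t_anom + rng_c.normal(0.0, sigma_month)
        values[p] = max(val, 0.0)
    cpue_true = pd.Series(values, name="cpue")

    rows = []
    records = []
    for p in periods:
        cpue_m = cpue_true[p]
        n = ef.records_per_month
        days = rng_e.integers(1, p.days_in_month + 1, n)
        efforts = rng_e.integers(ef.effort_min, ef.effort_max + 1, n).astype(float)
        regions = rng_e.integers(0, ef.n_regions, n)
        weights = rng_e.lognormal(0.0, ef.catch_dispersion, n) * efforts
        total_catch = cpue_m * efforts.sum()
        catches = total_catch * weights / weights.sum() if weights.sum() > 0 else np.zeros(n)
        for d, e, c, r in zip(days, efforts, catches, regions):
            date = pd.Timestamp(year=p.year, month=p.month, day=int(d))
            rows.append((date, float(c), float(e), f"region_{int(r)}"))
            records.append(
                CatchRecord(date=date, catch_kg=float(c), effort_person_days=float(e),
                            region_id=f"region_{int(r)}")
            )
    catch_df = pd.DataFrame(rows, columns=["date", "catch_kg", "effort_person_days", "region_id"])
    catch_df = catch_df.sort_values(["date", "region_id"], kind="stable").reset_index(drop=True)
    return cpue_true, catch_df, records


def _monthly_profiles(config: ScenarioConfig, ssh_box_anom: pd.Series) -> list:
    """Stratification profile at the box centre per month, heaved by SSH.

    Positive SSH anomalies displace the whole mean temperature profile
    downward by alpha (m per cm of SSH), deepening the thermocline.
    """
    pc = config.profile
    alpha = config.coupling.alpha_m_per_cm
    z = pc.depths()
    out = []
    for p, ssh_cm in ssh_box_anom.items():
        heave = alpha * float(ssh_cm)
        temp = pc.mean_temperature(z - heave)
        out.append((p, StratificationProfile(depth=z, temperature=temp)))
    return out


def emit_inputs(output: ScenarioOutput, directory) -> dict:
    """Write the scenario as pipeline-readable files; returns the path map.

    One NetCDF per field, the daily catch table as CSV, per-month
    stratification profiles as long-form CSV, and the truth record as JSON.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, da in output.fields.items():
        p = directory / f"{name}.nc"
        write_field(da, p, varname=name)
        paths[name] = p
    catch_path = directory / "catch.csv"
    output.catch.assign(date=output.catch["date"].dt.strftime("%Y-%m-%d")).to_csv(
        catch_path, index=False
    )
    paths["catch"] = catch_path
    prof_rows = []
    for p, prof in output.profiles:
        for z, t, rho in zip(prof.depth, prof.temperature, prof.density):
            prof_rows.append((str(p), z, t, rho))
    prof_path = directory / "profiles.csv"
    pd.DataFrame(prof_rows, columns=["time", "depth_m", "temperature_degC", "density_kg_m3"]).to_csv(
        prof_path, index=False
    )
    paths["profiles"] = prof_path
    truth_path = directory / "truth.json"
    truth = dict(output.truth)
    truth["packet_positions_by_lag"] = {
        str(k): list(v) for k, v in truth["packet_positions_by_lag"].items()
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# Config (de)serialization for the YAML interface


def config_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["box"] = {
        "lon_min": config.box.lon_min,
        "lon_max": config.box.lon_max,
        "lat_min": config.box.lat_min,
        "lat_max": config.box.lat_max,
    }
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d or {})
    kwargs = {}
    simple = {
        "grid": GridConfig,
        "wave": WaveConfig,
        "coupling": CouplingConfig,
        "cpue": CpueConfig,
        "effort": EffortConfig,
        "profile": ProfileConfig,
    }
    for key, cls in simple.items():
        if key in d:
            sub = dict(d[key])
            for fname in ("genesis_winters", "climatology"):
                if fname in sub and isinstance(sub[fname], list):
                    sub[fname] = tuple(sub[fname])
            kwargs[key] = cls(**sub)
    if "background" in d:
        kwargs["background"] = {
            name: FieldBackground(**vals) if isinstance(vals, dict) else vals
            for name, vals in d["background"].items()
        }
    if "box" in d:
        kwargs["box"] = BoxSpec(**d["box"])
    if "seed" in d:
        kwargs["seed"] = int(d["seed"])
    return ScenarioConfig(**kwargs)
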