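"""Hovmoller diagrams, phase-speed estimation, and Rossby-wave theory.

Propagation diagnostics follow the standard recipe for long first-baroclinic
Rossby waves: an anomaly extremum is tracked across a lag-longitude (or
lag-latitude) Hovmoller section built from monthly event composites, a line
is fitted to its position in km versus lag in seconds, and the recovered
speed is compared with the long-wave theoretical limit

    c = beta * Ld**2,   beta = 2 * Omega * cos(lat) / a

where Ld is the first-mode baroclinic Rossby radius of deformation, here
computed in the WKB approximation Ld = (1 / (pi |f|)) * integral N dz.

Sign convention: phase speeds are positive westward, stated on every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
import xarray as xr

from ._time import SECONDS_PER_MONTH
from .anomaly import AnomalyField
from .exceptions import DomainError, ResolutionError, TrackingError
from .grid import KM_PER_DEG, TransectSpec, extract_transect
from .stats_maps import EventSet, lag_composite

OMEGA = 7.292e-5  # Earth's rotation rate, s^-1
EARTH_RADIUS_M = 6.371e6
GRAVITY = 9.81
RHO0 = 1025.0  # reference seawater density, kg m^-3


def coriolis(lat: float) -> float:
    """Coriolis parameter f = 2 Omega sin(lat), s^-1."""
    return 2.0 * OMEGA * np.sin(np.deg2rad(lat))


def beta_parameter(lat: float) -> float:
    """Meridional gradient of f: beta = 2 Omega cos(lat) / a, m^-1 s^-1."""
    return 2.0 * OMEGA * np.cos(np.deg2rad(lat)) / EARTH_RADIUS_M


@dataclass
class HovmollerDiagram:
    """Lag x coordinate section of composite anomalies along a transect.

    ``values`` has dims (lag, lat-or-lon); lags count months before the
    anchor December (lag 0) and decrease toward it.
    """

    values: xr.DataArray
    transect: TransectSpec
    n_events: int
    sig_mask: xr.DataArray | None = None

    @property
    def lags(self) -> np.ndarray:
        return self.values["lag"].values

    @property
    def coord(self) -> np.ndarray:
        return self.values[self.transect.free_dim].values


@dataclass
class PhaseSpeedEstimate:
    """Tracked-extremum phase speed from a Hovmoller diagram.

    ``speed_cm_s`` is positive for westward (zonal) or southward-to-northward
    ... strictly: positive means propagation toward decreasing coordinate for
    zonal transects (westward) and toward increasing coordinate for
    meridional ones (northward), matching the trajectories being diagnosed.
    """

    speed_cm_s: float
    tracked_positions: pd.Series  # degree position per lag
    fit_r2: float
    lat_ref: float
    direction: str = "westward"

    def to_dict(self) -> dict:
        return {
            "speed_cm_s": self.speed_cm_s,
            "direction": self.direction,
            "fit_r2": self.fit_r2,
            "lat_ref": self.lat_ref,
            "tracked_positions": {int(k): float(v) for k, v in self.tracked_positions.items()},
        }


def build_hovmoller(
    anoms: AnomalyField | xr.DataArray,
    events: EventSet,
    spec: TransectSpec,
    lags=range(0, 17),
    sign: str = "positive",
    level: float = 0.90,
) -> HovmollerDiagram:
    """Monthly-composite anomalies along a transect, one row per lag.

    Each row is the monthly lag composite over the event winters (anchored at
    December), reduced onto the transect by nearest-grid-line selection; the
    composite significance mask is carried alongside.
    """
    rows, sig_rows, kept = [], [], []
    n_events = 0
    for lag in lags:
        comp = lag_composite(anoms, events, sign=sign, lag_months=lag, window="monthly", level=level)
        rows.append(extract_transect(comp.mean_anomaly, spec))
        sig_rows.append(
            extract_transect(comp.sig_mask, spec) if comp.sig_mask is not None else None
        )
        kept.append(lag)
        n_events = max(n_events, comp.n_events)
    lag_idx = pd.Index(kept, name="lag")
    values = xr.concat(rows, dim=lag_idx)
    values.name = "hovmoller"
    sig = None
    if all(s is not None for s in sig_rows):
        sig = xr.concat(sig_rows, dim=lag_idx)
    return HovmollerDiagram(values=values, transect=spec, n_events=n_events, sig_mask=sig)


def _parabolic_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid extremum position from a 3-point parabola around index i."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dx = 0.5 * (x[i + 1] - x[i - 1])
    return float(x[i] + delta * dx)


def estimate_phase_speed(
    hov: HovmollerDiagram,
    search: tuple[float, float] | None = None,
    min_lags: int = 5,
    track_halfwidth: float = 9.0,
    noise_floor: float | None = None,
    max_gaps: int = 2,
    smooth_sigma_deg: float = 1.0,
) -> PhaseSpeedEstimate:
    """Extremum-tracking phase speed with a continuity-constrained search.

    Rows are lightly smoothed along the coordinate (Gaussian,
    ``smooth_sigma_deg``; symmetric, so it does not displace a packet's
    extremum) before the anomaly maximum is located (with sub-grid parabolic
    refinement) inside ``search``; at each subsequent lag
    the search window is re-centred on the previous position with half-width
    ``track_halfwidth`` degrees (the default accommodates speeds up to
    ~20 cm/s at subtropical latitudes, with margin for the edge-rejection
    rule below).  Positions below ``noise_floor`` (default:
    25% of the diagram's peak amplitude) are treated as track gaps; more than
    ``max_gaps`` consecutive gaps aborts the estimate.  Positions are
    converted to km (111.32 cos(lat_ref) km per degree longitude on zonal
    transects) and regressed on lag time; the returned speed is positive in
    the direction of propagation toward the transect's destination end
    (westward for zonal sections).
    """
    vals = hov.values
    coord_name = hov.transect.free_dim
    coords = vals[coord_name].values.astype(float)
    lags = np.asarray(vals["lag"].values, dtype=int)
    arr = vals.values
    if smooth_sigma_deg > 0 and coords.size > 2:
        from scipy.ndimage import gaussian_filter1d

        step = float(np.median(np.diff(coords)))
        arr = np.where(np.isfinite(arr), arr, 0.0)
        arr = gaussian_filter1d(arr, sigma=smooth_sigma_deg / step, axis=1, mode="nearest")
    if noise_floor is None:
        noise_floor = 0.25 * float(np.nanmax(np.abs(arr)))

    def peak_in(row, lo, hi):
        mask = (coords >= lo) & (coords <= hi) & np.isfinite(row)
        if not mask.any():
            return None
        idx = np.nonzero(mask)[0]
        i = int(np.argmax(np.where(mask, row, -np.inf)))
        if row[i] < noise_floor:
            return None
        # a maximum pinned to the window boundary is not a resolved extremum
        # (the true peak lies at or beyond the edge); treat it as a gap
        if i == idx[0] or i == idx[-1]:
            return None
        return i

    # Anchor the track at the diagram's strongest extremum inside the search
    # window, then walk outward in both lag directions with a continuity-
    # constrained window; a false peak at a signal-free lag cannot then
    # derail the whole track.
    lo0, hi0 = search if search is not None else (coords.min(), coords.max())
    order = np.argsort(lags)
    anchor_k, anchor_val = None, -np.inf
    for k in order:
        i = peak_in(arr[k], lo0, hi0)
        if i is not None and arr[k][i] > anchor_val:
            anchor_k, anchor_val = k, arr[k][i]
    if anchor_k is None:
        raise TrackingError("no extremum above the noise floor inside the search window")

    positions: dict[int, float] = {}
    i0 = peak_in(arr[anchor_k], lo0, hi0)
    positions[int(lags[anchor_k])] = _parabolic_peak(coords, arr[anchor_k], i0)
    pos_in_order = int(np.nonzero(order == anchor_k)[0][0])
    for direction in (1, -1):
        prev_pos = positions[int(lags[anchor_k])]
        gaps = 0
        j = pos_in_order + direction
        while 0 <= j < len(order):
            k = order[j]
            lo = max(prev_pos - track_halfwidth, lo0)
            hi = min(prev_pos + track_halfwidth, hi0)
            i = peak_in(arr[k], lo, hi)
            if i is None:
                gaps += 1
                if gaps > max_gaps:
                    break
            else:
                gaps = 0
                pos = _parabolic_peak(coords, arr[k], i)
                positions[int(lags[k])] = pos
                prev_pos = pos
            j += direction
    if len(positions) < min_lags:
        raise TrackingError(
            f"extremum tracked at only {len(positions)} lags (need {min_lags}); "
            f"positions: {positions}"
        )
    track = pd.Series(positions).sort_index()
    if hov.transect.axis == "zonal":
        lat_ref = float(hov.transect.fixed_coord)
        km_per_deg = KM_PER_DEG * np.cos(np.deg2rad(lat_ref))
        direction = "westward"
        sign = -1.0  # westward = decreasing longitude
    else:
        lat_ref = float(np.mean(track.values))
        km_per_deg = KM_PER_DEG
        direction = "northward"
        sign = 1.0
    t_s = -track.index.values.astype(float) * SECONDS_PER_MONTH
    x_m = track.values * km_per_deg * 1000.0
    slope, intercept = np.polyfit(t_s, x_m, 1)
    resid = x_m - (slope * t_s + intercept)
    ss_tot = np.sum((x_m - x_m.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else np.nan
    speed = sign * slope * 100.0  # m/s -> cm/s, signed toward propagation direction
    return PhaseSpeedEstimate(
        speed_cm_s=float(speed),
        tracked_positions=track,
        fit_r2=r2,
        lat_ref=lat_ref,
        direction=direction,
    )


@dataclass
class StratificationProfile:
    """A vertical T/density profile with derived buoyancy frequency.

    ``depth`` is metres positive-down and strictly increasing.  If density is
    not supplied it is derived from temperature through a linear equation of
    state rho = RHO0 (1 - alpha_T (T - 10)).  N is defined on layer midpoints
    from the density gradient; statically unstable layers clip N^2 to zero.
    """

    depth: np.ndarray
    temperature: np.ndarray | None = None
    density: np.ndarray | None = None
    alpha_T: float = 2.0e-4

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or len(self.depth) < 2:
            raise ResolutionError("profile needs >= 2 depth levels")
        if not np.all(np.diff(self.depth) > 0):
            raise DomainError("depth must be strictly increasing, positive down")
        if self.density is None:
            if self.temperature is None:
                raise ValueError("supply temperature or density")
            self.density = RHO0 * (1.0 - self.alpha_T * (np.asarray(self.temperature) - 10.0))
        self.density = np.asarray(self.density, dtype=float)

    @property
    def mid_depth(self) -> np.ndarray:
        return 0.5 * (self.depth[1:] + self.depth[:-1])

    def density_gradient(self) -> np.ndarray:
        """d(rho)/dz on layer midpoints (kg m^-4), positive for stable columns."""
        return np.diff(self.density) / np.diff(self.depth)

    def buoyancy_frequency(self) -> np.ndarray:
        """N on layer midpoints (s^-1); N^2 < 0 clipped to zero with a warning."""
        n2 = (GRAVITY / RHO0) * self.density_gradient()
        if np.any(n2 < 0):
            import warnings

            warnings.warn("statically unstable layers: clipping N^2 to 0", stacklevel=2)
            n2 = np.clip(n2, 0.0, None)
        return np.sqrt(n2)


def rossby_radius(profile: StratificationProfile, lat: float) -> float:
    """WKB first-baroclinic Rossby radius Ld = (1 / (pi |f|)) * integral N dz (m)."""
    if abs(lat) <= 2.0:
        raise DomainError(f"latitude {lat} too close to the equator for f-plane radius")
    n = profile.buoyancy_frequency()
    dz = np.diff(profile.depth)
    integral = float(np.sum(n * dz))  # N is piecewise constant on layers
    return integral / (np.pi * abs(coriolis(lat)))


def theoretical_phase_speed(Ld_m: float, lat: float) -> float:
    """Long-wave first-baroclinic Rossby phase speed c = beta Ld^2, cm/s westward."""
    if Ld_m < 0:
        raise ValueError("deformation radius must be non-negative")
    return beta_parameter(lat) * Ld_m**2 * 100.0


def mixed_layer_depth(profile: StratificationProfile, delta_rho: float = 0.125) -> tuple[float, bool]:
    """Depth where density first exceeds the surface value by ``delta_rho``.

    Linear interpolation between levels.  Returns (depth_m, criterion_met);
    a column never meeting the criterion reports the full depth with
    ``criterion_met=False``.
    """
    rho = profile.density
    target = rho[0] + delta_rho
    above = rho > target
    if not above.any():
        return float(profile.depth[-1]), False
    j = int(np.argmax(above))
    if j == 0:
        return float(profile.depth[0]), True
    z0, z1 = profile.depth[j - 1], profile.depth[j]
    r0, r1 = rho[j - 1], rho[j]
    frac = (target - r0) / (r1 - r0)
    return float(z0 + frac * (z1 - z0)), True


def thermocline_depth(profile: StratificationProfile) -> float:
    """Depth of maximum d(rho)/dz below the mixed layer.

    The gradient lives on layer midpoints; ties break to the shallowest
    qualifying depth.  Raises :class:`ResolutionError` when fewer than three
    midpoints lie below the mixed layer.
    """
    mld, _ = mixed_layer_depth(profile)
    grad = profile.density_gradient()
    mids = profile.mid_depth
    below = mids > mld
    if below.sum() < 3:
        raise ResolutionError(
            f"only {int(below.sum())} density-gradient levels below the mixed layer ({mld:.0f} m)"
        )
    g = np.where(below, grad, -np.inf)
    return float(mids[int(np.argmax(g))])  # argmax returns the first (shallowest) max
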