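"""Monthly anomalies of gridded fields: climatology removal and linear detrending.

An anomaly is what remains of a cell's monthly series after subtracting its
monthly climatology and a single least-squares linear trend.  Both are
removed in one joint least-squares fit (regression on the twelve
calendar-month indicators plus linear time) rather than sequentially:
removing the climatology first aliases part of any trend into a sawtooth
that a subsequent single line cannot absorb, whereas the joint projection
is idempotent, linear, and reconstructs the input exactly from
climatology + trend + anomaly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from ._time import NDJ, check_monthly, season_periods, winter_labels
from .exceptions import AxisError

#: Minimum unmasked samples per cell for the joint climatology+trend fit;
#: below this the cell falls back to plain per-month centring and is flagged.
MIN_DETREND_SAMPLES = 14


@dataclass
class ClimatologyField:
    """Per-cell monthly means over years, with per-month sample counts."""

    mean: xr.DataArray  # dims (month, [depth,] lat, lon)
    count: xr.DataArray


@dataclass
class AnomalyField:
    """Deseasonalized, detrended field with the provenance to invert it.

    ``slope`` has units of the field per month; ``trend_flagged`` marks cells
    with too few samples for a trend fit (their anomalies are deseasonalized
    only).
    """

    anom: xr.DataArray
    climatology: ClimatologyField
    slope: xr.DataArray
    intercept: xr.DataArray
    trend_flagged: xr.DataArray

    def reconstruct(self) -> xr.DataArray:
        """Rebuild the original field from anomaly + climatology + trend."""
        months = self.anom["time"].dt.month
        clim = self.climatology.mean.sel(month=months).drop_vars("month")
        t = xr.DataArray(
            np.arange(self.anom.sizes["time"], dtype=float),
            dims="time",
            coords={"time": self.anom["time"]},
        )
        return self.anom + clim + self.slope * t + self.intercept


def monthly_climatology(field: xr.DataArray) -> ClimatologyField:
    """Per-cell, per-calendar-month mean over all years, ignoring missing cells."""
    check_monthly(field["time"].values)
    grouped = field.groupby("time.month")
    return ClimatologyField(mean=grouped.mean("time"), count=grouped.count("time"))


def compute_anomalies(field: xr.DataArray) -> AnomalyField:
    """Remove monthly climatology and linear trend in one least-squares fit.

    Per cell, the series is projected off the span of the 12 calendar-month
    indicator functions plus linear time (masked-aware); the residual is the
    anomaly.  Cells with fewer than :data:`MIN_DETREND_SAMPLES` unmasked
    months fall back to plain per-month centring and are flagged.
    """
    periods = check_monthly(field["time"].values)
    n_time = len(periods)
    if n_time < 24:
        raise AxisError("anomaly computation needs at least two years of monthly data")
    months = field["time"].dt.month.values
    t = np.arange(n_time, dtype=float)
    X = np.zeros((n_time, 13))
    X[np.arange(n_time), months - 1] = 1.0
    X[:, 12] = t

    spatial_shape = field.shape[1:]
    Y = field.values.reshape(n_time, -1)
    finite = np.isfinite(Y)
    counts = finite.sum(axis=0)
    resid = np.full_like(Y, np.nan)
    coefs = np.zeros((13, Y.shape[1]))

    fallback = counts < MIN_DETREND_SAMPLES
    complete = finite.all(axis=0) & ~fallback
    if complete.any():
        beta = np.linalg.pinv(X) @ Y[:, complete]
        resid[:, complete] = Y[:, complete] - X @ beta
        coefs[:, complete] = beta
    for j in np.nonzero(~complete & ~fallback)[0]:
        m = finite[:, j]
        beta, *_ = np.linalg.lstsq(X[m], Y[m, j], rcond=None)
        coefs[:, j] = beta
        resid[m, j] = Y[m, j] - X[m] @ beta
    for j in np.nonzero(fallback)[0]:
        m = finite[:, j]
        cj = np.zeros(12)
        for mo in range(12):
            sel = m & (months == mo + 1)
            cj[mo] = Y[sel, j].mean() if sel.any() else 0.0
        coefs[:12, j] = cj
        resid[m, j] = Y[m, j] - cj[months[m] - 1]

    clim_counts = monthly_climatology(field).count
    clim_mean = xr.DataArray(
        coefs[:12].reshape((12,) + spatial_shape),
        coords={"month": np.arange(1, 13), **{d: field[d] for d in field.dims[1:]}},
        dims=("month",) + field.dims[1:],
    )
    slope = xr.DataArray(
        coefs[12].reshape(spatial_shape),
        coords={d: field[d] for d in field.dims[1:]},
        dims=field.dims[1:],
    )
    intercept = xr.zeros_like(slope)  # absorbed into the month constants
    anom = field.copy(data=resid.reshape(field.shape))
    anom.attrs.update(field.attrs)
    anom.name = f"{field.name or 'field'}_anom"
    return AnomalyField(
        anom=anom,
        climatology=ClimatologyField(mean=clim_mean, count=clim_counts),
        slope=slope,
        intercept=intercept,
        trend_flagged=xr.DataArray(
            fallback.reshape(spatial_shape),
            coords={d: field[d] for d in field.dims[1:]},
            dims=field.dims[1:],
        ),
    )


def seasonal_mean_field(
    anoms: AnomalyField | xr.DataArray,
    season=NDJ,
    lag_months: int = 0,
) -> xr.DataArray:
    """Per-winter seasonal-mean anomaly fields at a (backward) monthly lag.

    The season window for each winter is resolved on the calendar: the NDJ
    window of winter ``y`` at lag 3 is Aug-Oct of year ``y``, and at lag 12
    the previous winter's NDJ.  Winters whose lagged window is mostly or
    entirely outside the record are omitted; windows missing a minority of
    months average the available ones (flagged via the ``complete``
    coordinate).  The result gains a ``winter`` dimension.
    """
    da = anoms.anom if isinstance(anoms, AnomalyField) else anoms
    periods = check_monthly(da["time"].values)
    lookup = {p: i for i, p in enumerate(periods)}
    fields, labels, complete = [], [], []
    for y in winter_labels(periods, season):
        window = season_periods(y, season, lag_months)
        idx = [lookup[p] for p in window if p in lookup]
        if len(idx) <= len(window) / 2:
            continue
        fields.append(da.isel(time=idx).mean("time", skipna=True))
        labels.append(y)
        complete.append(len(idx) == len(window))
    out = xr.concat(fields, dim=pd.Index(labels, name="winter"))
    out = out.assign_coords(complete=("winter", np.asarray(complete)))
    out.attrs.update(da.attrs)
    return out
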