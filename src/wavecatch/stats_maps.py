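"""Correlation maps, threshold-event detection, and lagged composites.

The correlation between the winter CPUE series x' and a gridded anomaly y'
is the uncentred Pearson form

    R = sum(x'_i y'_i) / (sqrt(sum x'_i^2) sqrt(sum y'_i^2))

applied to series that are already detrended anomalies (so their means are
zero by construction and no further centring is applied).  With n winters
the fit has df = n - 2 degrees of freedom, and significance is assessed by
a two-sided Student t-test of t = R sqrt(df / (1 - R^2)).

Composites average member anomaly fields over event winters; their
significance is a one-sample two-sided t-test of the member mean against
zero with df = n_events - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from ._time import anchor_period, check_monthly
from .anomaly import AnomalyField, seasonal_mean_field
from .cpue import SeasonalSeries
from .exceptions import ValidationError

#: Minimum overlapping winters for a per-cell correlation.
MIN_OVERLAP = 3


def detrend_series(series: SeasonalSeries) -> SeasonalSeries:
    """Remove the least-squares line (in winter label) from a seasonal series.

    Mirrors, at seasonal resolution, the anomaly construction applied to the
    gridded fields; the result has zero mean and zero linear trend.
    """
    y = series.value.values.astype(float)
    t = series.value.index.values.astype(float)
    ok = np.isfinite(y)
    coef = np.polyfit(t[ok], y[ok], 1)
    resid = y - np.polyval(coef, t)
    return SeasonalSeries(
        value=pd.Series(resid, index=series.value.index, name=series.value.name),
        complete=series.complete.copy(),
        season=series.season,
    )


@dataclass
class CorrelationMap:
    """Per-cell correlation with sample size, df, and a significance mask."""

    r: xr.DataArray
    n: xr.DataArray
    df: xr.DataArray
    sig_mask: xr.DataArray | None = None
    level: float | None = None


def pearson_map(cpue: SeasonalSeries, field_winters: xr.DataArray) -> CorrelationMap:
    """Correlate a winter series with per-winter anomaly fields, cell by cell.

    Only winters present in both inputs contribute; cells with fewer than
    three finite overlaps are masked.  Both inputs are expected to be
    detrended anomalies already (see :func:`detrend_series`).
    """
    common = cpue.value.index.intersection(field_winters["winter"].values)
    if len(common) < MIN_OVERLAP:
        raise ValidationError(f"only {len(common)} overlapping winters, need >= {MIN_OVERLAP}")
    x = xr.DataArray(
        cpue.value.loc[common].values, dims="winter", coords={"winter": common.values}
    )
    y = field_winters.sel(winter=common.values)
    ok = np.isfinite(y) & np.isfinite(x)
    n = ok.sum("winter")
    xm = x.where(ok)
    ym = y.where(ok)
    sxy = (xm * ym).sum("winter")
    sxx = (xm**2).sum("winter")
    syy = (ym**2).sum("winter")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    r = r.where((n >= MIN_OVERLAP) & (sxx > 0) & (syy > 0))
    r = r.clip(-1.0, 1.0)
    r.name = "r"
    return CorrelationMap(r=r, n=n, df=(n - 2).where(np.isfinite(r)))


def t_significance(cmap: CorrelationMap, level: float = 0.90) -> CorrelationMap:
    """Two-sided Student-t significance mask at the given confidence level.

    |R| = 1 is significant by convention (the t statistic diverges).  The map
    is updated in place and returned.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    r = cmap.r.values
    df = cmap.df.values
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    sig = np.isfinite(r) & (df >= 1) & (p < 1.0 - level)
    cmap.sig_mask = xr.DataArray(sig, coords=cmap.r.coords, dims=cmap.r.dims, name="sig")
    cmap.level = level
    return cmap


@dataclass
class EventSet:
    """Winters whose index anomaly exceeds +/- threshold_sd sample SDs."""

    positive_winters: list[int]
    negative_winters: list[int]
    threshold_sd: float
    index_series: SeasonalSeries
    sd: float = dataclass_field(default=np.nan)

    def winters(self, sign: str) -> list[int]:
        if sign not in ("positive", "negative"):
            raise ValueError(f"sign must be positive or negative, got {sign!r}")
        return self.positive_winters if sign == "positive" else self.negative_winters


def detect_events(index: SeasonalSeries, threshold_sd: float = 1.0) -> EventSet:
    """Classify winters exceeding the +/- threshold on the index's own SD.

    The threshold is ``threshold_sd`` times the sample SD (ddof 1) of the
    full index series; exceedance is strict.  The index is expected to be an
    anomaly series (zero mean).
    """
    vals = index.value.dropna()
    if len(vals) < 3:
        raise ValidationError(f"need >= 3 winters to define events, got {len(vals)}")
    sd = float(vals.std(ddof=1))
    if sd == 0:
        warnings.warn("zero-variance index: no events detectable", stacklevel=2)
        return EventSet([], [], threshold_sd, index, sd=0.0)
    pos = vals.index[vals > threshold_sd * sd].tolist()
    neg = vals.index[vals < -threshold_sd * sd].tolist()
    return EventSet(pos, neg, threshold_sd, index, sd=sd)


def events_to_csv(events: EventSet, path) -> None:
    """Write the event list as CSV (winter, index value, sign)."""
    rows = [(w, float(events.index_series.value[w]), "positive") for w in events.positive_winters]
    rows += [(w, float(events.index_series.value[w]), "negative") for w in events.negative_winters]
    pd.DataFrame(rows, columns=["winter", "index_value", "sign"]).sort_values("winter").to_csv(
        path, index=False
    )


@dataclass
class CompositeResult:
    """Mean anomaly over event members with one-sample t significance."""

    mean_anomaly: xr.DataArray
    n_events: int
    t_stat: xr.DataArray | None
    sig_mask: xr.DataArray | None
    lag: int
    level: float | None = None
    members: list[int] = dataclass_field(default_factory=list)


def lag_composite(
    anoms: AnomalyField | xr.DataArray,
    events: EventSet,
    sign: str = "positive",
    lag_months: int = 0,
    window: str = "seasonal",
    level: float = 0.90,
    season=None,
) -> CompositeResult:
    """Composite anomaly fields over event winters at a backward lag.

    ``window='seasonal'`` averages the 3-month season shifted back by
    ``lag_months``; ``window='monthly'`` takes the single month anchored at
    December of the event winter.  Events whose lagged window falls entirely
    outside the record are dropped (n_events adjusts).  Significance is a
    two-sided one-sample t-test against zero with df = n_events - 1; with a
    single member the composite is that member's field and t is undefined.
    """
    da = anoms.anom if isinstance(anoms, AnomalyField) else anoms
    members_all = events.winters(sign)
    if len(members_all) < 1:
        raise ValidationError(f"no {sign} events to composite")
    if window == "monthly":
        periods = check_monthly(da["time"].values)
        lookup = {p: i for i, p in enumerate(periods)}
        fields, used = [], []
        for y in members_all:
            p = anchor_period(y, lag_months)
            if p in lookup:
                fields.append(da.isel(time=lookup[p]))
                used.append(y)
        if not fields:
            raise ValidationError(f"no {sign} event has data at lag {lag_months}")
        stack = xr.concat(fields, dim=pd.Index(used, name="winter"))
    elif window == "seasonal":
        from ._time import NDJ

        per_winter = seasonal_mean_field(da, season or NDJ, lag_months)
        avail = [y for y in members_all if y in per_winter["winter"].values]
        if not avail:
            raise ValidationError(f"no {sign} event has data at lag {lag_months}")
        stack = per_winter.sel(winter=avail)
        used = avail
    else:
        raise ValueError(f"window must be 'seasonal' or 'monthly', got {window!r}")

    mean = stack.mean("winter", skipna=True)
    n = len(used)
    if n >= 2:
        sd = stack.std("winter", ddof=1, skipna=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t.values), n - 1)
        sig = xr.DataArray(
            np.isfinite(t.values) & (p < 1.0 - level),
            coords=mean.coords,
            dims=mean.dims,
            name="sig",
        )
    else:
        t, sig = None, None
    return CompositeResult(
        mean_anomaly=mean,
        n_events=n,
        t_stat=t,
        sig_mask=sig,
        lag=lag_months,
        level=level if n >= 2 else None,
        members=list(used),
    )
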