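"""Daily catch records to monthly CPUE, climatology, and seasonal means.

CPUE (catch per unit effort) is the month's total catch mass divided by the
month's total fishing effort in person-days — a pooled ratio, not a mean of
daily ratios, so low-effort days do not dominate.  Months with no records
are missing, never zero: a zero catch is an observation, an absent month is
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._time import NDJ, season_months, season_periods, winter_labels
from .exceptions import ValidationError


@dataclass(frozen=True)
class CatchRecord:
    """One day's catch for one reporting region."""

    date: pd.Timestamp
    catch_kg: float
    effort_person_days: float
    region_id: str | None = None

    def __post_init__(self):
        if not self.effort_person_days > 0:
            raise ValidationError(f"effort must be strictly positive, got {self.effort_person_days}")
        if self.catch_kg < 0:
            raise ValidationError(f"catch mass must be non-negative, got {self.catch_kg}")


@dataclass
class CPUESeries:
    """Monthly CPUE (kg per person-day) with per-month record counts.

    ``value`` is indexed by a monthly :class:`pandas.PeriodIndex`; months with
    ``n_records == 0`` hold NaN.
    """

    value: pd.Series
    n_records: pd.Series

    def __post_init__(self):
        neg = self.value.dropna() < 0
        if neg.any():
            raise ValidationError("CPUE values must be non-negative where defined")

    @property
    def time(self) -> pd.PeriodIndex:
        return self.value.index


@dataclass
class SeasonalSeries:
    """Per-winter seasonal means, labelled by the year opening the season.

    ``complete`` flags winters whose every constituent month was present;
    partial winters keep the mean of their available months.
    """

    value: pd.Series
    complete: pd.Series = field(default=None)  # type: ignore[assignment]
    season: tuple[int, ...] = NDJ

    def __post_init__(self):
        if self.complete is None:
            self.complete = pd.Series(True, index=self.value.index)

    @property
    def winters(self) -> pd.Index:
        return self.value.index


DEFAULT_COLUMNS = {"date": "date", "catch": "catch_kg", "effort": "effort_person_days"}


def read_catch_csv(path, columns: dict | None = None) -> list[CatchRecord]:
    """Read daily catch records from delimited text, validating each row.

    ``columns`` maps the logical names ``date``, ``catch``, ``effort`` (and
    optionally ``region``) to the file's header names.  Malformed rows raise
    :class:`ValidationError` citing the 1-based data line number.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    df = pd.read_csv(path)
    for key in ("date", "catch", "effort"):
        if cols[key] not in df.columns:
            raise ValidationError(f"{path}: missing column {cols[key]!r} (header: {list(df.columns)})")
    records = []
    region_col = cols.get("region")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        try:
            date = pd.Timestamp(raw[cols["date"]])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: line {i}: unparseable date {raw[cols['date']]!r}") from exc
        try:
            records.append(
                CatchRecord(
                    date=date,
                    catch_kg=float(raw[cols["catch"]]),
                    effort_person_days=float(raw[cols["effort"]]),
                    region_id=str(raw[region_col]) if region_col and region_col in df.columns else None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return records


def monthly_cpue(records: list[CatchRecord]) -> CPUESeries:
    """Pool records into monthly CPUE = sum(catch) / sum(effort).

    Records from different regions pool into a single numerator and
    denominator.  The monthly axis runs contiguously from the first to the
    last record's month; intervening months with no records are missing.
    """
    if not records:
        raise ValidationError("need at least one catch record")
    df = pd.DataFrame(
        {
            "period": [r.date.to_period("M") for r in records],
            "catch": [r.catch_kg for r in records],
            "effort": [r.effort_person_days for r in records],
        }
    )
    grouped = df.groupby("period").sum()
    full = pd.period_range(grouped.index.min(), grouped.index.max(), freq="M")
    catch = grouped["catch"].reindex(full)
    effort = grouped["effort"].reindex(full)
    n = df.groupby("period").size().reindex(full, fill_value=0)
    value = catch / effort
    return CPUESeries(value=value.rename("cpue"), n_records=n.rename("n_records"))


def monthly_climatology_sd(series: CPUESeries) -> tuple[pd.Series, pd.Series]:
    """Per-calendar-month mean and sample SD (ddof 1) across years.

    Missing months are skipped.  A calendar month observed fewer than twice
    has an undefined (NaN) SD.
    """
    months = series.value.index.month
    mean = series.value.groupby(months).mean()
    sd = series.value.groupby(months).std(ddof=1)
    counts = series.value.groupby(months).count()
    sd[counts < 2] = np.nan
    idx = pd.RangeIndex(1, 13, name="month")
    return mean.reindex(idx), sd.reindex(idx)


def seasonal_mean(series: CPUESeries, season=NDJ) -> SeasonalSeries:
    """Per-winter mean of the season's monthly CPUE values.

    The NDJ season spanning Nov(y)-Jan(y+1) is labelled ``y``; a season that
    does not cross the year boundary is labelled by its own calendar year.
    Winters missing a majority of the season's months are dropped (the edge
    winters of a record contribute only when most of their season is
    observed); winters missing a minority keep the mean of the available
    months and are flagged incomplete.
    """
    season = season_months(season)
    labels = winter_labels(series.value.index, season)
    values, complete = {}, {}
    for y in labels:
        periods = season_periods(y, season)
        vals = [series.value.get(p, np.nan) for p in periods]
        arr = np.asarray(vals, dtype=float)
        if np.isfinite(arr).sum() <= len(season) / 2:
            continue
        values[y] = float(np.nanmean(arr))
        complete[y] = bool(np.all(np.isfinite(arr)))
    idx = pd.Index(sorted(values), name="winter")
    return SeasonalSeries(
        value=pd.Series([values[y] for y in idx], index=idx, name="seasonal_mean"),
        complete=pd.Series([complete[y] for y in idx], index=idx, name="complete"),
        season=season,
    )


def cpue_to_csv(series: CPUESeries, path) -> None:
    """Write monthly CPUE as CSV with columns year, month, cpue, n_records."""
    idx = series.value.index
    pd.DataFrame(
        {
            "year": idx.year,
            "month": idx.month,
            "cpue": series.value.values,
            "n_records": series.n_records.values,
        }
    ).to_csv(path, index=False)
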