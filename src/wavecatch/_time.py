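"""Calendar helpers: monthly axes, winter labelling, lagged-window resolution.

Conventions used throughout the package:

* A *winter* is labelled by the year of the November that opens the
  November-January season (winter ``y`` spans Nov(y), Dec(y), Jan(y+1)).
* Monthly lags are anchored at December of the winter label, so lag 0 of
  winter ``y`` is Dec(y) and lag 12 is Dec(y-1).
* One month, when converted to seconds for phase-speed work, is taken as
  365.25/12 days.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

#: Mean month length in seconds (365.25/12 days); used for speed conversions.
SECONDS_PER_MONTH = 365.25 / 12 * 86400.0

#: Default analysis season (November-January).
NDJ = (11, 12, 1)


def to_periods(time) -> pd.PeriodIndex:
    """Coerce a time coordinate (datetime64 array or index) to monthly periods."""
    return pd.DatetimeIndex(np.asarray(time)).to_period("M")


def check_monthly(time) -> pd.PeriodIndex:
    """Validate a strictly increasing, gap-free monthly axis; return periods."""
    periods = to_periods(time)
    if len(periods) > 1:
        steps = np.diff(periods.asi8)
        if not np.all(steps == 1):
            from .exceptions import AxisError

            raise AxisError(
                "time axis must be strictly increasing with a one-month step "
                f"and no gaps (got steps {sorted(set(steps.tolist()))})"
            )
    return periods


def season_months(season: Sequence[int] = NDJ) -> tuple[int, ...]:
    """Validate that ``season`` is a contiguous run of calendar months."""
    season = tuple(int(m) for m in season)
    if not season or any(m < 1 or m > 12 for m in season):
        raise ValueError(f"invalid season months {season}")
    for prev, nxt in zip(season, season[1:]):
        if nxt != prev % 12 + 1:
            raise ValueError(f"season {season} is not a contiguous month run")
    return season


def season_periods(label: int, season: Sequence[int] = NDJ, lag_months: int = 0) -> list[pd.Period]:
    """Resolve the calendar months of a (possibly lagged) season for one winter.

    The season is labelled by the calendar year of its first month; months that
    fall after a December crossing belong to ``label + 1``.  A positive
    ``lag_months`` shifts every month backward on the calendar, so the NDJ
    season at lag 3 resolves to August-October of the same year and at lag 12
    to the previous winter's NDJ.
    """
    season = season_months(season)
    year = label
    out = []
    for i, m in enumerate(season):
        if i > 0 and m < season[i - 1]:
            year += 1
        out.append(pd.Period(freq="M", year=year, month=m) - int(lag_months))
    return out


def anchor_period(label: int, lag_months: int = 0) -> pd.Period:
    """December of winter ``label``, shifted back by ``lag_months``."""
    return pd.Period(freq="M", year=label, month=12) - int(lag_months)


def winter_labels(periods: pd.PeriodIndex, season: Sequence[int] = NDJ) -> list[int]:
    """All winter labels whose season intersects the given monthly axis."""
    season = season_months(season)
    years = range(periods[0].year - 1, periods[-1].year + 1)
    labels = []
    pset = set(periods)
    for y in years:
        if any(p in pset for p in season_periods(y, season)):
            labels.append(y)
    return labels
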