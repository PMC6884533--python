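import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy import stats as sps

from wavecatch.exceptions import ValidationError
from wavecatch.stats_maps import (
    detect_events,
    detrend_series,
    lag_composite,
    pearson_map,
    t_significance,
)

from .conftest import make_field, winter_series


def _winter_fields(values, first_winter=2000, lats=(30.0, 30.5), lons=(130.0, 130.5)):
    """Per-winter fields from an array shaped (n_winters, n_lat, n_lon)."""
    values = np.asarray(values, dtype=float)
    winters = pd.Index(range(first_winter, first_winter + values.shape[0]), name="winter")
    return xr.DataArray(
        values,
        coords={"winter": winters, "lat": np.asarray(lats), "lon": np.asarray(lons)},
        dims=("winter", "lat", "lon"),
    )


def brute_force_pearson(x, y):
    """Independent oracle: uncentred Pearson via an explicit loop-free formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.sum(x * y) / (np.sqrt(np.sum(x**2)) * np.sqrt(np.sum(y**2)))


class TestPearsonMap:
    def test_proportional_cell_r_one(self):
        x = winter_series([-1.0, 0.0, 1.0, 2.0, -2.0])
        fields = _winter_fields(2.5 * x.value.values[:, None, None] * np.ones((1, 2, 2)))
        cmap = pearson_map(x, fields)
        np.testing.assert_allclose(cmap.r.values, 1.0, atol=1e-12)

    def test_negated_cell_r_minus_one(self):
        x = winter_series([-1.0, 0.0, 1.0, 2.0, -2.0])
        fields = _winter_fields(-x.value.values[:, None, None] * np.ones((1, 2, 2)))
        cmap = pearson_map(x, fields)
        np.testing.assert_allclose(cmap.r.values, -1.0, atol=1e-12)

    def test_hand_computed_example(self):
        # anomalies x' = {-1,0,1}, y' = {-4/3,-1/3,5/3}: R = 3/(sqrt(2) sqrt(42/9))
        x = winter_series([-1.0, 0.0, 1.0])
        yprime = np.array([-4 / 3, -1 / 3, 5 / 3])
        fields = _winter_fields(yprime[:, None, None] * np.ones((1, 2, 2)))
        cmap = pearson_map(x, fields)
        expected = 3.0 / (np.sqrt(2.0) * np.sqrt(42.0 / 9.0))
        np.testing.assert_allclose(cmap.r.values, expected, rtol=1e-10)
        assert expected == pytest.approx(0.9820, abs=5e-5)

    def test_matches_brute_force_loop_on_fixture(self):
        rng = np.random.default_rng(0)
        n_w, n_lat, n_lon = 13, 5, 5
        x = winter_series(rng.normal(size=n_w))
        y = rng.normal(size=(n_w, n_lat, n_lon))
        fields = _winter_fields(y, lats=30 + 0.5 * np.arange(n_lat), lons=130 + 0.5 * np.arange(n_lon))
        cmap = pearson_map(x, fields)
        for i in range(n_lat):
            for j in range(n_lon):
                expected = brute_force_pearson(x.value.values, y[:, i, j])
                assert abs(float(cmap.r.values[i, j]) - expected) < 1e-12

    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(1)
        x = winter_series(rng.normal(size=13))
        fields = _winter_fields(rng.normal(size=(13, 2, 2)))
        cmap = pearson_map(x, fields)
        assert set(np.unique(cmap.df.values)) == {11.0}

    def test_too_few_overlaps_raises(self):
        x = winter_series([1.0, 2.0])
        fields = _winter_fields(np.zeros((2, 2, 2)))
        with pytest.raises(ValidationError):
            pearson_map(x, fields)


class TestTSignificance:
    def test_zero_r_never_significant(self):
        x = winter_series([-1.0, 0.0, 1.0, 2.0, -2.0])
        y = np.zeros((5, 2, 2))
        y[:, 0, 0] = [0, 1, -1, -1, 1]  # orthogonal to x
        fields = _winter_fields(y)
        cmap = pearson_map(x, fields)
        t_significance(cmap, level=0.90)
        assert not bool(cmap.sig_mask.values[0, 0])

    def test_decision_matches_reference_cdf(self):
        # R = 0.5 with df = 11: t = 0.5 sqrt(11/0.75); compare with scipy's CDF
        r, df = 0.5, 11
        t = r * np.sqrt(df / (1 - r**2))
        p = 2 * sps.t.sf(abs(t), df)
        x = winter_series(np.arange(13.0) - 6.0)
        rng = np.random.default_rng(8)
        # construct a cell with R very close to 0.5 against x
        xv = x.value.values
        xv = xv - xv.mean()
        z = rng.normal(size=13)
        z -= z @ xv / (xv @ xv) * xv
        z /= np.sqrt(z @ z)
        xhat = xv / np.sqrt(xv @ xv)
        yv = r * xhat + np.sqrt(1 - r**2) * z
        fields = _winter_fields(yv[:, None, None] * np.ones((1, 2, 2)))
        cmap = pearson_map(x, fields)
        np.testing.assert_allclose(cmap.r.values, r, atol=1e-10)
        t_significance(cmap, level=0.90)
        assert bool(cmap.sig_mask.values[0, 0]) == (p < 0.10)

    def test_perfect_correlation_significant_by_convention(self):
        x = winter_series([-1.0, 0.0, 1.0, 2.0, -2.0])
        fields = _winter_fields(x.value.values[:, None, None] * np.ones((1, 2, 2)))
        cmap = pearson_map(x, fields)
        t_significance(cmap, level=0.99)
        assert bool(cmap.sig_mask.values.all())


class TestDetectEvents:
    def test_all_zero_index_no_events(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            ev = detect_events(winter_series([0.0] * 8))
        assert ev.positive_winters == [] and ev.negative_winters == []

    def test_strict_threshold_and_signs(self):
        vals = [0.1, -0.2, 2.5, 0.0, -2.5, 0.3, -0.1, 0.2]
        ev = detect_events(winter_series(vals, first_winter=1990), threshold_sd=1.0)
        assert ev.positive_winters == [1992]
        assert ev.negative_winters == [1994]

    def test_event_count_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=20)
        s = winter_series(vals)
        counts = []
        for thr in (0.5, 1.0, 1.5, 2.0):
            ev = detect_events(s, threshold_sd=thr)
            counts.append(len(ev.positive_winters) + len(ev.negative_winters))
        assert counts == sorted(counts, reverse=True)

    def test_generator_implant_recovered(self):
        # a +2 sigma winter implanted on weak noise must land in the positive set
        rng = np.random.default_rng(3)
        vals = 0.3 * rng.normal(size=20)
        sd0 = np.std(vals, ddof=1)
        vals[7] = 2.0 * sd0 / 0.3 * 0.3 * 2  # well above 1 SD of the final series
        ev = detect_events(winter_series(vals, first_winter=2000))
        assert 2007 in ev.positive_winters


class TestLagComposite:
    def _anoms(self, n_time=72, start="2000-01"):
        rng = np.random.default_rng(0)
        da = make_field(n_time=n_time, start=start)
        return da.copy(data=rng.normal(size=da.shape))

    def test_single_event_equals_member_field(self):
        da = self._anoms()
        ev = detect_events(winter_series([0.0, 0.0, 3.0, 0.0, -0.1, 0.1], first_winter=2000))
        comp = lag_composite(da, ev, sign="positive", lag_months=0, window="monthly")
        assert comp.n_events == 1 and comp.t_stat is None
        dec = da.sel(time="2002-12-01").values
        np.testing.assert_array_equal(comp.mean_anomaly.values, dec)

    def test_equal_and_opposite_members_cancel(self):
        da = make_field(n_time=72, start="2000-01")
        vals = da.values.copy()
        i1 = 35  # Dec 2002
        i2 = 47  # Dec 2003
        vals[i1] = 4.0
        vals[i2] = -4.0
        da = da.copy(data=vals)
        ev = detect_events(winter_series([0, 0, 3.0, 3.0, 0, -0.1], first_winter=2000))
        comp = lag_composite(da, ev, sign="positive", lag_months=0, window="monthly")
        np.testing.assert_allclose(comp.mean_anomaly.values, 0.0, atol=1e-12)

    def test_mean_equals_brute_force_member_mean(self):
        da = self._anoms()
        ev = detect_events(winter_series([0, 3.0, 0, 3.0, 0, -0.1], first_winter=2000))
        for window, lag in (("monthly", 2), ("seasonal", 3)):
            comp = lag_composite(da, ev, sign="positive", lag_months=lag, window=window)
            members = []
            for y in comp.members:
                if window == "monthly":
                    t = pd.Period(f"{y}-12", "M") - lag
                    members.append(da.sel(time=t.to_timestamp()).values)
                else:
                    from wavecatch._time import season_periods

                    ps = season_periods(y, lag_months=lag)
                    members.append(
                        np.mean([da.sel(time=p.to_timestamp()).values for p in ps], axis=0)
                    )
            expected = np.mean(members, axis=0)
            np.testing.assert_array_equal(comp.mean_anomaly.values, expected)

    def test_event_before_record_dropped(self):
        da = self._anoms(n_time=72, start="2000-01")
        ev = detect_events(winter_series([3.0, 0, 0, 3.0, 0, -0.1], first_winter=2000))
        comp = lag_composite(da, ev, sign="positive", lag_months=16, window="monthly")
        # winter 2000 at lag 16 needs Aug 1999: before the record
        assert comp.n_events == 1 and comp.members == [2003]

    def test_no_events_raises(self):
        da = self._anoms()
        ev = detect_events(winter_series([0.1, -0.1, 0.1, -0.1, 0.1, -0.1], first_winter=2000))
        assert ev.positive_winters == []
        with pytest.raises(ValidationError):
            lag_composite(da, ev, sign="positive")


class TestDetrendSeries:
    def test_removes_mean_and_trend(self):
        s = winter_series(np.arange(10.0) * 2 + 5)
        out = detrend_series(s)
        np.testing.assert_allclose(out.value.values, 0.0, atol=1e-9)
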