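import numpy as np
import pandas as pd
import pytest

from demosync.covariates import (
    SEASONS,
    count_eces,
    match_mast,
    mean_clutch_size_lag,
    seasonal_aggregate,
)
from demosync.geo import haversine_km


def _daily(start, end, pop="A", tmean=None, tmin=None, tmax=None, precip=None, seed=0):
    dates = pd.date_range(start, end, freq="D")
    rng = np.random.default_rng(seed)
    n = len(dates)
    return pd.DataFrame({
        "population_id": pop,
        "date": dates,
        "tmean": tmean if tmean is not None else rng.normal(8, 6, n),
        "tmin": tmin if tmin is not None else rng.normal(3, 6, n),
        "tmax": tmax if tmax is not None else rng.normal(13, 6, n),
        "precip": precip if precip is not None else rng.gamma(1.0, 2.0, n),
    })


class TestSeasonalAggregate:
    def test_constant_input(self):
        daily = _daily("2000-06-01", "2001-05-31", tmean=5.0)
        out = seasonal_aggregate(daily, "A", 2001)
        assert all(out[f"temp_{s}"] == pytest.approx(5.0)
                   for s, _, _ in SEASONS)

    def test_disjoint_windows(self):
        daily = _daily("2000-06-01", "2001-05-31")
        dates = pd.to_datetime(daily["date"])
        daily["tmean"] = np.where(dates.dt.month.isin([6, 7, 8]), 10.0, 0.0)
        out = seasonal_aggregate(daily, "A", 2001)
        assert out["temp_summer"] == pytest.approx(10.0)
        assert out["temp_winter"] == pytest.approx(0.0)

    def test_matches_calendar_filter_oracle(self):
        daily = _daily("2000-06-01", "2001-05-31", seed=11)
        out = seasonal_aggregate(daily, "A", 2001)
        dates = pd.to_datetime(daily["date"])
        windows = {
            "summer": (dates >= "2000-06-01") & (dates <= "2000-08-31"),
            "autumn": (dates >= "2000-09-01") & (dates <= "2000-11-30"),
            "winter": (dates >= "2000-12-01") & (dates <= "2001-02-28"),
            "spring": (dates >= "2001-03-01") & (dates <= "2001-05-31"),
        }
        for name, mask in windows.items():
            assert out[f"temp_{name}"] == pytest.approx(daily.loc[mask, "tmean"].mean())
            assert out[f"precip_{name}"] == pytest.approx(daily.loc[mask, "precip"].mean())

    def test_windows_partition_the_year(self):
        daily = _daily("2000-06-01", "2001-05-31")
        dates = pd.to_datetime(daily["date"])
        from demosync.covariates import _season_mask

        total = sum(_season_mask(dates, label, 2001).sum() for label, _, _ in SEASONS)
        assert total == len(daily)  # every day in exactly one season

    def test_missing_days_beyond_tolerance_gives_nan(self):
        daily = _daily("2000-06-01", "2001-05-31", tmean=5.0)
        dates = pd.to_datetime(daily["date"])
        keep = ~((dates.dt.month == 7) | (dates.dt.month == 8))  # drop 2/3 of summer
        out = seasonal_aggregate(daily[keep], "A", 2001)
        assert np.isnan(out["temp_summer"])
        assert out["temp_spring"] == pytest.approx(5.0)


class TestExtremeEvents:
    def test_constant_series_has_no_events(self):
        daily = _daily("2000-06-01", "2001-05-31", tmin=0.0, tmax=10.0)
        assert count_eces(daily, "A", 2001) == (0, 0)

    def test_toy_series_bruteforce_count(self):
        # 20 days; one clearly extreme low below the 5th percentile
        tmin = np.full(20, 5.0) + np.arange(20) * 0.01
        tmin[7] = -20.0
        daily = _daily("2000-06-01", "2000-06-20", tmin=tmin, tmax=np.full(20, 15.0))
        n_cold, n_hot = count_eces(daily, "A", 2001)
        lo = np.quantile(tmin, 0.05)
        assert n_cold == int((tmin < lo).sum()) == 1
        assert n_hot == 0

    def test_iid_year_gives_about_five_percent(self):
        rng = np.random.default_rng(2)
        n = 365
        daily = _daily("2000-06-01", "2001-05-31", tmin=rng.normal(0, 5, n),
                       tmax=rng.normal(10, 5, n))
        n_cold, n_hot = count_eces(daily, "A", 2001)
        sd = np.sqrt(n * 0.05 * 0.95)  # binomial sd ~ 4.2 days
        assert abs(n_cold - 0.05 * n) <= 3 * sd
        assert abs(n_hot - 0.05 * n) <= 3 * sd

    def test_thresholds_use_full_record_but_counts_use_window(self):
        # cold spell outside the count window must not be counted
        daily = _daily("1999-06-01", "2001-05-31", tmin=0.0, tmax=10.0)
        daily.loc[:39, "tmin"] = -30.0  # extremes in 1999 only
        n_cold, _ = count_eces(daily, "A", 2001)
        assert n_cold == 0


class TestClutchSize:
    def test_arithmetic(self):
        nests = pd.DataFrame({"population_id": "A", "year": 2000,
                              "clutch_size": [8, 10, 9]})
        assert mean_clutch_size_lag(nests, "A", 2001) == pytest.approx(9.0)

    def test_no_previous_year_is_missing(self):
        nests = pd.DataFrame({"population_id": ["A"], "year": [2001], "clutch_size": [9]})
        assert np.isnan(mean_clutch_size_lag(nests, "A", 2001))

    def test_matches_loop_oracle_and_rejects_nonpositive(self):
        rng = np.random.default_rng(3)
        sizes = rng.integers(4, 14, size=50).astype(float)
        nests = pd.DataFrame({"population_id": "A", "year": 2005, "clutch_size": sizes})
        nests.loc[len(nests)] = ["A", 2005, 0.0]  # rejected row
        assert mean_clutch_size_lag(nests, "A", 2006) == pytest.approx(sizes.mean())


class TestMastMatching:
    def _mast(self, coords, year=2000):
        return pd.DataFrame({
            "site_id": range(len(coords)),
            "lat": [c[0] for c in coords], "lon": [c[1] for c in coords],
            "year": year, "mast_value": np.arange(len(coords), dtype=float),
        })

    def test_coincident_site(self):
        mast = self._mast([(50.0, 10.0)])
        value, dist, is_local = match_mast(50.0, 10.0, True, mast, 2001)
        assert dist == 0.0 and value == 0.0 and is_local

    def test_beyond_1500_km_is_missing(self):
        mast = self._mast([(50.0, 10.0)])
        value, dist, _ = match_mast(50.0, 33.0, True, mast, 2001)  # ~1630 km east
        assert dist > 1500 and np.isnan(value)

    def test_nearest_matches_bruteforce_haversine(self):
        rng = np.random.default_rng(4)
        coords = [(rng.uniform(40, 60), rng.uniform(0, 30)) for _ in range(3)]
        mast = self._mast(coords)
        value, dist, _ = match_mast(50.0, 15.0, True, mast, 2001)
        dists = [haversine_km(50.0, 15.0, la, lo) for la, lo in coords]
        assert value == float(np.argmin(dists))
        assert dist == pytest.approx(min(dists))

    def test_local_needs_distance_and_beech_flag(self):
        mast = self._mast([(50.0, 10.0)])
        _, _, local_far = match_mast(50.0, 12.0, True, mast, 2001)   # ~143 km
        _, _, local_no_beech = match_mast(50.0, 10.2, False, mast, 2001)
        _, _, local_ok = match_mast(50.0, 10.2, True, mast, 2001)    # ~14 km
        assert not local_far and not local_no_beech and local_ok

    def test_tie_resolves_to_lowest_site_index(self):
        mast = self._mast([(50.0, 11.0), (50.0, 9.0)])  # symmetric about lon 10
        value, _, _ = match_mast(50.0, 10.0, True, mast, 2001)
        assert value == 0.0
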