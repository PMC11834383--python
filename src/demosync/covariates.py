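"""Per-population-year explanatory variables.

Thirteen variables are built for each population-year t, all referring to the
twelve months preceding (and including the spring of) the focal breeding
season:

* ``clutch_size_lag1`` — mean clutch size per breeding attempt in year t-1;
* seasonal means of daily mean temperature and of daily precipitation over
  summer (Jun–Aug, t-1), autumn (Sep–Nov, t-1), winter (Dec t-1 – Feb t) and
  spring (Mar–May, t);
* ``n_cold_ece`` / ``n_hot_ece`` — counts of extreme climatic event days in
  June(t-1)–May(t): days whose minimum temperature falls below the 5th
  percentile of the population's full daily record, or whose maximum exceeds
  its 95th percentile;
* ``mast_lag1`` — the beech mast value in year t-1 at the geographically
  nearest mast-collection site (missing beyond 1500 km), and
  ``mast_lag1_local`` — the same value restricted to populations inside the
  beech distribution with a mast site within 100 km.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import haversine_km

logger = logging.getLogger(__name__)

COVARIATE_NAMES = (
    "clutch_size_lag1",
    "temp_summer", "temp_autumn", "temp_winter", "temp_spring",
    "precip_summer", "precip_autumn", "precip_winter", "precip_spring",
    "n_cold_ece", "n_hot_ece",
    "mast_lag1", "mast_lag1_local",
)

# (label, months, year offset relative to breeding year) — the four windows
# partition June 1 (t-1) .. May 31 (t)
SEASONS = (
    ("summer", (6, 7, 8), -1),
    ("autumn", (9, 10, 11), -1),
    ("winter", (12, 1, 2), 0),   # Dec belongs to t-1, Jan/Feb to t
    ("spring", (3, 4, 5), 0),
)


@dataclass
class CovariateConfig:
    max_missing_fraction: float = 0.10
    ece_lower_q: float = 0.05
    ece_upper_q: float = 0.95
    mast_max_km: float = 1500.0
    mast_local_km: float = 100.0
    first_clutches_only: bool = False


def _season_mask(dates: pd.Series, label: str, breeding_year: int) -> pd.Series:
    months, _ = {s[0]: (s[1], s[2]) for s in SEASONS}[label]
    mask = pd.Series(False, index=dates.index)
    for m in months:
        y = breeding_year - 1 if (m >= 6 or (label == "winter" and m == 12)) else breeding_year
        mask |= (dates.dt.month == m) & (dates.dt.year == y)
    return mask


def _expected_days(label: str, breeding_year: int) -> int:
    months = {s[0]: s[1] for s in SEASONS}[label]
    n = 0
    for m in months:
        y = breeding_year - 1 if (m >= 6 or (label == "winter" and m == 12)) else breeding_year
        n += pd.Period(f"{y}-{m:02d}").days_in_month
    return n


def seasonal_aggregate(
    daily: pd.DataFrame,
    population_id,
    breeding_year: int,
    max_missing_fraction: float = 0.10,
) -> dict:
    """Seasonal temperature and precipitation means preceding one breeding season.

    Returns a dict with keys ``temp_{season}`` (mean of daily ``tmean``) and
    ``precip_{season}`` (mean of daily ``precip``). A window with more than
    ``max_missing_fraction`` of its calendar days missing yields NaN.
    """
    d = daily[daily["population_id"] == population_id]
    dates = pd.to_datetime(d["date"])
    out = {}
    for label, _, _ in SEASONS:
        mask = _season_mask(dates, label, breeding_year)
        expected = _expected_days(label, breeding_year)
        window = d[mask]
        for prefix, col in (("temp", "tmean"), ("precip", "precip")):
            vals = window[col].dropna()
            if len(vals) < (1.0 - max_missing_fraction) * expected:
                logger.warning(
                    "%s %s %d: %d/%d days present; value set missing",
                    population_id, label, breeding_year, len(vals), expected,
                )
                out[f"{prefix}_{label}"] = np.nan
            else:
                out[f"{prefix}_{label}"] = float(vals.mean())
    return out


def ece_thresholds(daily_pop: pd.DataFrame, lower_q=0.05, upper_q=0.95) -> tuple[float, float]:
    """Population-specific cold/hot thresholds over the full daily record."""
    lo = float(np.quantile(daily_pop["tmin"].dropna(), lower_q))
    hi = float(np.quantile(daily_pop["tmax"].dropna(), upper_q))
    return lo, hi


def count_eces(
    daily: pd.DataFrame,
    population_id,
    breeding_year: int,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
) -> tuple[float, float]:
    """Numbers of cold and hot extreme-event days in June(t-1)–May(t).

    Thresholds are the 5th percentile of daily minimum temperature and the
    95th percentile of daily maximum temperature over the population's entire
    record; a day counts when it falls strictly beyond a threshold.
    """
    d = daily[daily["population_id"] == population_id]
    if d.empty:
        return np.nan, np.nan
    lo, hi = ece_thresholds(d, lower_q, upper_q)
    dates = pd.to_datetime(d["date"])
    start = pd.Timestamp(breeding_year - 1, 6, 1)
    end = pd.Timestamp(breeding_year, 5, 31)
    window = d[(dates >= start) & (dates <= end)]
    if window.empty:
        return np.nan, np.nan
    n_cold = int((window["tmin"] < lo).sum())
    n_hot = int((window["tmax"] > hi).sum())
    return n_cold, n_hot


def mean_clutch_size_lag(
    nests: pd.DataFrame,
    population_id,
    breeding_year: int,
    first_clutches_only: bool = False,
) -> float:
    """Mean clutch size per breeding attempt in the year before breeding."""
    sel = nests[(nests["population_id"] == population_id) & (nests["year"] == breeding_year - 1)]
    bad = sel["clutch_size"] <= 0
    if bad.any():
        logger.warning("%d non-positive clutch sizes rejected", int(bad.sum()))
        sel = sel[~bad]
    if first_clutches_only and "attempt" in sel.columns:
        sel = sel[sel["attempt"] == 1]
    if sel.empty:
        return np.nan
    return float(sel["clutch_size"].mean())


def match_mast(
    site_lat: float,
    site_lon: float,
    beech_flag: bool,
    mast: pd.DataFrame,
    breeding_year: int,
    max_km: float = 1500.0,
    local_km: float = 100.0,
) -> tuple[float, float, bool]:
    """Beech mast value from the nearest collection site in year t-1.

    Returns ``(mast_value, distance_km, is_local)``. The value is missing when
    the nearest site with a record lies beyond ``max_km``; ``is_local`` asks
    additionally that the site is within ``local_km`` and the population sits
    inside the beech distribution. Distance ties resolve to the lowest site
    index.
    """
    cand = mast[mast["year"] == breeding_year - 1]
    if cand.empty:
        return np.nan, np.nan, False
    dist = haversine_km(site_lat, site_lon, cand["lat"].to_numpy(), cand["lon"].to_numpy())
    order = np.lexsort((np.arange(len(dist)), dist))
    best = order[0]
    if len(dist) > 1 and np.isclose(dist[order[0]], dist[order[1]]):
        logger.info("mast distance tie at %.3f km; lowest site index wins", dist[best])
    d = float(dist[best])
    if d > max_km:
        return np.nan, d, False
    value = float(cand["mast_value"].to_numpy()[best])
    is_local = bool(d <= local_km and beech_flag)
    return value, d, is_local


def build_covariates(
    sites: pd.DataFrame,
    years_by_population: dict,
    daily: pd.DataFrame | None = None,
    nests: pd.DataFrame | None = None,
    mast: pd.DataFrame | None = None,
    config: CovariateConfig | None = None,
) -> pd.DataFrame:
    """Long-format covariate table for every requested population-year.

    ``years_by_population`` maps population_id -> iterable of breeding years.
    Missing input tables simply leave their covariates out.
    """
    config = config or CovariateConfig()
    site_ix = sites.set_index("population_id")
    rows = []

    def add(pop, year, name, value, meta=np.nan):
        rows.append(
            {"population_id": pop, "year": int(year), "name": name,
             "value": value, "meta_distance_km": meta}
        )

    for pop, years in years_by_population.items():
        daily_pop = daily[daily["population_id"] == pop] if daily is not None else None
        for year in years:
            if nests is not None:
                add(pop, year, "clutch_size_lag1",
                    mean_clutch_size_lag(nests, pop, year, config.first_clutches_only))
            if daily_pop is not None and len(daily_pop):
                seas = seasonal_aggregate(daily_pop, pop, year, config.max_missing_fraction)
                for name, value in seas.items():
                    add(pop, year, name, value)
                n_cold, n_hot = count_eces(
                    daily_pop, pop, year, config.ece_lower_q, config.ece_upper_q
                )
                add(pop, year, "n_cold_ece", n_cold)
                add(pop, year, "n_hot_ece", n_hot)
            if mast is not None:
                meta = site_ix.loc[pop]
                value, dist, is_local = match_mast(
                    float(meta["lat"]), float(meta["lon"]), bool(meta.get("beech_flag", False)),
                    mast, year, config.mast_max_km, config.mast_local_km,
                )
                add(pop, year, "mast_lag1", value, dist)
                add(pop, year, "mast_lag1_local", value if is_local else np.nan, dist)
    return pd.DataFrame(rows)


def covariates_wide(covariates: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long covariate table to one column per variable."""
    return (
        covariates.pivot_table(
            index=["population_id", "year"], columns="name", values="value", aggfunc="first"
        )
        .reset_index()
        .rename_axis(columns=None)
    )
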