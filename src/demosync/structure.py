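"""Annual breeding demographic structure from individual capture records.

Each breeding great tit is assigned an integer age: birds with a known hatch
year get their exact age (year - hatch_year); birds first trapped as breeding
adults are assigned age 2 at first capture, with later captures aged forward
from that. Age 1 birds are subadults; the primary descriptor of a population's
breeding demographic structure is the proportion of its aged breeders that are
subadults. Alternative descriptors (mean age, proportion senescent, and the
change of each descriptor against a trailing running mean) are computed
alongside. Population-years enter downstream analyses only when at least
``min_n_breeders`` parents bred and more than ``min_aged_fraction`` of them
could be aged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESCRIPTORS = (
    "prop_subadult",
    "mean_age",
    "prop_senescent",
    "delta_prop_subadult",
    "delta_mean_age",
    "delta_prop_senescent",
)

#: default thresholds for including a population-year
MIN_N_BREEDERS = 20
MIN_AGED_FRACTION = 0.25


@dataclass
class StructureConfig:
    senescent_age_threshold: int = 4
    running_mean_window: int = 5
    min_n_breeders: int = MIN_N_BREEDERS
    min_aged_fraction: float = MIN_AGED_FRACTION


def read_breeding_records(path) -> pd.DataFrame:
    """Read a breeding-records CSV (empty fields are missing)."""
    df = pd.read_csv(
        path,
        dtype={"population_id": str, "individual_id": str, "first_capture_age_class": str},
    )
    df["year"] = df["year"].astype(int)
    df["hatch_year"] = pd.to_numeric(df["hatch_year"], errors="coerce")
    return df


def assign_ages(records: pd.DataFrame) -> pd.DataFrame:
    """Assign an integer age to every capture of an identified breeder.

    Parameters
    ----------
    records : DataFrame
        Columns ``population_id, year, individual_id, hatch_year,
        first_capture_age_class`` (extra columns are ignored). Rows with a
        missing ``individual_id`` cannot be aged and are dropped here; they
        still count toward ``n_breeders`` in :func:`summarise_all`.

    Returns
    -------
    DataFrame with columns ``population_id, year, individual_id, age,
    age_known_exactly``; one row per input capture that could be aged.

    Notes
    -----
    Birds first captured as subadults have an implied hatch year of the year
    before first capture; if ``hatch_year`` is absent for such a record it is
    filled from that rule. Birds first captured as adults, with no hatch year,
    are assigned age 2 in their first capture year and aged forward from it.
    Records whose computed age falls below 1 are rejected with an error logged.
    """
    rec = records[records["individual_id"].notna() & (records["individual_id"] != "")].copy()
    if rec.empty:
        return pd.DataFrame(
            columns=["population_id", "year", "individual_id", "age", "age_known_exactly"]
        )

    first = rec.sort_values("year").groupby("individual_id", sort=False).first()
    first_year = first["year"]
    first_class = first["first_capture_age_class"]

    # consolidate hatch year per individual (it is a property of the bird)
    hatch = rec.groupby("individual_id")["hatch_year"].first()
    implied = first_year - 1
    use_implied = hatch.isna() & (first_class == "subadult")
    hatch = hatch.where(~use_implied, implied)

    inconsistent = hatch.notna() & (first_class == "adult")
    if inconsistent.any():
        logger.warning(
            "%d individuals first captured as adults carry a hatch year; "
            "using the hatch year", int(inconsistent.sum()),
        )

    rec["_hatch"] = rec["individual_id"].map(hatch)
    rec["_first_year"] = rec["individual_id"].map(first_year)

    known = rec["_hatch"].notna()
    age = np.where(known, rec["year"] - rec["_hatch"], 2 + rec["year"] - rec["_first_year"])

    bad = age < 1
    if bad.any():
        logger.error("rejecting %d records with computed age < 1", int(bad.sum()))

    out = pd.DataFrame(
        {
            "population_id": rec["population_id"],
            "year": rec["year"],
            "individual_id": rec["individual_id"],
            "age": age.astype(float),
            "age_known_exactly": known.to_numpy(),
        }
    )
    out = out[~bad].reset_index(drop=True)
    out["age"] = out["age"].astype(int)
    return out


def summarise_population(
    aged: pd.DataFrame,
    all_parents_count: int,
    population_id,
    year: int,
    senescent_age_threshold: int = 4,
    min_n_breeders: int = MIN_N_BREEDERS,
    min_aged_fraction: float = MIN_AGED_FRACTION,
) -> dict:
    """Descriptor summary for one population-year.

    ``aged`` holds the aged captures of that population-year; individuals
    breeding more than once in the season are counted once. ``all_parents_count``
    is the number of breeders including unaged ones (never below the aged count).
    """
    if len(aged):
        aged = aged.drop_duplicates(subset="individual_id")
    n_aged = len(aged)
    n_breeders = max(int(all_parents_count), n_aged)
    if n_aged == 0:
        prop_subadult = mean_age = prop_senescent = np.nan
        passes = False
    else:
        ages = aged["age"].to_numpy()
        prop_subadult = float(np.mean(ages == 1))
        mean_age = float(np.mean(ages))
        prop_senescent = float(np.mean(ages >= senescent_age_threshold))
        passes = (n_breeders >= min_n_breeders) and (n_aged / n_breeders > min_aged_fraction)
    return {
        "population_id": population_id,
        "year": int(year),
        "n_breeders": n_breeders,
        "n_aged": n_aged,
        "prop_subadult": prop_subadult,
        "mean_age": mean_age,
        "prop_senescent": prop_senescent,
        "passes_filters": bool(passes),
    }


def running_mean_deltas(summaries: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Add delta descriptors: value minus the mean of the previous ``window``
    observed years (missing when fewer than 2 prior observed years exist).

    ``summaries`` holds one population, sorted by year; observed years are the
    rows present, so gaps in the calendar do not shrink the window.
    """
    out = summaries.sort_values("year").reset_index(drop=True).copy()
    for col in ("prop_subadult", "mean_age", "prop_senescent"):
        x = out[col]
        prior_mean = x.shift(1).rolling(window, min_periods=2).mean()
        out["delta_" + col] = x - prior_mean
    return out


def summarise_all(
    records: pd.DataFrame,
    config: StructureConfig | None = None,
) -> pd.DataFrame:
    """Full ingest: records -> filtered annual summaries for every population.

    ``n_breeders`` counts distinct identified parents plus one per
    unidentified-parent row (unknown identities cannot be deduplicated).
    """
    config = config or StructureConfig()
    aged = assign_ages(records)

    ident = records["individual_id"].notna() & (records["individual_id"] != "")
    n_known = (
        records[ident]
        .groupby(["population_id", "year"])["individual_id"]
        .nunique()
        .rename("n_known")
    )
    n_unknown = (
        records[~ident].groupby(["population_id", "year"]).size().rename("n_unknown")
    )
    breeders = pd.concat([n_known, n_unknown], axis=1).fillna(0)
    breeders["n_breeders"] = (breeders["n_known"] + breeders["n_unknown"]).astype(int)

    rows = []
    aged_groups = dict(iter(aged.groupby(["population_id", "year"]))) if len(aged) else {}
    for (pop, year), brow in breeders.iterrows():
        grp = aged_groups.get((pop, year), aged.iloc[:0])
        rows.append(
            summarise_population(
                grp,
                int(brow["n_breeders"]),
                pop,
                year,
                senescent_age_threshold=config.senescent_age_threshold,
                min_n_breeders=config.min_n_breeders,
                min_aged_fraction=config.min_aged_fraction,
            )
        )
    summ = pd.DataFrame(rows)
    summ = pd.concat(
        [
            running_mean_deltas(grp, window=config.running_mean_window)
            for _, grp in summ.groupby("population_id")
        ],
        ignore_index=True,
    )
    cols = ["population_id", "year", "n_breeders", "n_aged", *DESCRIPTORS, "passes_filters"]
    return summ[cols].sort_values(["population_id", "year"]).reset_index(drop=True)
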