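"""Irregular population-by-year panels for the synchrony likelihood.

Populations are observed over staggered multi-decade windows, so each year t
carries a value vector for only the subset of populations monitored that year.
The panel stores a dense populations x years matrix with NaN for unobserved
cells, a per-population normalised copy (sample mean 0, sd 1 over each
population's observed years — required by the unit diagonal of the yearly
correlation matrices), and a grouping of year columns by their observation
pattern: years observing the same set of populations share one correlation
matrix, which the likelihood exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import SiteGeometry


@dataclass
class Pattern:
    """Years sharing one set of observed populations."""

    pop_idx: np.ndarray      # indices into the panel's population list
    year_cols: np.ndarray    # column indices of the years with this pattern


@dataclass
class PanelData:
    population_ids: list
    years: np.ndarray                      # sorted calendar years (columns)
    values: np.ndarray                     # raw matrix, NaN = unobserved
    normalised: np.ndarray = field(default=None, repr=False)
    patterns: list = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.normalised is None:
            self.normalised = normalise_rows(self.values)
        if self.patterns is None:
            # populations with <2 observed years (or zero variance) have an
            # all-NaN normalised row and drop out of the likelihood
            self.patterns = find_patterns(self.normalised)

    @property
    def n_populations(self) -> int:
        return len(self.population_ids)

    @property
    def n_years_used(self) -> int:
        """Years entering the likelihood (>= 2 populations observed)."""
        return int(sum(len(p.year_cols) for p in self.patterns))

    def filter_years(self, start: int | None = None, end: int | None = None) -> "PanelData":
        """Restrict to breeding years in [start, end] (either side open)."""
        keep = np.ones(len(self.years), dtype=bool)
        if start is not None:
            keep &= self.years >= start
        if end is not None:
            keep &= self.years <= end
        return PanelData(self.population_ids, self.years[keep], self.values[:, keep])

    def overlap_years(self) -> np.ndarray:
        """Pairwise counts of co-observed years (the likelihood weights)."""
        obs = ~np.isnan(self.values)
        return (obs.astype(int) @ obs.T.astype(int)).astype(int)

    @classmethod
    def from_summaries(
        cls,
        summaries: pd.DataFrame,
        descriptor: str = "prop_subadult",
        apply_filters: bool = True,
        years: tuple | None = None,
    ) -> "PanelData":
        """Panel of one descriptor from the annual-summary table.

        Rows failing the sample-size/aged-fraction filters are excluded when
        ``apply_filters``; ``years=(start, end)`` restricts the calendar range.
        """
        df = summaries
        if apply_filters and "passes_filters" in df.columns:
            df = df[df["passes_filters"].astype(bool)]
        df = df[df[descriptor].notna()]
        wide = df.pivot_table(index="population_id", columns="year", values=descriptor,
                              aggfunc="first")
        panel = cls(list(wide.index), wide.columns.to_numpy(int), wide.to_numpy(float))
        if years is not None:
            panel = panel.filter_years(*years)
        return panel


def normalise_rows(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Per-row (population) z-normalisation over observed entries."""
    out = np.full_like(values, np.nan)
    for i in range(values.shape[0]):
        row = values[i]
        obs = ~np.isnan(row)
        if obs.sum() >= 2:
            sd = np.std(row[obs], ddof=ddof)
            if sd > 0:
                out[i, obs] = (row[obs] - np.mean(row[obs])) / sd
    return out


def find_patterns(values: np.ndarray) -> list:
    """Group year columns by identical sets of observed populations.

    Years with fewer than two observed populations carry no information about
    cross-population correlation and are dropped.
    """
    obs = ~np.isnan(values)
    groups: dict[bytes, list] = {}
    for t in range(values.shape[1]):
        col = obs[:, t]
        if col.sum() < 2:
            continue
        groups.setdefault(col.tobytes(), []).append(t)
    patterns = []
    for key, cols in groups.items():
        mask = np.frombuffer(key, dtype=bool)
        patterns.append(Pattern(np.flatnonzero(mask), np.asarray(cols, dtype=np.int64)))
    patterns.sort(key=lambda p: p.year_cols[0])
    return patterns


def check_alignment(panel: PanelData, geometry: SiteGeometry) -> np.ndarray:
    """Map panel population order onto geometry order; error on mismatch."""
    return geometry.index_of(panel.population_ids)
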