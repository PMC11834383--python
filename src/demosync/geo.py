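"""Great-circle geometry shared by the covariate matching and synchrony modules.

All distances in the package are haversine great-circle distances on a sphere
of radius 6371.0 km; at the continental scales involved (< ~4000 km) the error
relative to an ellipsoidal model is below 0.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


@dataclass
class SiteGeometry:
    """Population coordinates and their pairwise great-circle distance matrix."""

    population_ids: list
    latitude: np.ndarray
    longitude: np.ndarray
    distance_km: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        if np.any(np.abs(self.latitude) > 90.0) or np.any(np.abs(self.longitude) > 180.0):
            raise ValueError("coordinates outside [-90, 90] x [-180, 180]")
        if self.distance_km is None:
            self.distance_km = haversine_km(
                self.latitude[:, None], self.longitude[:, None],
                self.latitude[None, :], self.longitude[None, :],
            )
            np.fill_diagonal(self.distance_km, 0.0)

    @property
    def n_populations(self) -> int:
        return len(self.population_ids)

    def index_of(self, population_ids) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.population_ids)}
        return np.array([lookup[p] for p in population_ids], dtype=np.int64)

    @classmethod
    def from_sites(cls, sites) -> "SiteGeometry":
        """Build from a sites table with columns population_id, lat, lon."""
        return cls(
            population_ids=list(sites["population_id"]),
            latitude=sites["lat"].to_numpy(dtype=float),
            longitude=sites["lon"].to_numpy(dtype=float),
        )


def haversine_matrix(sites) -> SiteGeometry:
    """Pairwise distance matrix for a sites table (population_id, lat, lon)."""
    return SiteGeometry.from_sites(sites)
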