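"""Distance-decay spatial synchrony estimated by yearly MVN maximum likelihood.

The synchrony between two populations a distance d km apart is modelled with
a Gaussian autocorrelation function

    rho(d) = rho_inf + (rho0 - rho_inf) * exp(-d^2 / (2 l^2))

where rho0 is the correlation as distance approaches zero, rho_inf the
correlation at infinite distance, and l (km) the standard deviation of the
Gaussian kernel — the characteristic spatial scale over which fluctuations
remain correlated. Each year's vector of per-population normalised descriptor
values is taken to be multivariate normal with unit variances and
correlations rho(d_ij); the total log-likelihood is the sum of the annual
terms, so population pairs whose series overlap for more years contribute
proportionally more (overlap weighting is emergent). Parameters are
constrained to 0 <= rho_inf <= rho0 < 1, l > 0: pairwise sample correlations
may be negative, but the modelled average synchrony cannot be.

Uncertainty comes from a parametric bootstrap: panels are re-simulated from
the fitted correlation structure on the observed yearly population sets,
re-normalised, and refitted; medians and 95% percentile intervals of the
parameters and of rho at reference distances are reported.

Usage::

    model = SpatialSynchrony.from_summaries(summaries, sites)
    res = model.fit(seed=1)
    boot = res.bootstrap(n_reps=2000, seed=1)
    print(boot.summary())
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from ._likelihood import PackedPanel, loglik_reference, nll_packed
from .geo import SiteGeometry
from .panel import PanelData, normalise_rows

logger = logging.getLogger(__name__)

REFERENCE_DISTANCES = (100.0, 500.0, 1000.0, 2500.0)


@dataclass
class SynchronyParams:
    """The triple (rho0, rho_inf, l) of the Gaussian synchrony curve."""

    rho0: float
    rho_inf: float
    l: float

    def __post_init__(self):
        if not (0.0 <= self.rho_inf <= self.rho0 < 1.0):
            raise ValueError(f"require 0 <= rho_inf <= rho0 < 1, got {self}")
        if not self.l > 0:
            raise ValueError("require l > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.rho0, self.rho_inf, self.l])


def rho(d, params: SynchronyParams):
    """Synchrony at distance d km; rho(0) = rho0, rho(inf) -> rho_inf."""
    d = np.asarray(d, dtype=float)
    out = params.rho_inf + (params.rho0 - params.rho_inf) * np.exp(
        -(d ** 2) / (2.0 * params.l ** 2)
    )
    return float(out) if out.ndim == 0 else out


def build_sigma(population_ids, geometry: SiteGeometry, params: SynchronyParams) -> np.ndarray:
    """Unit-diagonal correlation matrix for the populations observed in a year."""
    idx = geometry.index_of(population_ids)
    if len(idx) < 2:
        raise ValueError("need at least two observed populations")
    d = geometry.distance_km[np.ix_(idx, idx)]
    sigma = rho(d, params)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def log_likelihood(
    params: SynchronyParams,
    panel: PanelData,
    geometry: SiteGeometry,
    method: str = "kernel",
) -> float:
    """Summed annual MVN log-likelihood of the normalised panel.

    ``method="kernel"`` uses the compiled pattern-grouped path; ``"reference"``
    is the slow explicit-inverse check, identical to within numerical error.
    """
    if method == "reference":
        return loglik_reference(params.rho0, params.rho_inf, params.l, panel, geometry)
    packed = PackedPanel(panel, geometry)
    return -nll_packed(params.rho0, params.rho_inf, params.l, packed)


# ---------------------------------------------------------------------------
# parameter transform: unconstrained theta <-> constrained (rho0, rho_inf, l)

_THETA_BOUND = 13.0


def _theta_to_params(theta, l_bounds):
    r0 = expit(theta[0])
    ri = r0 * expit(theta[1])
    l = float(np.exp(theta[2]))
    return r0, ri, np.clip(l, *l_bounds)

def _params_to_theta(rho0, rho_inf, l):
    r0 = np.clip(rho0, 1e-6, 1 - 1e-6)
    ratio = np.clip(rho_inf / r0 if r0 > 0 else 0.0, 1e-6, 1 - 1e-6)
    return np.array([logit(r0), logit(ratio), np.log(l)])


class SpatialSynchrony:
    """Model object tying a descriptor panel to site geometry.

    Parameters
    ----------
    panel : PanelData
        Per-population descriptor series (normalisation is applied internally).
    geometry : SiteGeometry
        Coordinates and pairwise great-circle distances; must cover every
        panel population.
    l_bounds : (float, float)
        Search range for the spatial scale, km.
    """

    def __init__(self, panel: PanelData, geometry: SiteGeometry,
                 l_bounds: tuple = (1.0, 20000.0)):
        if panel.n_years_used < 1:
            raise ValueError("panel has no year with >= 2 observed populations")
        self.panel = panel
        self.geometry = geometry
        self.l_bounds = l_bounds
        self._packed = PackedPanel(panel, geometry)

    @classmethod
    def from_summaries(cls, summaries: pd.DataFrame, sites: pd.DataFrame,
                       descriptor: str = "prop_subadult",
                       years: tuple | None = None, **kw) -> "SpatialSynchrony":
        panel = PanelData.from_summaries(summaries, descriptor, years=years)
        return cls(panel, SiteGeometry.from_sites(sites), **kw)

    def loglike(self, params: SynchronyParams) -> float:
        return -nll_packed(params.rho0, params.rho_inf, params.l, self._packed)

    # -- fitting -----------------------------------------------------------

    def _minimise(self, theta0, y_flat=None, fast=False):
        packed = self._packed
        bounds = [(-_THETA_BOUND, _THETA_BOUND), (-_THETA_BOUND, _THETA_BOUND),
                  (np.log(self.l_bounds[0]), np.log(self.l_bounds[1]))]

        def nll(theta):
            r0, ri, l = _theta_to_params(theta, self.l_bounds)
            return nll_packed(r0, ri, l, packed, y_flat)

        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10 if not fast else 1e-8, "gtol": 1e-7,
                     "maxiter": 200 if not fast else 100},
        )
        return res

    def fit(self, n_starts: int = 8, seed: int | None = None,
            start: SynchronyParams | None = None) -> "SynchronyResults":
        """Maximum-likelihood fit with jittered multi-starts.

        ``seed`` controls the start jitter only; the likelihood itself is
        deterministic. A solution at the edge of the constrained domain is
        flagged, not an error.
        """
        rng = np.random.default_rng(seed)
        starts = []
        if start is not None:
            starts.append(_params_to_theta(start.rho0, start.rho_inf, start.l))
        base = _params_to_theta(0.3, 0.03, 600.0)
        starts.append(base)
        while len(starts) < n_starts:
            starts.append(np.array([
                logit(rng.uniform(0.05, 0.8)),
                logit(rng.uniform(0.02, 0.5)),
                np.log(np.exp(rng.uniform(np.log(50.0), np.log(5000.0)))),
            ]))
        best, traces = None, []
        for theta0 in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = self._minimise(theta0)
            traces.append(res)
            if res.fun < 1e11 and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError(f"all optimizer starts failed: {traces}")
        r0, ri, l = _theta_to_params(best.x, self.l_bounds)
        params = SynchronyParams(min(r0, 1 - 1e-9), min(ri, r0), l)
        at_boundary = bool(
            np.any(np.abs(best.x[:2]) > _THETA_BOUND - 0.5)
            or l <= self.l_bounds[0] * 1.01 or l >= self.l_bounds[1] * 0.99
        )
        return SynchronyResults(
            model=self, params=params, llf=-float(best.fun),
            converged=bool(best.success), at_boundary=at_boundary,
            n_years_used=self.panel.n_years_used,
            n_populations=self.panel.n_populations,
        )


@dataclass
class SynchronyResults:
    """Point estimates from :meth:`SpatialSynchrony.fit`."""

    model: SpatialSynchrony
    params: SynchronyParams
    llf: float
    converged: bool
    at_boundary: bool
    n_years_used: int
    n_populations: int

    def rho_at(self, distances=REFERENCE_DISTANCES) -> dict:
        """Plug-in synchrony at the given distances (km)."""
        return {float(d): float(rho(d, self.params)) for d in distances}

    def summary(self) -> str:
        p = self.params
        lines = [
            "Spatial synchrony fit (Gaussian distance decay, yearly MVN ML)",
            f"  populations: {self.n_populations}   years used: {self.n_years_used}",
            f"  log-likelihood: {self.llf:.3f}   converged: {self.converged}"
            + ("   [boundary]" if self.at_boundary else ""),
            f"  rho0    = {p.rho0:.3f}",
            f"  rho_inf = {p.rho_inf:.3f}",
            f"  l       = {p.l:.0f} km",
        ]
        for d, r in self.rho_at().items():
            lines.append(f"  rho({d:.0f} km) = {r:.3f} (plug-in)")
        return "\n".join(lines)

    # -- parametric bootstrap ---------------------------------------------

    def bootstrap(self, n_reps: int = 2000, seed: int | None = None,
                  reference_distances=REFERENCE_DISTANCES,
                  max_dropped_fraction: float = 0.05) -> "SynchronyBootstrapResults":
        """Parametric bootstrap of all reported quantities.

        Each replicate simulates every year's observed-population vector from
        MVN(0, Sigma_t) at the point estimate (independent years, observation
        pattern preserved), re-normalises per population, and refits starting
        from the point estimate plus one jittered start.
        """
        model = self.model
        panel = model.panel
        packed = model._packed
        rng = np.random.default_rng(seed)

        chols = []
        for pat, (pi, yc) in zip(panel.patterns, packed._placements):
            gi = model.geometry.index_of([panel.population_ids[i] for i in pi])
            d = model.geometry.distance_km[np.ix_(gi, gi)]
            sigma = rho(d, self.params)
            np.fill_diagonal(sigma, 1.0)
            chols.append(np.linalg.cholesky(sigma + 1e-10 * np.eye(len(pi))))

        theta_point = _params_to_theta(self.params.rho0, self.params.rho_inf, self.params.l)
        rows, n_dropped = [], 0
        dists = np.asarray(reference_distances, dtype=float)
        for _ in range(n_reps):
            sim = np.full(panel.values.shape, np.nan)
            for L, (pi, yc) in zip(chols, packed._placements):
                z = rng.standard_normal((len(pi), len(yc)))
                sim[np.ix_(pi, yc)] = L @ z
            norm = normalise_rows(sim)
            # a population with a single co-observed year cannot be
            # re-standardised; its simulated value is already N(0,1)
            single = (np.sum(~np.isnan(sim), axis=1) == 1)
            norm[single] = sim[single]
            y_flat = packed.refill(norm)
            try:
                res = model._minimise(theta_point, y_flat=y_flat, fast=True)
                jitter = theta_point + rng.normal(0.0, 0.5, size=3)
                res2 = model._minimise(jitter, y_flat=y_flat, fast=True)
                if res2.fun < res.fun:
                    res = res2
                if res.fun >= 1e11:
                    raise RuntimeError("replicate fit failed")
            except Exception:
                n_dropped += 1
                continue
            r0, ri, l = _theta_to_params(res.x, model.l_bounds)
            prm = SynchronyParams(min(r0, 1 - 1e-9), min(ri, r0), l)
            row = {"rho0": prm.rho0, "rho_inf": prm.rho_inf, "l": prm.l}
            for d, r in zip(dists, rho(dists, prm)):
                row[f"rho_{d:.0f}"] = float(r)
            rows.append(row)
        if n_reps and n_dropped > max_dropped_fraction * n_reps:
            logger.warning("%d/%d bootstrap replicates dropped", n_dropped, n_reps)
        reps = pd.DataFrame(rows)
        return SynchronyBootstrapResults(
            point=self, replicates=reps, n_requested=n_reps, n_dropped=n_dropped,
            reference_distances=tuple(float(d) for d in dists), seed=seed,
        )


@dataclass
class SynchronyBootstrapResults:
    """Bootstrap distributions, medians and 95% percentile intervals."""

    point: SynchronyResults
    replicates: pd.DataFrame
    n_requested: int
    n_dropped: int
    reference_distances: tuple
    seed: int | None = None
    _table: pd.DataFrame = field(default=None, repr=False)

    @property
    def params(self) -> SynchronyParams:
        return self.point.params

    def table(self) -> pd.DataFrame:
        """Median and 95% interval per reported quantity (one row each)."""
        if self._table is None:
            rows = []
            for col in self.replicates.columns:
                v = self.replicates[col].to_numpy()
                rows.append({
                    "parameter": col,
                    "median": float(np.median(v)),
                    "ci_low": float(np.percentile(v, 2.5)),
                    "ci_high": float(np.percentile(v, 97.5)),
                })
            self._table = pd.DataFrame(rows).set_index("parameter")
        return self._table

    def median(self, name: str) -> float:
        return float(self.table().loc[name, "median"])

    def conf_int(self, name: str) -> tuple:
        row = self.table().loc[name]
        return float(row["ci_low"]), float(row["ci_high"])

    def curve(self, distance_grid) -> pd.DataFrame:
        """Median synchrony and 95% band over a distance grid (km)."""
        grid = np.asarray(distance_grid, dtype=float)
        reps = self.replicates
        vals = (
            reps["rho_inf"].to_numpy()[:, None]
            + (reps["rho0"] - reps["rho_inf"]).to_numpy()[:, None]
            * np.exp(-(grid[None, :] ** 2) / (2.0 * reps["l"].to_numpy()[:, None] ** 2))
        )
        return pd.DataFrame({
            "distance_km": grid,
            "median": np.median(vals, axis=0),
            "ci_low": np.percentile(vals, 2.5, axis=0),
            "ci_high": np.percentile(vals, 97.5, axis=0),
        })

    def summary(self) -> str:
        lines = [
            "Spatial synchrony: parametric bootstrap "
            f"({len(self.replicates)} replicates, {self.n_dropped} dropped)",
            f"{'parameter':<12}{'median':>10}{'95% interval':>24}",
        ]
        for name, row in self.table().iterrows():
            lines.append(
                f"{name:<12}{row['median']:>10.3f}"
                f"      [{row['ci_low']:.3f}, {row['ci_high']:.3f}]"
            )
        p = self.point.params
        lines.append(
            f"point estimate: rho0={p.rho0:.3f} rho_inf={p.rho_inf:.3f} l={p.l:.0f} km"
        )
        return "\n".join(lines)


def pairwise_correlations(panel: PanelData) -> pd.DataFrame:
    """Pearson correlations per population pair over overlapping years,
    with the overlap-year count used as plotting weight."""
    from .geo import haversine_km  # noqa: F401  (distance added by caller)

    rows = []
    vals = panel.normalised
    for i in range(panel.n_populations):
        for j in range(i + 1, panel.n_populations):
            both = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            n = int(both.sum())
            if n < 3:
                continue
            r = float(np.corrcoef(vals[i, both], vals[j, both])[0, 1])
            rows.append({
                "population_a": panel.population_ids[i],
                "population_b": panel.population_ids[j],
                "correlation": r,
                "n_overlap_years": n,
            })
    return pd.DataFrame(rows)


def adjust_for_covariate(
    summaries: pd.DataFrame,
    covariate: pd.DataFrame,
    descriptor: str = "prop_subadult",
    min_obs: int = 3,
) -> PanelData:
    """Residualise the descriptor against a covariate before refitting.

    Per population, the descriptor is regressed on the covariate by ordinary
    least squares; the residuals are z-normalised within the population and
    become the new panel series. Years with a missing covariate drop out of
    that population's series. A population whose covariate is constant passes
    through un-adjusted (flagged in the log); one whose residuals are all
    (numerically) zero is dropped.

    ``covariate`` is long format: population_id, year, value.
    """
    df = summaries
    if "passes_filters" in df.columns:
        df = df[df["passes_filters"].astype(bool)]
    merged = df.merge(
        covariate.rename(columns={"value": "_cov"})[["population_id", "year", "_cov"]],
        on=["population_id", "year"], how="left",
    )
    merged = merged[merged[descriptor].notna() & merged["_cov"].notna()]

    pop_ids, series = [], {}
    for pop, grp in merged.groupby("population_id"):
        if len(grp) < min_obs:
            continue
        y = grp[descriptor].to_numpy(float)
        x = grp["_cov"].to_numpy(float)
        if np.std(x) == 0:
            logger.warning("covariate constant in %s; series passes through un-adjusted", pop)
            resid = y - y.mean()
        else:
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (intercept + slope * x)
        if np.allclose(resid, 0.0, atol=1e-12):
            logger.warning("degenerate residuals in %s; population dropped", pop)
            continue
        pop_ids.append(pop)
        series[pop] = dict(zip(grp["year"].astype(int), resid))

    years = sorted({yr for s in series.values() for yr in s})
    mat = np.full((len(pop_ids), len(years)), np.nan)
    ycol = {yr: k for k, yr in enumerate(years)}
    for i, pop in enumerate(pop_ids):
        for yr, v in series[pop].items():
            mat[i, ycol[yr]] = v
    return PanelData(pop_ids, np.asarray(years, int), mat)
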