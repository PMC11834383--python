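"""Orchestration: CSV inputs -> descriptor tables, covariates, model fits,
synchrony curves and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import CovariateConfig, build_covariates, covariates_wide
from .geo import SiteGeometry
from .mixed import fit_all_covariates
from .panel import PanelData
from .structure import DESCRIPTORS, StructureConfig, read_breeding_records, summarise_all
from .synchrony import (
    REFERENCE_DISTANCES,
    SpatialSynchrony,
    adjust_for_covariate,
    pairwise_correlations,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    records_csv: str | None = None
    summaries_csv: str | None = None          # alternative entry point
    sites_csv: str = ""
    daily_csv: str | None = None
    nests_csv: str | None = None
    mast_csv: str | None = None
    covariates_csv: str | None = None         # pre-built long covariates
    output_dir: str = "outputs"
    descriptor: str = "prop_subadult"
    covariate_names: list = field(default_factory=list)
    n_bootstrap: int = 2000
    seed: int = 1
    reference_distances: tuple = REFERENCE_DISTANCES
    year_range: tuple | None = None           # e.g. (2000, 2022)
    distance_grid_max_km: float = 4000.0
    structure: StructureConfig = field(default_factory=StructureConfig)
    covariate_config: CovariateConfig = field(default_factory=CovariateConfig)

    def __post_init__(self):
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.descriptor not in DESCRIPTORS:
            raise ValueError(f"unknown descriptor {self.descriptor!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        structure = StructureConfig(**raw.pop("structure", {}))
        cov = CovariateConfig(**raw.pop("covariate_config", {}))
        if "year_range" in raw and raw["year_range"] is not None:
            raw["year_range"] = tuple(raw["year_range"])
        return cls(structure=structure, covariate_config=cov, **raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in sorted(config.__dict__.items())}, sort_keys=True
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _bootstrap_report(boot, seed) -> dict:
    p = boot.point.params
    report = {
        "point": {"rho0": p.rho0, "rho_inf": p.rho_inf, "l_km": p.l,
                  "loglik": boot.point.llf, "at_boundary": boot.point.at_boundary},
        "plug_in_rho": {f"{d:.0f}km": v for d, v in boot.point.rho_at(
            boot.reference_distances).items()},
        "n_replicates": int(len(boot.replicates)),
        "n_dropped": int(boot.n_dropped),
        "n_years_used": boot.point.n_years_used,
        "n_populations": boot.point.n_populations,
        "seed": seed,
        "estimates": {},
    }
    for name, row in boot.table().iterrows():
        report["estimates"][name] = {
            "median": row["median"], "ci_low": row["ci_low"], "ci_high": row["ci_high"],
        }
    return report


def fit_and_bootstrap(panel: PanelData, geometry: SiteGeometry,
                      n_bootstrap: int, seed: int,
                      reference_distances=REFERENCE_DISTANCES):
    model = SpatialSynchrony(panel, geometry)
    res = model.fit(seed=seed)
    return res.bootstrap(n_reps=n_bootstrap, seed=seed,
                         reference_distances=reference_distances)


def make_figure_data(boot, distance_grid) -> dict:
    """Curve table (median + 95% band over the grid) and the pairwise
    Pearson-correlation scatter weighted by overlap years."""
    curve = boot.curve(distance_grid)
    scatter = pairwise_correlations(boot.point.model.panel)
    geom = boot.point.model.geometry
    if len(scatter):
        idx = {p: i for i, p in enumerate(geom.population_ids)}
        scatter["distance_km"] = [
            geom.distance_km[idx[a], idx[b]]
            for a, b in zip(scatter["population_a"], scatter["population_b"])
        ]
    return {"curve": curve, "pairwise": scatter}


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages: ingest (or load) summaries -> covariates -> one random-slope
    model per covariate -> raw synchrony fit + bootstrap -> covariate-adjusted
    synchrony fits -> figure data. Every output lands in ``output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "descriptor": config.descriptor,
        "stages": {},
    }

    # --- stage 1: annual summaries
    if config.summaries_csv:
        summaries = pd.read_csv(config.summaries_csv)
    else:
        records = read_breeding_records(config.records_csv)
        logger.info("ingest: %d capture records", len(records))
        summaries = summarise_all(records, config.structure)
    summaries.to_csv(out / "summaries.csv", index=False)
    manifest["stages"]["summaries"] = {
        "rows": int(len(summaries)),
        "rows_passing_filters": int(summaries["passes_filters"].astype(bool).sum()),
    }

    sites = pd.read_csv(config.sites_csv)
    geometry = SiteGeometry.from_sites(sites)

    # --- stage 2: covariates
    covariates = None
    if config.covariates_csv:
        covariates = pd.read_csv(config.covariates_csv)
    elif any([config.daily_csv, config.nests_csv, config.mast_csv]):
        years_by_pop = {
            pop: sorted(grp["year"].unique())
            for pop, grp in summaries.groupby("population_id")
        }
        covariates = build_covariates(
            sites, years_by_pop,
            daily=pd.read_csv(config.daily_csv) if config.daily_csv else None,
            nests=pd.read_csv(config.nests_csv) if config.nests_csv else None,
            mast=pd.read_csv(config.mast_csv) if config.mast_csv else None,
            config=config.covariate_config,
        )
    if covariates is not None:
        covariates.to_csv(out / "covariates.csv", index=False)
        manifest["stages"]["covariates"] = {"rows": int(len(covariates))}

    # --- stage 3: mixed models, one per covariate
    if covariates is not None:
        wide = covariates_wide(covariates)
        names = config.covariate_names or None
        mixed_table = fit_all_covariates(summaries, wide, config.descriptor, names)
        mixed_table.to_csv(out / "mixed_models.csv", index=False)
        manifest["stages"]["mixed_models"] = {"fits": int(len(mixed_table))}

    # --- stage 4: raw synchrony
    panel = PanelData.from_summaries(summaries, config.descriptor,
                                     years=config.year_range)
    boot = fit_and_bootstrap(panel, geometry, config.n_bootstrap,
                             int(rng.integers(2 ** 31)),
                             config.reference_distances)
    report = _bootstrap_report(boot, config.seed)
    (out / "synchrony_fit.json").write_text(json.dumps(report, indent=2))
    boot.replicates.to_csv(out / "synchrony_bootstrap.csv", index=False)
    manifest["stages"]["synchrony"] = {
        "n_years_used": boot.point.n_years_used,
        "n_populations": boot.point.n_populations,
        "n_replicates": int(len(boot.replicates)),
    }

    grid = np.linspace(0.0, config.distance_grid_max_km, 101)
    fig = make_figure_data(boot, grid)
    fig["curve"].to_csv(out / "synchrony_curve.csv", index=False)
    fig["pairwise"].to_csv(out / "pairwise_correlations.csv", index=False)

    # --- stage 5: covariate-adjusted synchrony
    if covariates is not None:
        adjusted = {}
        names = config.covariate_names or sorted(covariates["name"].unique())
        for name in names:
            cov = covariates[covariates["name"] == name]
            if cov["value"].notna().sum() < 10:
                continue
            try:
                adj_panel = adjust_for_covariate(summaries, cov, config.descriptor)
                if config.year_range:
                    adj_panel = adj_panel.filter_years(*config.year_range)
                adj_boot = fit_and_bootstrap(
                    adj_panel, geometry, config.n_bootstrap,
                    int(rng.integers(2 ** 31)), config.reference_distances,
                )
            except (ValueError, RuntimeError) as err:
                logger.warning("adjusted fit for %s failed: %s", name, err)
                continue
            adjusted[name] = _bootstrap_report(adj_boot, config.seed)
            adj_boot.curve(grid).to_csv(out / f"synchrony_curve_adj_{name}.csv", index=False)
        (out / "synchrony_adjusted.json").write_text(json.dumps(adjusted, indent=2))
        manifest["stages"]["adjusted_synchrony"] = {"fits": sorted(adjusted)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
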