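import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from demosync import (
    PanelData,
    SiteGeometry,
    SpatialSynchrony,
    SynchronyParams,
    adjust_for_covariate,
    build_sigma,
    log_likelihood,
    pairwise_correlations,
    rho,
)


def _geometry(n, seed=0):
    rng = np.random.default_rng(seed)
    return SiteGeometry([f"p{i}" for i in range(n)],
                        rng.uniform(35, 65, n), rng.uniform(-4, 33, n))


def _panel_raw(values, geometry):
    """Panel whose values are used as-is (already standardised)."""
    values = np.asarray(values, dtype=float)
    return PanelData([*geometry.population_ids[:values.shape[0]]],
                     np.arange(2000, 2000 + values.shape[1]),
                     values, normalised=values)


class TestRho:
    def test_at_zero_equals_rho0(self):
        p = SynchronyParams(0.6, 0.1, 200.0)
        assert rho(0.0, p) == pytest.approx(0.6)

    def test_limit_at_infinity_is_rho_inf(self):
        p = SynchronyParams(0.6, 0.1, 200.0)
        assert rho(1e7, p) == pytest.approx(0.1)

    @given(
        rho0=st.floats(0.01, 0.95), ratio=st.floats(0.0, 1.0),
        l=st.floats(10.0, 5000.0),
    )
    def test_non_increasing_and_bounded(self, rho0, ratio, l):
        p = SynchronyParams(rho0, rho0 * ratio, l)
        d = np.linspace(0, 10000, 200)
        r = rho(d, p)
        assert np.all(np.diff(r) <= 1e-15)
        assert np.all((r >= p.rho_inf - 1e-12) & (r <= p.rho0 + 1e-12))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SynchronyParams(0.3, 0.4, 100.0)   # rho_inf > rho0
        with pytest.raises(ValueError):
            SynchronyParams(1.0, 0.0, 100.0)   # rho0 must be < 1
        with pytest.raises(ValueError):
            SynchronyParams(0.3, 0.1, 0.0)     # l must be positive


class TestBuildSigma:
    def test_zero_correlation_gives_identity(self):
        geom = _geometry(4)
        sigma = build_sigma(geom.population_ids, geom, SynchronyParams(0.0, 0.0, 100.0))
        assert np.allclose(sigma, np.eye(4))

    def test_two_populations_closed_form(self):
        geom = _geometry(2)
        p = SynchronyParams(0.5, 0.1, 800.0)
        sigma = build_sigma(geom.population_ids, geom, p)
        expected = rho(geom.distance_km[0, 1], p)
        assert sigma[0, 1] == pytest.approx(expected)
        assert sigma[0, 0] == sigma[1, 1] == 1.0

    def test_elementwise_oracle_and_positive_definite(self):
        geom = _geometry(5, seed=3)
        p = SynchronyParams(0.7, 0.2, 400.0)
        sigma = build_sigma(geom.population_ids, geom, p)
        for i in range(5):
            for j in range(5):
                expected = 1.0 if i == j else rho(geom.distance_km[i, j], p)
                assert sigma[i, j] == pytest.approx(expected)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)


class TestLogLikelihood:
    def test_independent_standard_normals_closed_form(self):
        geom = _geometry(2)
        panel = _panel_raw([[0.0], [0.0]], geom)
        ll = log_likelihood(SynchronyParams(0.0, 0.0, 100.0), panel, geom)
        assert ll == pytest.approx(-np.log(2 * np.pi))

    def test_bivariate_closed_form(self):
        geom = _geometry(2, seed=1)
        y1, y2 = 0.7, -1.2
        panel = _panel_raw([[y1], [y2]], geom)
        p = SynchronyParams(0.6, 0.0, 500.0)
        r = rho(geom.distance_km[0, 1], p)
        expected = multivariate_normal([0, 0], [[1, r], [r, 1]]).logpdf([y1, y2])
        assert log_likelihood(p, panel, geom) == pytest.approx(expected, abs=1e-10)

    def test_kernel_equals_reference_and_quadratic_form(self):
        rng = np.random.default_rng(7)
        geom = _geometry(5, seed=7)
        values = rng.standard_normal((5, 3))
        values[0, 2] = np.nan  # irregular observation
        panel = _panel_raw(values, geom)
        p = SynchronyParams(0.45, 0.05, 700.0)
        ll_kernel = log_likelihood(p, panel, geom, method="kernel")
        ll_ref = log_likelihood(p, panel, geom, method="reference")
        assert ll_kernel == pytest.approx(ll_ref, abs=1e-8)
        # explicit-inverse quadratic form, year by year
        expected = 0.0
        for t in range(3):
            idx = np.flatnonzero(~np.isnan(values[:, t]))
            sigma = build_sigma([geom.population_ids[i] for i in idx], geom, p)
            y = values[idx, t]
            expected += (
                -0.5 * (len(idx) * np.log(2 * np.pi)
                        + np.log(np.linalg.det(sigma))
                        + y @ np.linalg.inv(sigma) @ y)
            )
        assert ll_kernel == pytest.approx(expected, abs=1e-8)

    def test_identity_params_equal_sum_of_univariate_densities(self):
        rng = np.random.default_rng(8)
        geom = _geometry(4, seed=8)
        values = rng.standard_normal((4, 6))
        panel = _panel_raw(values, geom)
        ll = log_likelihood(SynchronyParams(0.0, 0.0, 100.0), panel, geom)
        expected = np.sum(-0.5 * (np.log(2 * np.pi) + values ** 2))
        assert ll == pytest.approx(expected, abs=1e-8)


class TestFit:
    def test_relabelling_and_unobserved_population_invariance(self, small_sim):
        res = SpatialSynchrony(small_sim.panel, small_sim.geometry).fit(seed=0)
        # permute population order in the panel
        perm = np.array([3, 1, 5, 0, 4, 2])
        panel2 = PanelData(
            [small_sim.panel.population_ids[i] for i in perm],
            small_sim.panel.years, small_sim.panel.values[perm],
        )
        res2 = SpatialSynchrony(panel2, small_sim.geometry).fit(seed=0)
        assert res2.params.rho0 == pytest.approx(res.params.rho0, abs=1e-4)
        assert res2.params.l == pytest.approx(res.params.l, rel=1e-3)
        # an extra never-observed population changes nothing
        geom3 = SiteGeometry(
            small_sim.geometry.population_ids + ["ghost"],
            np.append(small_sim.geometry.latitude, 50.0),
            np.append(small_sim.geometry.longitude, 10.0),
        )
        res3 = SpatialSynchrony(small_sim.panel, geom3).fit(seed=0)
        assert res3.params.rho0 == pytest.approx(res.params.rho0, abs=1e-6)

    def test_perfectly_synchronous_panel_hits_upper_boundary(self):
        geom = _geometry(5, seed=2)
        series = np.random.default_rng(0).standard_normal(25)
        panel = PanelData(geom.population_ids, np.arange(2000, 2025),
                          np.tile(series, (5, 1)))
        res = SpatialSynchrony(panel, geom).fit(seed=0)
        assert res.params.rho0 > 0.95
        assert res.at_boundary

    def test_white_noise_panel_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        geom = _geometry(10, seed=3)
        panel = PanelData(geom.population_ids, np.arange(1950, 2010),
                          rng.standard_normal((10, 60)))
        res = SpatialSynchrony(panel, geom).fit(seed=0)
        assert res.params.rho0 < 0.1

    def test_deterministic_given_seed(self, small_sim):
        a = SpatialSynchrony(small_sim.panel, small_sim.geometry).fit(seed=9)
        b = SpatialSynchrony(small_sim.panel, small_sim.geometry).fit(seed=9)
        assert a.params.as_array() == pytest.approx(b.params.as_array())


class TestBootstrap:
    def test_smoke_two_replicates(self, small_sim):
        res = SpatialSynchrony(small_sim.panel, small_sim.geometry).fit(seed=0)
        boot = res.bootstrap(n_reps=2, seed=0)
        assert len(boot.replicates) == 2

    def test_reproducible_and_medians_inside_intervals(self, small_sim):
        res = SpatialSynchrony(small_sim.panel, small_sim.geometry).fit(seed=0)
        a = res.bootstrap(n_reps=40, seed=5)
        b = res.bootstrap(n_reps=40, seed=5)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        for name, row in a.table().iterrows():
            assert row["ci_low"] <= row["median"] <= row["ci_high"]

    def test_reference_distance_rhos_monotone_per_replicate(self, small_sim):
        res = SpatialSynchrony(small_sim.panel, small_sim.geometry).fit(seed=0)
        boot = res.bootstrap(n_reps=25, seed=2)
        d = boot.replicates[["rho_100", "rho_500", "rho_1000", "rho_2500"]].to_numpy()
        assert np.all(np.diff(d, axis=1) <= 1e-12)

    def test_curve_matches_bruteforce_percentiles(self, small_sim):
        res = SpatialSynchrony(small_sim.panel, small_sim.geometry).fit(seed=0)
        boot = res.bootstrap(n_reps=30, seed=3)
        grid = np.array([0.0, 250.0, 900.0])
        curve = boot.curve(grid)
        reps = boot.replicates
        for gi, d in enumerate(grid):
            vals = [
                rho(d, SynchronyParams(r.rho0, min(r.rho_inf, r.rho0), r.l))
                for r in reps.itertuples()
            ]
            assert curve["median"].iloc[gi] == pytest.approx(np.median(vals))
            assert curve["ci_low"].iloc[gi] == pytest.approx(np.percentile(vals, 2.5))
        # at d=0 the curve median is the bootstrap median of rho0
        assert curve["median"].iloc[0] == pytest.approx(boot.median("rho0"))


class TestAdjustForCovariate:
    def _summaries(self, panel):
        rows = []
        for i, pop in enumerate(panel.population_ids):
            for t, year in enumerate(panel.years):
                v = panel.values[i, t]
                if np.isfinite(v):
                    rows.append({"population_id": pop, "year": int(year),
                                 "prop_subadult": v, "passes_filters": True})
        return pd.DataFrame(rows)

    def test_uncorrelated_covariate_leaves_series_nearly_unchanged(self, small_sim):
        summ = self._summaries(small_sim.panel)
        rng = np.random.default_rng(0)
        cov = summ[["population_id", "year"]].copy()
        cov["value"] = rng.standard_normal(len(cov))
        adj = adjust_for_covariate(summ, cov)
        raw = small_sim.panel
        for i, pop in enumerate(adj.population_ids):
            j = raw.population_ids.index(pop)
            both = ~np.isnan(adj.normalised[i])
            r = np.corrcoef(adj.normalised[i][both],
                            raw.normalised[j][~np.isnan(raw.normalised[j])])[0, 1]
            assert r > 0.9

    def test_perfect_fit_population_dropped(self, small_sim):
        summ = self._summaries(small_sim.panel)
        cov = summ[["population_id", "year"]].copy()
        cov["value"] = summ["prop_subadult"]  # descriptor == covariate
        adj = adjust_for_covariate(summ, cov)
        assert adj.n_populations == 0

    def test_constant_covariate_passes_through(self, small_sim, caplog):
        summ = self._summaries(small_sim.panel)
        cov = summ[["population_id", "year"]].copy()
        cov["value"] = 1.0
        with caplog.at_level("WARNING"):
            adj = adjust_for_covariate(summ, cov)
        assert adj.n_populations == small_sim.panel.n_populations
        assert "un-adjusted" in caplog.text


def test_pairwise_correlations_shape_and_weights(small_sim):
    pc = pairwise_correlations(small_sim.panel)
    assert {"population_a", "population_b", "correlation", "n_overlap_years"} <= set(pc)
    assert (pc["n_overlap_years"] >= 3).all()
    assert pc["correlation"].between(-1, 1).all()
    expected = small_sim.panel.overlap_years()
    ids = small_sim.panel.population_ids
    for row in pc.itertuples():
        i, j = ids.index(row.population_a), ids.index(row.population_b)
        assert row.n_overlap_years == expected[i, j]
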