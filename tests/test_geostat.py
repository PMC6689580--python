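import numpy as np
import pandas as pd
import pytest

import vaquitrend as vt
from vaquitrend.geostat import GeostatParams


class TestLogTransform:
    @pytest.mark.parametrize(
        "w,expected",
        [(0.0, 0.0), (np.e - 1.0, 1.0), (4.37, np.log(5.37))],
    )
    def test_values(self, w, expected):
        assert vt.log_transform(w) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            vt.log_transform(-0.1)

    def test_strictly_increasing(self):
        w = np.linspace(0, 50, 200)
        assert np.all(np.diff(vt.log_transform(w)) > 0)


class TestCorrelationMatrix:
    def test_closed_form(self):
        h = np.array([[0.0, 10.0], [10.0, 0.0]])
        r = vt.correlation_matrix(h, rho=10.0)
        assert r[0, 0] == 1.0 and r[1, 1] == 1.0
        assert r[0, 1] == pytest.approx(np.exp(-3.0))  # ~0.049787 at h = rho

    def test_large_range_limit(self):
        h = np.array([[0.0, 2.0], [2.0, 0.0]])
        r = vt.correlation_matrix(h, rho=1e9)
        assert r[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_positive_definite_on_grid(self, small_truth):
        grid = vt.simulate_grid(small_truth)
        r = vt.correlation_matrix(grid, rho=5.0)
        assert np.allclose(r, r.T)
        assert np.min(np.linalg.eigvalsh(r)) > 0

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            vt.correlation_matrix(np.zeros((2, 2)), rho=0.0)

    def test_duplicate_coordinates_warn(self):
        grid = vt.SiteGrid(site_ids=(1, 2), coords_km=np.zeros((2, 2)))
        with pytest.warns(UserWarning, match="duplicated"):
            vt.correlation_matrix(grid, rho=1.0)


class TestLogPosterior:
    def test_finite_for_valid_params(self, toy_dataset):
        params = GeostatParams(
            mu=np.array([1.0, 0.5]),
            Z=np.zeros((2, 2)),
            sigma2_eps=0.3,
            sigma2_z=0.5,
            rho=8.0,
        )
        assert np.isfinite(vt.log_posterior(params, toy_dataset))

    def test_precision_weighting(self, toy_grid):
        # with Y exactly at mu + Z, more sampling days means higher density
        base = pd.DataFrame(
            {"year": [2011, 2011], "site_id": [1, 2], "W": [np.e - 1.0] * 2, "n": [10, 10]}
        )
        heavy = base.assign(n=[20, 20])
        params = GeostatParams(
            mu=np.array([1.0]), Z=np.zeros((1, 2)), sigma2_eps=0.3, sigma2_z=0.5, rho=8.0
        )
        lp_base = vt.log_posterior(params, vt.MonitoringDataset(toy_grid, base))
        lp_heavy = vt.log_posterior(params, vt.MonitoringDataset(toy_grid, heavy))
        assert lp_heavy > lp_base

    def test_single_observation_posterior_matches_quadrature(self, toy_grid):
        # 1-site, 1-year toy with fixed variances: grid quadrature over
        # (mu, Z) is an independent oracle for the posterior mean of mu
        grid1 = vt.SiteGrid(site_ids=(1,), coords_km=np.array([[0.0, 0.0]]))
        y_obs, n_obs = 1.2, 25
        summ = pd.DataFrame(
            {"year": [2011], "site_id": [1], "W": [np.expm1(y_obs)], "n": [n_obs]}
        )
        ds = vt.MonitoringDataset(grid1, summ)
        s2e, s2z, v0 = 0.4, 0.3, 25.0

        mu_grid = np.linspace(-6, 8, 281)
        z_grid = np.linspace(-4, 4, 161)
        mm, zz = np.meshgrid(mu_grid, z_grid, indexing="ij")
        log_dens = (
            -0.5 * (y_obs - mm - zz) ** 2 / (s2e / n_obs)
            - 0.5 * zz**2 / s2z
            - 0.5 * mm**2 / v0
        )
        dens = np.exp(log_dens - log_dens.max())
        oracle_mu = float(np.sum(mm * dens) / np.sum(dens))

        with pytest.warns(UserWarning, match="single year"):
            draws = vt.fit(
                ds,
                vt.PriorSpec(mu_var=v0),
                vt.MCMCConfig(n_burn=300, n_keep=3000, thin=1, seed=3),
                fixed={"sigma2_eps": s2e, "sigma2_z": s2z, "rho": 1.0},
                check_convergence=False,
            )
        assert draws.mu[:, 0].mean() == pytest.approx(oracle_mu, abs=0.05)


class TestFit:
    def test_seeded_determinism(self, toy_dataset):
        cfg = vt.MCMCConfig(n_burn=100, n_keep=200, thin=1, seed=11)
        a = vt.fit(toy_dataset, config=cfg, check_convergence=False)
        b = vt.fit(toy_dataset, config=cfg, check_convergence=False)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.Z, b.Z)
        assert np.array_equal(a.rho, b.rho)

    def test_fixed_parameters_are_pinned(self, toy_dataset):
        draws = vt.fit(
            toy_dataset,
            config=vt.MCMCConfig(n_burn=50, n_keep=100, thin=1, seed=0),
            fixed={"sigma2_eps": 0.25, "rho": 6.0},
            check_convergence=False,
        )
        assert np.all(draws.sigma2_eps == 0.25)
        assert np.all(draws.rho == 6.0)
        assert np.std(draws.sigma2_z) > 0

    def test_site_exchangeability(self, small_dataset, small_truth, short_config):
        # permuting site labels and coordinates together leaves posterior
        # year-mean summaries unchanged up to Monte-Carlo error (variance
        # parameters pinned so the comparison is on the Gaussian layer)
        dataset, _ = small_dataset
        fixed = {"sigma2_eps": small_truth.sigma2_eps,
                 "sigma2_z": small_truth.sigma2_z, "rho": small_truth.rho}
        draws = vt.fit(dataset, config=short_config, fixed=fixed,
                       check_convergence=False)

        perm = np.arange(dataset.grid.n_sites)[::-1]
        grid_p = vt.SiteGrid(
            site_ids=tuple(dataset.grid.site_ids[i] for i in perm),
            coords_km=dataset.grid.coords_km[perm],
        )
        ds_p = vt.MonitoringDataset(grid_p, dataset.summaries, dataset.core_window)
        draws_p = vt.fit(ds_p, config=short_config, fixed=fixed,
                         check_convergence=False)
        np.testing.assert_allclose(
            draws.mu.mean(axis=0), draws_p.mu.mean(axis=0), atol=0.05
        )

    def test_doubled_effort_tightens_year_means(self, small_dataset, small_truth,
                                                short_config):
        # halving the observation variance (doubled sampling days) must
        # narrow the year-mean credible intervals
        dataset, _ = small_dataset
        fixed = {"sigma2_eps": small_truth.sigma2_eps,
                 "sigma2_z": small_truth.sigma2_z, "rho": small_truth.rho}
        doubled = vt.MonitoringDataset(
            dataset.grid,
            dataset.summaries.assign(n=dataset.summaries["n"] * 2),
            dataset.core_window,
        )
        base = vt.fit(dataset, config=short_config, fixed=fixed,
                      check_convergence=False)
        tight = vt.fit(doubled, config=short_config, fixed=fixed,
                       check_convergence=False)

        def cri_width(d):
            lo, hi = np.quantile(d.mu, [0.025, 0.975], axis=0)
            return hi - lo

        assert cri_width(tight).mean() < cri_width(base).mean()

    def test_missing_site_years_get_spatial_field_values(self, fitted):
        dataset, realization, draws = fitted
        missing = realization.n_days_sampled == 0
        assert missing.any()
        # Z is drawn for every site every year, including unobserved ones
        assert np.all(np.std(draws.Z, axis=0)[missing] > 0)

    def test_draws_serialize_roundtrip(self, fitted, tmp_path):
        _, _, draws = fitted
        path = tmp_path / "draws.csv"
        draws.write_csv(path, tmp_path / "meta.json")
        back = vt.PosteriorDraws.from_frame(pd.read_csv(path))
        np.testing.assert_allclose(back.mu, draws.mu)
        np.testing.assert_allclose(back.Z, draws.Z)
        assert back.years == draws.years


class TestPriorSensitivity:
    def test_unit_widen_factor_reproduces_fit(self, toy_dataset):
        cfg = vt.MCMCConfig(n_burn=100, n_keep=300, thin=1, seed=5)
        report = vt.rerun_with_wider_priors(toy_dataset, vt.PriorSpec(), cfg, 1.0)
        assert report["max_abs_diff_lambda"] == 0.0

    def test_data_dominates_under_wider_priors(self, small_dataset, short_config):
        dataset, _ = small_dataset
        report = vt.rerun_with_wider_priors(dataset, vt.PriorSpec(), short_config, 10.0)
        # posterior-mean lambda shifts stay within Monte-Carlo noise
        assert report["max_abs_diff_lambda"] < 0.1
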