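import numpy as np
import pytest
from hypothesis import given, strategies as st

import vaquitrend as vt


@pytest.fixture(scope="module")
def simple_streams():
    rng = np.random.default_rng(0)
    return {
        (2015, 2016): rng.lognormal(-0.9, 0.4, 4000),
        (2016, 2017): rng.lognormal(-0.7, 0.4, 4000),
        (2017, 2018): rng.lognormal(-0.7, 0.4, 4000),
    }


@pytest.fixture(scope="module")
def trajectories(simple_streams):
    prior = vt.lognormal_from_moments(66.0, 33.0)
    return vt.project(prior, simple_streams, seed=1)


class TestLognormalFromMoments:
    def test_moment_matching_reproduces_inputs(self):
        prior = vt.lognormal_from_moments(66.0, 33.0)
        d = prior.distribution
        assert d.mean() == pytest.approx(66.0, rel=1e-9)
        assert d.std() == pytest.approx(33.0, rel=1e-9)

    def test_median_closed_form(self):
        prior = vt.lognormal_from_moments(66.0, 33.0)
        assert prior.median == pytest.approx(66.0 / np.sqrt(1.25), rel=1e-12)
        assert round(prior.median) == 59

    def test_sampler_matches_moments(self):
        prior = vt.lognormal_from_moments(66.0, 33.0)
        x = prior.sample(200_000, np.random.default_rng(2))
        assert x.mean() == pytest.approx(66.0, rel=0.02)
        assert x.std() == pytest.approx(33.0, rel=0.05)

    def test_vanishing_sd_concentrates_at_mean(self):
        prior = vt.lognormal_from_moments(66.0, 1e-6)
        assert prior.median == pytest.approx(66.0, rel=1e-9)
        assert prior.sigma_log < 1e-7

    def test_invalid_moments_rejected(self):
        with pytest.raises(ValueError):
            vt.lognormal_from_moments(-1.0, 5.0)
        with pytest.raises(ValueError):
            vt.lognormal_from_moments(10.0, 0.0)


class TestProject:
    def test_unit_lambda_preserves_prior(self):
        prior = vt.lognormal_from_moments(66.0, 33.0)
        ones = {(2015, 2016): np.ones(1000), (2016, 2017): np.ones(1000),
                (2017, 2018): np.ones(1000)}
        traj = vt.project(prior, ones, seed=3)
        np.testing.assert_array_equal(traj.abundance(2018), traj.abundance(2015))

    def test_constant_halving(self):
        prior = vt.lognormal_from_moments(66.0, 33.0)
        halves = {(y, y + 1): np.full(500, 0.5) for y in (2015, 2016, 2017)}
        traj = vt.project(prior, halves, seed=4)
        np.testing.assert_allclose(
            traj.abundance(2018), traj.abundance(2015) / 8.0, rtol=1e-12
        )

    def test_multiplicative_consistency_per_trajectory(self, trajectories):
        t = trajectories.table
        expected = (
            t["N_2015"] * t["lambda_2015_2016"] * t["lambda_2016_2017"]
            * t["lambda_2017_2018"]
        )
        np.testing.assert_allclose(t["N_2018"], expected, rtol=1e-12)

    def test_stream_length_mismatch_rejected(self):
        prior = vt.lognormal_from_moments(66.0, 33.0)
        streams = {(2015, 2016): np.ones(100), (2016, 2017): np.ones(99)}
        with pytest.raises(ValueError, match="mismatch"):
            vt.project(prior, streams)

    def test_non_chaining_pairs_rejected(self):
        prior = vt.lognormal_from_moments(66.0, 33.0)
        streams = {(2015, 2016): np.ones(10), (2017, 2018): np.ones(10)}
        with pytest.raises(ValueError, match="chain"):
            vt.project(prior, streams)


class TestMinimumCounts:
    def test_zero_minimums_retain_everything(self, trajectories):
        updated = vt.apply_minimum_counts(trajectories, {2017: 0, 2018: 0})
        assert updated.n_retained == updated.n_trajectories
        for year in trajectories.years:
            a = vt.summarize_abundance(trajectories, year)
            b = vt.summarize_abundance(updated, year)
            assert a == b

    def test_impossible_minimum_raises(self, trajectories):
        huge = int(trajectories.table["N_2018"].max()) + 10
        with pytest.raises(ValueError, match="no trajectories"):
            vt.apply_minimum_counts(trajectories, {2018: huge})

    def test_retained_trajectories_respect_minimums(self, trajectories):
        updated = vt.apply_minimum_counts(trajectories, {2017: 7, 2018: 6})
        kept = updated.table[updated.table["retained"]]
        assert (kept["N_2017"] >= 7).all() and (kept["N_2018"] >= 6).all()
        assert 0 < updated.n_retained < updated.n_trajectories

    @given(minimum=st.integers(min_value=0, max_value=12))
    def test_truncation_monotonicity(self, trajectories, minimum):
        # raising a minimum count never decreases any post-update mean
        lo = vt.apply_minimum_counts(trajectories, {2018: minimum})
        hi = vt.apply_minimum_counts(trajectories, {2018: minimum + 2})
        for year in trajectories.years:
            assert (
                vt.summarize_abundance(hi, year)["mean"]
                >= vt.summarize_abundance(lo, year)["mean"] - 1e-9
            )

    def test_rounding_modes(self, trajectories):
        ceil = vt.apply_minimum_counts(trajectories, {2018: 6}, rounding="ceil")
        floor = vt.apply_minimum_counts(trajectories, {2018: 6}, rounding="floor")
        # ceil(N) >= 6 is weaker than floor(N) >= 6
        assert ceil.n_retained >= floor.n_retained
        with pytest.raises(ValueError, match="rounding"):
            vt.apply_minimum_counts(trajectories, {2018: 6}, rounding="round")

    def test_rejection_equals_importance_weighting(self, trajectories):
        # 0/1-importance-weighted summaries on the full set are an
        # independent oracle for the rejection summaries
        updated = vt.apply_minimum_counts(trajectories, {2017: 7, 2018: 6})
        n_all = trajectories.table["N_2018"].to_numpy()
        w = (
            (trajectories.table["N_2017"].to_numpy() >= 7)
            & (trajectories.table["N_2018"].to_numpy() >= 6)
        ).astype(float)
        oracle_mean = np.sum(w * n_all) / np.sum(w)
        s = vt.summarize_abundance(updated, 2018)
        assert s["mean"] == pytest.approx(oracle_mean, rel=1e-12)
        assert s["n_trajectories"] == int(w.sum())


class TestSummaries:
    def test_degenerate_draws(self):
        prior = vt.lognormal_from_moments(50.0, 1e-9)
        streams = {(2015, 2016): np.ones(100)}
        traj = vt.project(prior, streams, seed=5)
        s = vt.summarize_abundance(traj, 2016)
        assert s["mean"] == pytest.approx(s["median"], rel=1e-6)
        assert s["cri_high"] - s["cri_low"] == pytest.approx(0.0, abs=1e-4)

    def test_abundance_table_covers_all_years(self, trajectories):
        table = vt.abundance_table(trajectories)
        assert table["year"].tolist() == trajectories.years


class TestUpdatedTrendTable:
    def test_no_truncation_identical_to_pre_update(self, fitted):
        _, _, draws = fitted
        b = vt.compute_B(draws)
        years = draws.years
        streams = {
            (t1, t2): vt.compute_lambda(b, years, t1, t2).draws
            for t1, t2 in zip(years[:-1], years[1:])
        }
        prior = vt.lognormal_from_moments(66.0, 33.0)
        traj = vt.project(prior, streams, seed=6)
        zeros = {years[-1]: 0}
        updated = vt.apply_minimum_counts(traj, zeros)
        before = vt.trend_table(draws)
        after = vt.updated_trend_table(draws, updated)
        assert before.equals(after)

    def test_misaligned_draws_rejected(self, fitted, trajectories):
        _, _, draws = fitted
        with pytest.raises(ValueError, match="aligned"):
            vt.updated_trend_table(draws, trajectories)
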