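"""Hierarchical Bernoulli/logit model: likelihood, sampler, post-processing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from yearlings import hier_model
from yearlings.hier_model import ModelData, Priors
import oracles


def toy_data(n=30, alpha=0.3, beta=-1.2, seed=0, evi_sd=1.0, missing=0):
    rng = np.random.default_rng(seed)
    evi = rng.normal(0, evi_sd, n)
    y = (rng.random(n) < expit(alpha + beta * evi)).astype(float)
    if missing:
        y[rng.choice(n, missing, replace=False)] = np.nan
    return ModelData(y=y, species_idx=np.zeros(n, dtype=np.int64),
                     evi=evi - evi.mean(), species_codes=["SP01"],
                     evi_center=float(evi.mean()))


class TestBuildModelData:
    def _frames(self):
        inds = pd.DataFrame({
            "band_id": ["B1", "B2", "B3", "B4"],
            "species_code": ["TEWA", "TEWA", "TEWA", "OVEN"],
            "station_id": ["S1", "S2", "S1", "S3"],
            "year": [2012, 2012, 2013, 2012],
            "resolved_age": ["SY", "ASY", "AHY", "SY"]})
        evi = pd.DataFrame({
            "station_id": ["S1", "S2", "S1"],
            "year": [2012, 2012, 2013],
            "evi": [0.5, 0.3, 0.4]})
        return inds, evi

    def test_outcome_coding(self):
        inds, evi = self._frames()
        data = hier_model.build_model_data(inds.iloc[:3], evi)
        assert data.y[0] == 1.0 and data.y[1] == 0.0
        assert np.isnan(data.y[2])

    def test_covariate_centered(self):
        inds, evi = self._frames()
        data = hier_model.build_model_data(inds.iloc[:3], evi)
        assert abs(data.evi.mean()) < 1e-9

    def test_rows_without_covariate_dropped_and_counted(self):
        inds, evi = self._frames()
        data = hier_model.build_model_data(inds, evi)  # S3/2012 has no EVI
        assert data.y.size == 3
        assert data.n_dropped_no_covariate == 1

    def test_target_species_restriction(self):
        inds, evi = self._frames()
        data = hier_model.build_model_data(inds, evi,
                                           target_species=["TEWA"])
        assert data.species_codes == ["TEWA"]


class TestLogPosterior:
    def test_single_observation_half_probability(self):
        base = ModelData(y=np.array([], float),
                         species_idx=np.array([], np.int64),
                         evi=np.array([], float), species_codes=["A"],
                         evi_center=0.0)
        one = ModelData(y=np.array([1.0]),
                        species_idx=np.array([0], np.int64),
                        evi=np.array([0.37]), species_codes=["A"],
                        evi_center=0.0)
        args = dict(mu_alpha=0, mu_beta=0, sigma_alpha=1, sigma_beta=1,
                    alpha=[0.0], beta=[0.0])
        diff = (hier_model.log_unnormalized_posterior(one, **args)
                - hier_model.log_unnormalized_posterior(base, **args))
        assert diff == pytest.approx(math.log(0.5), abs=1e-12)

    def test_likelihood_limit_at_certainty(self):
        n = 5
        data = ModelData(y=np.ones(n),
                         species_idx=np.zeros(n, np.int64),
                         evi=np.zeros(n), species_codes=["A"],
                         evi_center=0.0)
        args = dict(mu_alpha=0, mu_beta=0, sigma_alpha=10, sigma_beta=10)
        lp_small = hier_model.log_unnormalized_posterior(
            data, alpha=[2.0], beta=[0.0], **args)
        lp_big = hier_model.log_unnormalized_posterior(
            data, alpha=[20.0], beta=[0.0], **args)
        # likelihood term rises toward 0 as alpha -> +inf (priors aside)
        prior = lambda a: oracles._norm_logpdf(a, 0, 10)
        assert (lp_big - prior(20.0)) > (lp_small - prior(2.0))
        assert (lp_big - prior(20.0) - prior(0) - 2 * prior(0)) < 0

    def test_matches_independent_scalar_sum(self):
        rng = np.random.default_rng(13)
        n, J = 10, 3
        data = ModelData(
            y=np.array([1, 0, 1, np.nan, 0, 1, 1, 0, np.nan, 1], float),
            species_idx=rng.integers(0, J, n).astype(np.int64),
            evi=rng.normal(0, 0.1, n), species_codes=list("ABC"),
            evi_center=0.0)
        alpha = rng.normal(0, 1, J)
        beta = rng.normal(0, 1, J)
        got = hier_model.log_unnormalized_posterior(
            data, mu_alpha=0.2, mu_beta=-0.5, sigma_alpha=0.8,
            sigma_beta=1.3, alpha=alpha, beta=beta)
        want = oracles.scalar_log_posterior(
            list(data.y), list(data.species_idx), list(data.evi), 0.2,
            -0.5, 0.8, 1.3, list(alpha), list(beta))
        assert got == pytest.approx(want, abs=1e-10)

    def test_invalid_parameters_give_minus_inf(self):
        data = toy_data(5)
        assert hier_model.log_unnormalized_posterior(
            data, 0, 0, -1.0, 1.0, [0], [0]) == -math.inf
        assert hier_model.log_unnormalized_posterior(
            data, np.inf, 0, 1.0, 1.0, [0], [0]) == -math.inf


class TestPredict:
    def test_half_at_origin(self):
        assert hier_model.predict_yearling_prob(0.0, 0.0, 5.0) == 0.5

    def test_strictly_decreasing_for_negative_slope(self):
        evi = np.linspace(-0.3, 0.3, 50)
        p = hier_model.predict_yearling_prob(0.2, -1.3, evi)
        assert (np.diff(p) < 0).all()

    def test_matches_logit_inverse(self):
        rng = np.random.default_rng(2)
        a, b, x = rng.normal(size=3)
        p = hier_model.predict_yearling_prob(a, b, x)
        assert logit(p) == pytest.approx(a + b * x, abs=1e-12)


class TestFit:
    def test_posterior_mode_matches_grid_oracle(self):
        data = toy_data(n=30, seed=4)
        hypers = dict(mu_alpha=0.0, mu_beta=0.0, sigma_alpha=2.0,
                      sigma_beta=2.0)
        res = 0.02
        a_grid = np.arange(-2, 2, res)
        b_grid = np.arange(-3, 1, res)
        a_star, b_star, _ = oracles.grid_search_mode(
            list(data.y), list(data.evi), grid_alpha := hypers["mu_alpha"],
            hypers["mu_beta"], hypers["sigma_alpha"], hypers["sigma_beta"],
            a_grid, b_grid)
        opt = minimize(lambda t: -hier_model.log_unnormalized_posterior(
            data, **hypers, alpha=[t[0]], beta=[t[1]]), x0=[0.0, 0.0])
        assert abs(opt.x[0] - a_star) <= res
        assert abs(opt.x[1] - b_star) <= res
        # the sampler concentrates near the same mode
        post = hier_model.fit(data, chains=2, iterations=1500, warmup=1000,
                              seed=1, fixed_hypers=hypers)
        assert abs(post.draws["alpha"].mean() - a_star) < 0.45
        assert abs(post.draws["beta"].mean() - b_star) < 0.45

    def test_reproducible_given_seed(self):
        data = toy_data(n=60, seed=6)
        p1 = hier_model.fit(data, chains=2, iterations=200, warmup=200,
                            seed=9)
        p2 = hier_model.fit(data, chains=2, iterations=200, warmup=200,
                            seed=9)
        np.testing.assert_array_equal(p1.draws["mu_beta"],
                                      p2.draws["mu_beta"])

    def test_missing_outcomes_do_not_touch_the_posterior(self):
        """Unknown-age rows are uninformative under the likelihood: a fit
        with them present equals a fit on the observed subset, draw for
        draw, at a shared seed."""
        data = toy_data(n=200, seed=11, missing=50)
        with_missing = hier_model.fit(data, chains=2, iterations=300,
                                      warmup=300, seed=3)
        without = hier_model.fit(data.without_missing(), chains=2,
                                 iterations=300, warmup=300, seed=3)
        for name in hier_model.HYPER_NAMES:
            np.testing.assert_array_equal(with_missing.draws[name],
                                          without.draws[name])

    def test_pooling_limit_sigma_beta_zero(self):
        rng = np.random.default_rng(20)
        n, J = 400, 5
        sp = rng.integers(0, J, n).astype(np.int64)
        evi = rng.normal(0, 0.5, n)
        y = (rng.random(n) < expit(0.2 - 1.0 * evi)).astype(float)
        data = ModelData(y=y, species_idx=sp, evi=evi - evi.mean(),
                         species_codes=[f"S{j}" for j in range(J)],
                         evi_center=0.0)
        post = hier_model.fit(data, chains=2, iterations=300, warmup=2500,
                              seed=5, fixed_hypers={"sigma_beta": 1e-6})
        spread = np.abs(post.draws["beta"]
                        - post.draws["mu_beta"][:, :, None])
        assert spread.max() < 1e-4

    def test_posterior_concentrates_at_logistic_mle(self):
        """With flat-ish fixed priors and n = 2000, the single-species
        posterior sits on the logistic-regression MLE found by an
        independent grid search."""
        data = toy_data(n=2000, alpha=0.4, beta=-1.0, seed=17)
        hypers = dict(mu_alpha=0.0, mu_beta=0.0, sigma_alpha=50.0,
                      sigma_beta=50.0)
        post = hier_model.fit(data, chains=2, iterations=800, warmup=800,
                              seed=2, fixed_hypers=hypers)
        res = 0.02
        a_grid = np.arange(0.0, 0.9, res)
        b_grid = np.arange(-1.6, -0.4, res)
        a_star, b_star, _ = oracles.grid_search_mode(
            list(data.y), list(data.evi), 0.0, 0.0, 50.0, 50.0,
            a_grid, b_grid)
        assert post.draws["alpha"].mean() == pytest.approx(a_star, abs=0.1)
        assert post.draws["beta"].mean() == pytest.approx(b_star, abs=0.1)

    def test_null_slope_interval_covers_zero(self):
        rng = np.random.default_rng(30)
        n, J = 3000, 8
        sp = rng.integers(0, J, n).astype(np.int64)
        evi = rng.normal(0, 0.3, n)
        alpha_true = rng.normal(-0.3, 0.5, J)
        y = (rng.random(n) < expit(alpha_true[sp])).astype(float)
        data = ModelData(y=y, species_idx=sp, evi=evi - evi.mean(),
                         species_codes=[f"S{j}" for j in range(J)],
                         evi_center=0.0)
        post = hier_model.fit(data, chains=2, iterations=800, warmup=800,
                              seed=7)
        lo, hi = post.hyper_interval("mu_beta")
        assert lo <= 0.0 <= hi

    def test_single_outcome_class_species_is_flagged(self):
        rng = np.random.default_rng(40)
        n = 60
        sp = np.repeat([0, 1], n // 2).astype(np.int64)
        y = np.concatenate([np.ones(n // 2),
                            (rng.random(n // 2) < 0.4).astype(float)])
        data = ModelData(y=y, species_idx=sp, evi=rng.normal(0, 0.1, n),
                         species_codes=["A", "B"], evi_center=0.0)
        post = hier_model.fit(data, chains=1, iterations=50, warmup=50,
                              seed=1)
        assert any("single observed outcome class" in w
                   for w in post.warnings)


def test_impute_ahy_reports_posterior_probabilities():
    data = toy_data(n=120, alpha=1.5, beta=0.0, seed=8, missing=30)
    post = hier_model.fit(data, chains=2, iterations=300, warmup=300,
                          seed=4)
    out = hier_model.impute_ahy(post, data, np.random.default_rng(0))
    assert len(out) == 30
    assert ((out["p_yearling"] > 0) & (out["p_yearling"] < 1)).all()
    # alpha = 1.5 -> most unknown-age birds impute to yearling
    assert out["p_yearling"].mean() > 0.6
    assert out["imputed_SY"].isin([0, 1]).all()


class TestProfilesAndGroups:
    def _profiles_frames(self, means):
        inds = pd.DataFrame({
            "band_id": [f"B{i}" for i in range(len(means))],
            "species_code": [f"SP{i:02d}" for i in range(len(means))],
            "station_id": [f"S{i}" for i in range(len(means))],
            "year": 2012, "resolved_age": "SY"})
        evi = pd.DataFrame({"station_id": [f"S{i}"
                                           for i in range(len(means))],
                            "year": 2012, "evi": means})
        return inds, evi

    def test_quartile_groups_four_species(self):
        inds, evi = self._profiles_frames([1.0, 2.0, 3.0, 4.0])
        # EVI bounds are irrelevant to the grouping logic; scale down
        evi["evi"] = evi["evi"] / 10.0
        prof = hier_model.species_evi_profiles(inds, evi)
        groups = prof.set_index("species_code")["habitat_group"]
        assert groups["SP00"] == "successional"
        assert groups["SP01"] == "intermediate"
        assert groups["SP02"] == "intermediate"
        assert groups["SP03"] == "mature"

    def test_single_station_year_species_has_zero_range(self):
        inds, evi = self._profiles_frames([0.4, 0.5, 0.6, 0.7])
        prof = hier_model.species_evi_profiles(inds, evi)
        assert (prof["evi_range"] == 0.0).all()
        assert prof.set_index("species_code").loc["SP01", "evi_mean"] \
            == pytest.approx(0.5)

    def test_group_sizes_match_quantile_oracle(self):
        rng = np.random.default_rng(55)
        means = rng.uniform(0.3, 0.6, 29)
        inds, evi = self._profiles_frames(list(means))
        prof = hier_model.species_evi_profiles(inds, evi)
        q25, q75 = np.quantile(means, [0.25, 0.75])
        want_succ = int((means <= q25).sum())
        want_mat = int((means > q75).sum())
        counts = prof["habitat_group"].value_counts()
        assert counts["successional"] == want_succ
        assert counts["mature"] == want_mat
        assert counts.sum() == 29

    def test_group_summary_constant_draws(self):
        J = 4
        beta = np.full((2, 10, J), -0.7)
        post = hier_model.Posterior(
            draws={"beta": beta}, species_codes=[f"SP{i:02d}"
                                                 for i in range(J)],
            seed=0)
        prof = pd.DataFrame({
            "species_code": post.species_codes,
            "habitat_group": ["successional", "intermediate",
                              "intermediate", "mature"]})
        out = hier_model.group_coefficient_summary(post, prof)
        np.testing.assert_allclose(out["mean"], -0.7)
        assert (out["ci_2.5"] == out["ci_97.5"]).all()

    def test_group_summary_permutation_invariant(self):
        rng = np.random.default_rng(3)
        J = 6
        beta = rng.normal(-1, 0.5, (2, 50, J))
        codes = [f"SP{i:02d}" for i in range(J)]
        post = hier_model.Posterior(draws={"beta": beta},
                                    species_codes=codes, seed=0)
        prof = pd.DataFrame({"species_code": codes,
                             "habitat_group": ["successional"] * 2
                             + ["intermediate"] * 2 + ["mature"] * 2})
        out1 = hier_model.group_coefficient_summary(post, prof)
        out2 = hier_model.group_coefficient_summary(
            post, prof.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(out1, out2)


class TestMetaRegression:
    def _profiles(self, J, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "species_code": [f"SP{i:02d}" for i in range(J)],
            "evi_mean": rng.uniform(0.3, 0.6, J),
            "evi_range": rng.uniform(0.0, 0.2, J),
            "habitat_group": "intermediate"})

    def test_zero_noise_r2_one(self):
        prof = self._profiles(20)
        betas = pd.Series(
            -3.0 * prof["evi_mean"].values + 1.0 * prof["evi_range"].values,
            index=prof["species_code"])
        fit = hier_model.coefficient_meta_regression(betas, prof)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_recovers_structured_truth(self):
        rng = np.random.default_rng(99)
        prof = self._profiles(200, seed=99)
        zm = ((prof["evi_mean"] - prof["evi_mean"].mean())
              / prof["evi_mean"].std(ddof=1))
        zr = ((prof["evi_range"] - prof["evi_range"].mean())
              / prof["evi_range"].std(ddof=1))
        b1, b2, s = -0.7, 0.1, 0.3
        resp = b1 * zm + b2 * zr + rng.normal(0, s, len(prof))
        betas = pd.Series(resp.values, index=prof["species_code"])
        sd_y = np.sqrt(b1 ** 2 + b2 ** 2 + s ** 2)
        fit = hier_model.coefficient_meta_regression(betas, prof)
        for coef, lo, hi, truth in zip(fit.coef, fit.ci_low, fit.ci_high,
                                       (b1 / sd_y, b2 / sd_y)):
            assert lo <= truth <= hi

    def test_null_covers_zero(self):
        # response stream independent of the predictor stream
        rng = np.random.default_rng(987)
        prof = self._profiles(200, seed=12)
        betas = pd.Series(rng.normal(-1, 0.5, len(prof)),
                          index=prof["species_code"])
        fit = hier_model.coefficient_meta_regression(betas, prof)
        assert (fit.ci_low <= 0).all() and (fit.ci_high >= 0).all()

    def test_too_few_species_rejected(self):
        prof = self._profiles(3)
        betas = pd.Series([-1.0, -0.5, 0.0],
                          index=prof["species_code"])
        with pytest.raises(ValueError, match="4 species"):
            hier_model.coefficient_meta_regression(betas, prof)
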