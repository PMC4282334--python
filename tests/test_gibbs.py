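import numpy as np
import pytest
import scipy.sparse as sp

from mmnet import MMMCRegressor, classification_from_labels, build_weight_matrix
from mmnet.gibbs import dic_from_deviances, gaussian_deviance, posterior_summary
from oracles import conjugate_beta_posterior


def school_weights(rng, n, k, name="school"):
    labels = rng.integers(0, k, n)
    return build_weight_matrix(
        classification_from_labels(labels, tuple(range(n)), name), "equal"
    )


def regression_data(rng, n, beta=(0.5, -1.0, 0.25), sigma=1.0):
    p = len(beta)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p - 1)])
    y = X @ np.asarray(beta) + sigma * rng.standard_normal(n)
    return X, y


class TestValidation:
    def test_rank_deficient_design_rejected(self, rng):
        X = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank"):
            MMMCRegressor(n_iter=10, burn_in=1).fit(X, rng.standard_normal(20))

    def test_duplicate_classification_names_rejected(self, rng):
        X, y = regression_data(rng, 30)
        w = school_weights(rng, 30, 3)
        with pytest.raises(ValueError, match="unique"):
            MMMCRegressor([("a", w), ("a", w)], n_iter=10, burn_in=1).fit(X, y)

    def test_all_zero_weight_matrix_warns(self, rng):
        X, y = regression_data(rng, 30)
        Z = sp.csr_matrix((30, 4))
        with pytest.warns(UserWarning, match="all-zero"):
            MMMCRegressor([("empty", Z)], n_iter=50, burn_in=10,
                          random_state=0).fit(X, y)


class TestSamplerAgainstClosedForms:
    def test_no_structure_collapses_to_ols(self, rng):
        # generated with zero random-effect variance; posterior mean of beta
        # must sit on the OLS estimate within Monte-Carlo error
        X, y = regression_data(rng, 500)
        w = school_weights(rng, 500, 10)
        est = MMMCRegressor([("school", w)],
                            fixed_variances={"school": 1e-10},
                            n_iter=3000, burn_in=500, random_state=7).fit(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        mcse = 3 * est.coef_sd_ / np.sqrt(200)  # conservative ESS floor
        assert np.all(np.abs(est.coef_ - ols) < mcse)

    def test_fixed_variance_beta_matches_conjugate_posterior(self, rng):
        # variance components held at truth: the beta posterior is Gaussian
        # with a closed form computable by dense linear algebra
        n, k = 120, 8
        labels = rng.integers(0, k, n)
        w = build_weight_matrix(
            classification_from_labels(labels, tuple(range(n)), "school"), "equal"
        )
        s2_school, s2_e = 0.3, 0.8
        u = rng.normal(0, np.sqrt(s2_school), k)
        X, _ = regression_data(rng, n)
        y = X @ [0.5, -1.0, 0.25] + w.W @ u + rng.normal(0, np.sqrt(s2_e), n)
        est = MMMCRegressor(
            [("school", w)],
            fixed_variances={"school": s2_school},
            fixed_residual_variance=s2_e,
            n_iter=6000, burn_in=1000, random_state=11,
        ).fit(X, y)
        mean, cov = conjugate_beta_posterior(y, X, [w.W], [s2_school], s2_e)
        ess = 500.0  # conservative floor for autocorrelated chains
        np.testing.assert_allclose(
            est.coef_, mean, atol=3 * np.sqrt(np.diag(cov) / ess).max()
        )
        emp_cov = np.cov(est.chains_["beta"].T)
        scale = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert np.all(np.abs(emp_cov - cov) < 3 * scale * np.sqrt(2 / ess) + 1e-8)


class TestSamplerProperties:
    def test_seeded_chains_bit_identical(self, rng):
        X, y = regression_data(rng, 60)
        w = school_weights(rng, 60, 5)
        fits = [
            MMMCRegressor([("s", w)], n_iter=200, burn_in=50, random_state=5).fit(X, y)
            for _ in range(2)
        ]
        for key in fits[0].chains_:
            np.testing.assert_array_equal(fits[0].chains_[key], fits[1].chains_[key])

    def test_swapping_identical_classifications_invariant(self, rng):
        X, y = regression_data(rng, 60)
        w = school_weights(rng, 60, 5)
        a = MMMCRegressor([("s1", w), ("s2", w)], n_iter=300, burn_in=50,
                          random_state=3).fit(X, y)
        b = MMMCRegressor([("s2", w), ("s1", w)], n_iter=300, burn_in=50,
                          random_state=3).fit(X, y)
        np.testing.assert_array_equal(a.chains_["beta"], b.chains_["beta"])
        np.testing.assert_array_equal(a.chains_["sigma2_e"], b.chains_["sigma2_e"])

    def test_joint_and_single_site_updates_agree(self, rng):
        n, k = 80, 6
        labels = rng.integers(0, k, n)
        w = build_weight_matrix(
            classification_from_labels(labels, tuple(range(n)), "g"), "equal"
        )
        X, y0 = regression_data(rng, n)
        y = y0 + (w.W @ rng.normal(0, 0.6, k))
        res = {}
        for upd in ("joint", "single"):
            est = MMMCRegressor([("g", w)], update=upd, n_iter=4000, burn_in=1000,
                                random_state=9).fit(X, y)
            res[upd] = est
        sd = res["joint"].coef_sd_
        assert np.all(np.abs(res["joint"].coef_ - res["single"].coef_)
                      < 3 * sd / np.sqrt(100))
        assert abs(res["joint"].sigma2_e_ - res["single"].sigma2_e_) < 0.15

    def test_thinning_shortens_chains(self, rng):
        X, y = regression_data(rng, 40)
        est = MMMCRegressor(n_iter=200, burn_in=100, thin=5, random_state=1).fit(X, y)
        assert est.chains_["beta"].shape[0] == 20


class TestDic:
    def test_degenerate_chain_gives_zero_pd(self):
        dic, pd_ = dic_from_deviances(np.full(50, 123.4), 123.4)
        assert pd_ == pytest.approx(0.0)
        assert dic == pytest.approx(123.4)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            dic_from_deviances(np.array([]), 1.0)

    def test_stored_dic_consistent_with_chain_recomputation(self, small_dataset):
        ds = small_dataset
        est = MMMCRegressor([("school", ds._menu["school"])],
                            n_iter=400, burn_in=100, random_state=2).fit(
            ds.design_matrix(), ds.response)
        d_bar = gaussian_deviance(ds.response, est.fitted_values_, est.sigma2_e_)
        dic, pd_ = dic_from_deviances(est.chains_["deviance"], d_bar)
        assert est.dic_ == pytest.approx(dic)
        assert est.pd_ == pytest.approx(pd_)

    def test_pd_counts_one_free_mean_parameter(self):
        # iid N(mu, sigma2 known), flat prior on mu -> pD approx 1
        pds = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.normal(0.3, 1.0, 200)
            X = np.ones((200, 1))
            est = MMMCRegressor(fixed_residual_variance=1.0, n_iter=2000,
                                burn_in=500, random_state=seed).fit(X, y)
            pds.append(est.pd_)
        assert abs(np.mean(pds) - 1.0) < 0.2

    def test_structured_model_beats_null_on_structured_data(self, small_dataset):
        ds = small_dataset
        cls = [(k, ds._menu[k]) for k in ("school", "egonet")]
        full = MMMCRegressor(cls, n_iter=1200, burn_in=300, random_state=4).fit(
            ds.design_matrix(), ds.response)
        null = MMMCRegressor(n_iter=1200, burn_in=300, random_state=4).fit(
            ds.design_matrix()[:, :1], ds.response)
        assert full.dic_ < null.dic_


class TestPosteriorSummary:
    def test_summary_matches_stored_chain_statistics(self, rng):
        X, y = regression_data(rng, 50)
        w = school_weights(rng, 50, 4)
        est = MMMCRegressor([("s", w)], n_iter=300, burn_in=100,
                            random_state=6).fit(X, y)
        tab = posterior_summary(est)
        beta0 = est.chains_["beta"][:, 0]
        row = tab[tab.parameter == "beta[0]"].iloc[0]
        assert row["mean"] == pytest.approx(beta0.mean())
        assert row["sd"] == pytest.approx(beta0.std(ddof=1))
        # quantiles equal an independent order-statistics computation
        srt = np.sort(beta0)
        lo = np.percentile(srt, 2.5)
        assert row["2.5%"] == pytest.approx(lo)
        assert set(tab.parameter) == {
            "beta[0]", "beta[1]", "beta[2]", "sigma2_s", "sigma2_e"}

    def test_predict_uses_posterior_mean_coefficients(self, rng):
        X, y = regression_data(rng, 50)
        est = MMMCRegressor(n_iter=200, burn_in=50, random_state=1).fit(X, y)
        np.testing.assert_allclose(est.predict(X), X @ est.coef_)
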