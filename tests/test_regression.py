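import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import ks_2samp

from phylocoev import kernels
from phylocoev.data_model import SocietyTable
from phylocoev.exceptions import AlignmentError, ConfigError, SchemaError, ValidationError
from phylocoev.mcmc import SamplerConfig
from phylocoev.regression import (
    PosteriorSummary,
    PriorConfig,
    RegressionSpec,
    fit_structured_regression,
    ordinal_category_probs,
    predicted_contrast,
    rho_sensitivity,
)

from conftest import make_table


class TestOrdinalCategoryProbs:
    def test_sum_to_one(self, rng):
        for _ in range(50):
            mu = rng.normal(scale=3)
            alpha = np.sort(rng.normal(scale=2, size=4))
            if np.any(np.diff(alpha) <= 0):
                continue
            p = ordinal_category_probs(mu, alpha)
            assert abs(p.sum() - 1.0) < 1e-12
            assert (p >= 0).all()

    def test_symmetry_about_middle(self):
        p = ordinal_category_probs(0.0, np.array([-1.0, -0.4, 0.4, 1.0]))
        assert p[0] == pytest.approx(p[4])
        assert p[1] == pytest.approx(p[3])

    def test_hand_computed_case(self):
        # direct logistic-CDF differencing, assembled independently
        alpha = np.array([-1.0, 0.0, 1.0, 2.0])
        mu = 2.0
        cdf = [expit(a - mu) for a in alpha]
        expected = np.array([
            cdf[0], cdf[1] - cdf[0], cdf[2] - cdf[1], cdf[3] - cdf[2],
            1 - cdf[3],
        ])
        np.testing.assert_allclose(ordinal_category_probs(mu, alpha), expected,
                                   atol=1e-15)

    def test_unordered_cutpoints_rejected(self):
        with pytest.raises(ValidationError):
            ordinal_category_probs(0.0, np.array([0.0, -1.0, 1.0, 2.0]))

    def test_vectorized_mu(self):
        p = ordinal_category_probs(np.array([0.0, 2.0]),
                                   np.array([-1.0, 0.0, 1.0, 2.0]))
        assert p.shape == (2, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


def simulate_ordinal_table(n=83, slope=1.0, seed=0, alpha=(-1.5, -0.5, 0.5, 1.5),
                           latent_extra=None):
    rng = np.random.default_rng(seed)
    kava = rng.integers(0, 2, n).astype(float)
    mu = slope * kava
    if latent_extra is not None:
        mu = mu + latent_extra
    probs = ordinal_category_probs(mu, np.array(alpha))
    u = rng.uniform(size=n)
    y = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1).astype(float)
    return SocietyTable(pd.DataFrame({
        "society_id": [f"s{i:03d}" for i in range(n)],
        "language_taxon": [f"l{i:03d}" for i in range(n)],
        "kava": kava,
        "political_complexity": y,
        "social_stratification": y,
        "atoll_raw": 0.0,
        "latitude": rng.uniform(-25, 10, n),
        "longitude": rng.uniform(140, 180, n),
    }))


def quick_spec(**kw):
    defaults = dict(
        response="political_complexity",
        sampler_cfg=SamplerConfig(chains=1, draws=400, warmup=400, seed=1),
    )
    defaults.update(kw)
    return RegressionSpec(**defaults)


class TestFitStructuredRegression:
    def test_null_slope(self):
        table = simulate_ordinal_table(slope=0.0, seed=4)
        fit = fit_structured_regression(table, quick_spec())
        row = fit.summary.set_index("parameter").loc["b_kava"]
        assert 0.2 < row["ppm"] < 0.8
        assert row["ci95_lower"] < 0 < row["ci95_upper"]

    def test_recovers_slope_one(self):
        table = simulate_ordinal_table(slope=1.0, seed=7)
        fit = fit_structured_regression(table, quick_spec())
        row = fit.summary.set_index("parameter").loc["b_kava"]
        assert row["ci95_lower"] < 1.0 < row["ci95_upper"]

    def test_bernoulli_family(self):
        table = simulate_ordinal_table(slope=0.0, seed=9)
        spec = quick_spec(response="kava", predictors=("atoll_raw",),
                          family="bernoulli_logit")
        fit = fit_structured_regression(table, spec)
        assert "b_intercept" in fit.draws.columns

    def test_missing_rows_excluded_and_counted(self):
        table = simulate_ordinal_table(slope=1.0, seed=3)
        df = table.data.copy()
        df.loc[:4, "kava"] = np.nan
        fit = fit_structured_regression(SocietyTable(df), quick_spec())
        assert fit.meta["n_excluded"] == 5
        assert fit.meta["n_used"] == len(df) - 5

    def test_missing_covariance_kind_is_alignment_error(self):
        table = simulate_ordinal_table(seed=1)
        spec = quick_spec(random_structures=("phylogenetic",))
        with pytest.raises(AlignmentError):
            fit_structured_regression(table, spec, [])

    def test_cutpoints_ordered_in_draws(self):
        table = simulate_ordinal_table(seed=2)
        fit = fit_structured_regression(table, quick_spec())
        a = fit.draws[[f"alpha[{k}]" for k in range(1, 5)]].to_numpy()
        assert (np.diff(a, axis=1) > 0).all()

    def test_zero_scale_structured_matches_unstructured(self):
        table = simulate_ordinal_table(slope=1.0, seed=11)
        cov = [kernels.spatial_covariance(table, kernels.KernelConfig(rho=0.04))]
        cfg = SamplerConfig(chains=2, draws=2000, warmup=600, seed=21)
        plain = fit_structured_regression(table, quick_spec(sampler_cfg=cfg))
        fixed = fit_structured_regression(
            table,
            quick_spec(random_structures=("spatial",), fixed_re_scale=0.0,
                       sampler_cfg=cfg),
            cov,
        )
        ks = ks_2samp(plain.param("b_kava"), fixed.param("b_kava")).statistic
        assert ks < 0.1

    def test_prior_predictive_covers_all_categories(self, rng):
        pr = PriorConfig()
        cats = set()
        for _ in range(200):
            alpha = np.sort(rng.normal(scale=pr.cutpoint_sd, size=4))
            if np.any(np.diff(alpha) <= 0):
                continue
            beta = rng.normal(scale=pr.slope_sd)
            mu = beta * rng.integers(0, 2, 30)
            p = ordinal_category_probs(mu, alpha)
            draws = np.array([rng.choice(5, p=pi) for pi in p])
            cats.update(draws.tolist())
        assert cats == {0, 1, 2, 3, 4}


class TestPredictedContrast:
    def _manual_posterior(self, beta_draws, alpha, n=4):
        X = np.zeros((n, 1))
        draws = pd.DataFrame({"b_kava": beta_draws})
        for k, a in enumerate(alpha, start=1):
            draws[f"alpha[{k}]"] = a
        meta = {
            "family": "cumulative_logit",
            "predictors": ["kava"],
            "X": X,
            "n_levels": 5,
            "re_offset": np.zeros((len(beta_draws), n)),
        }
        return PosteriorSummary(draws, pd.DataFrame(), {}, meta)

    def test_zero_slope_gives_zero_contrast(self):
        post = self._manual_posterior(np.zeros(10), [-1.0, 0.0, 1.0, 2.0])
        contrast, row = predicted_contrast(post, "kava")
        np.testing.assert_allclose(contrast, 0.0, atol=1e-14)

    def test_single_draw_matches_hand_expectation(self):
        alpha = np.array([-1.0, -0.3, 0.5, 1.2])
        beta = 1.4
        post = self._manual_posterior(np.array([beta]), alpha)
        contrast, _ = predicted_contrast(post, "kava")
        scale = np.arange(5)
        e1 = (ordinal_category_probs(beta, alpha) * scale).sum()
        e0 = (ordinal_category_probs(0.0, alpha) * scale).sum()
        assert contrast[0] == pytest.approx(e1 - e0, abs=1e-12)

    def test_unknown_predictor(self):
        post = self._manual_posterior(np.zeros(5), [-1.0, 0.0, 1.0, 2.0])
        with pytest.raises(SchemaError):
            predicted_contrast(post, "atoll")

    def test_bernoulli_fit_rejected(self):
        table = simulate_ordinal_table(seed=9)
        spec = quick_spec(response="kava", predictors=("atoll_raw",))
        fit = fit_structured_regression(table, spec)
        with pytest.raises(ConfigError):
            predicted_contrast(fit, "atoll_raw")

    def test_positive_slope_positive_contrast(self):
        table = simulate_ordinal_table(slope=1.5, seed=13)
        fit = fit_structured_regression(table, quick_spec())
        contrast, row = predicted_contrast(fit, "kava")
        assert row["ppm"] > 0.9
        assert 0 < row["mean"] < 4


class TestRhoSensitivity:
    def test_empty_grid(self):
        table = simulate_ordinal_table(seed=2)
        with pytest.raises(ConfigError):
            rho_sensitivity(table, quick_spec(random_structures=("spatial",)), [])

    def test_requires_spatial(self):
        table = simulate_ordinal_table(seed=2)
        with pytest.raises(ConfigError):
            rho_sensitivity(table, quick_spec(), [0.02])

    def test_slope_attenuates_as_rho_grows_under_confounding(self):
        from scipy.special import expit

        from phylocoev import synthetic_data as sd
        from phylocoev.mcmc import SamplerConfig

        n, rep = 83, 0
        lat, lon, effect = sd.simulate_geography(n, 900 + rep, gp_scale=2.0,
                                                 rho=0.10)
        rng = np.random.default_rng(901 + rep)
        kava = (rng.uniform(size=n) < expit(effect)).astype(float)
        table = simulate_ordinal_table(n=n, slope=0.0, seed=902 + rep,
                                       latent_extra=effect)
        df = table.data.copy()
        df["kava"], df["latitude"], df["longitude"] = kava, lat, lon
        table = SocietyTable(df)
        spec = quick_spec(
            random_structures=("spatial",),
            sampler_cfg=SamplerConfig(chains=1, draws=400, warmup=450, seed=3),
        )
        out, _ = rho_sensitivity(table, spec, [0.02, 0.04, 0.06, 0.08])
        slopes = out["mean"].to_numpy()
        assert slopes[-1] < slopes[0]
        assert np.all(np.diff(slopes) < 0.2)  # non-increasing up to MC noise

    def test_single_rho_matches_direct_fit(self):
        table = simulate_ordinal_table(slope=1.0, seed=5, n=40)
        spec = quick_spec(
            random_structures=("spatial",),
            sampler_cfg=SamplerConfig(chains=1, draws=200, warmup=250, seed=2),
        )
        out, fits = rho_sensitivity(table, spec, [0.04])
        cov = [kernels.spatial_covariance(table, kernels.KernelConfig(rho=0.04))]
        from dataclasses import replace

        direct = fit_structured_regression(
            table, replace(spec, kernel_cfg=kernels.KernelConfig(rho=0.04)), cov)
        assert out.loc[0, "mean"] == pytest.approx(
            direct.summary.set_index("parameter").loc["b_kava", "mean"])
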