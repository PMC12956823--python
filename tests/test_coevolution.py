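import math

import dendropy
import numpy as np
import pandas as pd
import pytest
import scipy.linalg
from scipy.special import expit
from scipy.stats import multivariate_normal, norm

from phylocoev import synthetic_data as sd
from phylocoev.coevolution import (
    CoevSpec,
    OUParams,
    TreeIndex,
    _branch_system,
    delta_theta,
    fit_coevolution,
    ou_equilibrium,
    ou_stationary_cov,
    ou_transition_moments,
    tree_latent_loglik,
)
from phylocoev.exceptions import ConfigError, DegenerateInputError, StabilityError, ValidationError
from phylocoev.mcmc import SamplerConfig
from phylocoev.regression import PosteriorSummary

from conftest import coev_dataset


def random_stable_params(rng, with_corr=True):
    while True:
        A = np.array([
            [-rng.uniform(0.3, 2.0), rng.uniform(-1.5, 1.5)],
            [rng.uniform(-1.5, 1.5), -rng.uniform(0.3, 2.0)],
        ])
        if np.max(np.linalg.eigvals(A).real) < -0.05:
            break
    r = rng.uniform(-0.7, 0.7) if with_corr else 0.0
    return OUParams(
        b=rng.normal(size=2),
        A=A,
        sigma=rng.uniform(0.4, 1.5, size=2),
        R=np.array([[1.0, r], [r, 1.0]]),
        alpha=np.sort(rng.normal(scale=1.5, size=4)) + np.array([0, 0.2, 0.4, 0.6]),
        eta_anc=rng.normal(size=2),
    )


class TestOUEquilibrium:
    def test_zero_intercept(self):
        assert np.allclose(ou_equilibrium(np.diag([-1.0, -2.0]), np.zeros(2)), 0)

    def test_closed_form(self):
        theta = ou_equilibrium(np.diag([-1.0, -2.0]), np.array([2.0, 2.0]))
        np.testing.assert_allclose(theta, [2.0, 1.0])

    def test_residual_against_solver_oracle(self, rng):
        for _ in range(30):
            p = random_stable_params(rng)
            theta = ou_equilibrium(p.A, p.b)
            assert np.linalg.norm(p.A @ theta + p.b) < 1e-10
            # independent route: least-squares solve
            oracle = np.linalg.lstsq(p.A, -p.b, rcond=None)[0]
            np.testing.assert_allclose(theta, oracle, atol=1e-9)

    def test_unstable_rejected(self):
        with pytest.raises(StabilityError):
            ou_equilibrium(np.array([[1.0, 0.0], [0.0, -1.0]]), np.zeros(2))
        with pytest.raises(StabilityError):
            ou_equilibrium(np.array([[-1.0, 2.0], [2.0, -1.0]]), np.zeros(2))


class TestOUTransitionMoments:
    def _params(self):
        return OUParams(b=[0.3, -0.2], A=[[-1.2, 0.4], [0.7, -0.9]],
                        sigma=[0.8, 1.1], R=[[1, 0.3], [0.3, 1]],
                        alpha=[-1, 0, 1, 2])

    def test_zero_dt(self):
        p = self._params()
        eta = np.array([0.5, -1.0])
        mean, cov = ou_transition_moments(p, 0.0, eta)
        np.testing.assert_allclose(mean, eta, atol=1e-12)
        np.testing.assert_allclose(cov, 0.0, atol=1e-12)

    def test_scalar_ou_stationary_limit(self):
        # A = -I, Q = I: stationary variance q/(2a) = 0.5 per trait
        p = OUParams(b=np.zeros(2), A=-np.eye(2), sigma=np.ones(2),
                     R=np.eye(2), alpha=[-1, 0, 1, 2])
        mean, cov = ou_transition_moments(p, 50.0, np.array([3.0, -3.0]))
        np.testing.assert_allclose(cov, 0.5 * np.eye(2), atol=1e-10)
        np.testing.assert_allclose(mean, 0.0, atol=1e-10)

    def test_euler_maruyama_oracle_single(self, rng):
        p = self._params()
        eta0 = np.array([0.6, -0.4])
        dt = 0.3
        mean, cov = ou_transition_moments(p, dt, eta0)
        n_paths, step = 100_000, 1e-3
        G = p.G
        x = np.tile(eta0, (n_paths, 1))
        n_steps = int(round(dt / step))
        for _ in range(n_steps):
            drift = p.b + x @ p.A.T
            x = x + step * drift + math.sqrt(step) * rng.standard_normal((n_paths, 2)) @ G.T
        se_mean = x.std(axis=0) / math.sqrt(n_paths)
        assert np.all(np.abs(x.mean(axis=0) - mean) < 3 * se_mean + 5e-3)
        emp_cov = np.cov(x.T)
        assert np.all(np.abs(emp_cov - cov) < 3 * np.sqrt(2.0 / n_paths) * np.outer(
            x.std(axis=0), x.std(axis=0)) + 5e-3)

    def test_unstable_rejected(self):
        p = self._params()
        p.A = np.array([[-0.1, 2.0], [2.0, -0.1]])
        with pytest.raises(StabilityError):
            ou_transition_moments(p, 0.5, np.zeros(2))

    def test_negative_dt_rejected(self):
        with pytest.raises(ValidationError):
            ou_transition_moments(self._params(), -0.1, np.zeros(2))


class TestBranchSystemEquivalence:
    """Sampler-internal vectorized moments vs the scipy-based public route."""

    def test_matches_public_moments(self, rng):
        for _ in range(25):
            p = random_stable_params(rng)
            dts = rng.uniform(0.01, 1.5, size=6)
            theta, E, L = _branch_system(p.A, p.b, p.Q, dts)
            for i, dt in enumerate(dts):
                eta_p = rng.normal(size=2)
                mean, cov = ou_transition_moments(p, dt, eta_p)
                np.testing.assert_allclose(theta + E[i] @ (eta_p - theta), mean,
                                           atol=1e-9)
                np.testing.assert_allclose(L[i] @ L[i].T, cov, atol=1e-7)

    def test_complex_eigenvalues_handled(self):
        # rotational dynamics: complex eigenvalue pair
        A = np.array([[-0.5, 2.0], [-2.0, -0.5]])
        assert np.iscomplexobj(np.linalg.eigvals(A))
        p = OUParams(b=[0.1, 0.2], A=A, sigma=[1.0, 0.8],
                     R=np.eye(2), alpha=[-1, 0, 1, 2])
        theta, E, L = _branch_system(p.A, p.b, p.Q, np.array([0.4]))
        mean, cov = ou_transition_moments(p, 0.4, np.array([1.0, -1.0]))
        np.testing.assert_allclose(theta + E[0] @ (np.array([1.0, -1.0]) - theta),
                                   mean, atol=1e-9)
        np.testing.assert_allclose(L[0] @ L[0].T, cov, atol=1e-8)


class TestTreeIndex:
    def test_height_normalization_and_floor(self):
        tree = dendropy.Tree.get(data="((A:1,B:0):1,C:2);", schema="newick")
        idx = TreeIndex(tree)
        assert idx.height == pytest.approx(2.0)
        assert idx.edge[1:].min() >= 1e-6  # zero-length edge floored
        depth_a = None
        assert idx.n_tips == 3

    def test_single_node_tree(self):
        tree = dendropy.Tree.get(data="A;", schema="newick")
        idx = TreeIndex(tree)
        assert idx.n_nodes == 1
        assert idx.n_tips == 1


class TestTreeLatentLoglik:
    def test_five_tip_hand_assembled(self, rng):
        tree = dendropy.Tree.get(
            data="(((A:0.3,B:0.4):0.2,C:0.6):0.4,(D:0.5,E:0.7):0.3);",
            schema="newick")
        idx = TreeIndex(tree, normalize_height=False)
        p = OUParams(b=[0.2, -0.1], A=[[-1.0, 0.3], [0.5, -0.8]],
                     sigma=[0.9, 1.1], R=[[1, 0.2], [0.2, 1]],
                     alpha=[-1.0, -0.2, 0.5, 1.3], eta_anc=[0.3, -0.5])
        eta = rng.normal(size=(idx.n_nodes, 2))
        y1 = np.array([1, 0, 1, 1, 0], dtype=float)
        y2 = np.array([0, 2, 4, 1, 3], dtype=float)
        got = tree_latent_loglik(idx, p, eta, y1, y2)

        # oracle: three term groups assembled independently
        expected = sum(norm.logpdf(eta[0, k], loc=p.eta_anc[k], scale=1.0)
                       for k in range(2))
        for i in range(1, idx.n_nodes):
            mean, cov = ou_transition_moments(p, idx.edge[i],
                                              eta[idx.parent[i]])
            expected += multivariate_normal.logpdf(eta[i], mean=mean, cov=cov,
                                                   allow_singular=True)
        tips = eta[idx.tip_indices]
        for k in range(5):
            pk = expit(tips[k, 0])
            expected += math.log(pk if y1[k] == 1 else 1 - pk)
            cdf = np.concatenate([[0.0], expit(p.alpha - tips[k, 1]), [1.0]])
            expected += math.log(np.diff(cdf)[int(y2[k])])
        assert got == pytest.approx(expected, abs=1e-6)

    def test_single_tip_reduces_to_root_and_obs(self):
        tree = dendropy.Tree.get(data="A;", schema="newick")
        idx = TreeIndex(tree)
        p = OUParams(b=[0, 0], A=-np.eye(2), sigma=[1, 1], R=np.eye(2),
                     alpha=[-1, 0, 1, 2], eta_anc=[0, 0])
        eta = np.array([[0.5, -0.3]])
        got = tree_latent_loglik(idx, p, eta, np.array([1.0]), np.array([2.0]))
        expected = (norm.logpdf(0.5) + norm.logpdf(-0.3)
                    + math.log(expit(0.5))
                    + math.log(expit(1.0 + 0.3) - expit(0.3)))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_missing_observations_contribute_zero(self, rng):
        tree = sd.simulate_tree(5, seed=2)
        idx = TreeIndex(tree)
        p = OUParams(b=[0, 0], A=-np.eye(2), sigma=[1, 1], R=np.eye(2),
                     alpha=[-1, 0, 1, 2])
        eta = rng.normal(size=(idx.n_nodes, 2))
        y1 = np.array([1, 0, 1, 1, 0], dtype=float)
        y2 = np.array([0, 2, 4, 1, 3], dtype=float)
        full = tree_latent_loglik(idx, p, eta, y1, y2)
        mask1 = np.array([True, True, False, True, True])
        partial = tree_latent_loglik(idx, p, eta, y1, y2, mask_binary=mask1)
        tips = eta[idx.tip_indices]
        dropped = math.log(expit(tips[2, 0]))
        assert partial == pytest.approx(full - dropped, abs=1e-9)

    def test_shape_mismatch(self):
        tree = sd.simulate_tree(5, seed=2)
        idx = TreeIndex(tree)
        p = OUParams(b=[0, 0], A=-np.eye(2), sigma=[1, 1], R=np.eye(2),
                     alpha=[-1, 0, 1, 2])
        with pytest.raises(ValidationError, match="shape"):
            tree_latent_loglik(idx, p, np.zeros((3, 2)), np.ones(5), np.ones(5))


def _manual_coev_posterior(a12, a21, a11=-1.0, a22=-1.0, mad1=1.0, mad2=1.0):
    n = max(np.atleast_1d(a12).size, np.atleast_1d(a21).size)
    draws = pd.DataFrame({
        "A[1,2]": np.broadcast_to(a12, n).astype(float),
        "A[2,1]": np.broadcast_to(a21, n).astype(float),
        "A[1,1]": np.full(n, a11),
        "A[2,2]": np.full(n, a22),
        "mad_eta1": np.full(n, mad1),
        "mad_eta2": np.full(n, mad2),
        "sd_eta1": np.full(n, mad1),
        "sd_eta2": np.full(n, mad2),
    })
    return PosteriorSummary(draws, pd.DataFrame(), {}, {})


class TestDeltaTheta:
    def test_closed_form(self):
        post = _manual_coev_posterior(a12=0.0, a21=np.array([1.0]))
        dt = delta_theta(post, (1, 2))
        assert dt.draws[0] == pytest.approx(1.0)

    def test_zero_offdiagonal_gives_half_ppm(self):
        post = _manual_coev_posterior(a12=np.zeros(10), a21=np.zeros(10))
        dt = delta_theta(post, (2, 1))
        np.testing.assert_allclose(dt.draws, 0.0)
        assert dt.ppm == 0.5

    def test_sign_antisymmetry(self, rng):
        a21 = rng.normal(size=200)
        post_pos = _manual_coev_posterior(a12=np.zeros(200), a21=a21)
        post_neg = _manual_coev_posterior(a12=np.zeros(200), a21=-a21)
        d_pos = delta_theta(post_pos, (1, 2)).draws
        d_neg = delta_theta(post_neg, (1, 2)).draws
        np.testing.assert_allclose(d_pos, -d_neg, atol=1e-14)

    def test_quantile_oracle(self, rng):
        a21 = rng.normal(size=1000)
        post = _manual_coev_posterior(a12=np.zeros(1000), a21=a21)
        dt = delta_theta(post, (1, 2))
        # brute-force quantiles by sorting
        s = np.sort(dt.draws)
        def q(p):
            return np.percentile(dt.draws, p)
        assert dt.summary["median"] == pytest.approx(q(50))
        assert dt.summary["ci66_lower"] == pytest.approx(q(17))
        assert dt.summary["ci95_upper"] == pytest.approx(q(97.5))
        assert dt.ppm == pytest.approx(np.mean(dt.draws > 0))

    def test_zero_scale_degenerate(self):
        post = _manual_coev_posterior(a12=0.0, a21=np.ones(5), mad1=0.0)
        with pytest.raises(DegenerateInputError):
            delta_theta(post, (1, 2))

    def test_bad_direction(self):
        post = _manual_coev_posterior(a12=0.0, a21=np.ones(5))
        with pytest.raises(ConfigError):
            delta_theta(post, (1, 1))

    def test_mad_vs_sd_scaling(self):
        post = _manual_coev_posterior(a12=0.0, a21=np.ones(4), mad1=2.0)
        d_mad = delta_theta(post, (1, 2), scale="mad").draws
        np.testing.assert_allclose(d_mad, 2.0)


QUICK_COEV = SamplerConfig(chains=1, draws=300, warmup=400, seed=3, mh_sweeps=4)


class TestFitCoevolution:
    def test_directional_signal_detected(self):
        table, trees, tmap, true, _ = coev_dataset(n=60, rep=0)
        spec = CoevSpec(root_prior="informed", sampler_cfg=QUICK_COEV)
        fit = fit_coevolution(table, trees, spec, tmap)
        d12 = delta_theta(fit, (1, 2))
        d21 = delta_theta(fit, (2, 1))
        assert d12.ppm > d21.ppm
        assert d12.ppm > 0.5

    def test_structural_parameter_coverage(self):
        table, trees, tmap, true, _ = coev_dataset(n=60, rep=1)
        spec = CoevSpec(root_prior="informed", sampler_cfg=QUICK_COEV)
        fit = fit_coevolution(table, trees, spec, tmap)
        s = fit.summary.set_index("parameter")
        checks = {
            "A[1,1]": true.A[0, 0], "A[2,2]": true.A[1, 1],
            "sigma[1]": true.sigma[0], "sigma[2]": true.sigma[1],
            "b[1]": true.b[0], "b[2]": true.b[1],
        }
        covered = sum(
            s.loc[k, "ci95_lower"] <= v <= s.loc[k, "ci95_upper"]
            for k, v in checks.items()
        )
        assert covered >= 4

    def test_diag_a_negative_in_all_draws(self):
        table, trees, tmap, _, _ = coev_dataset(n=40, rep=2)
        spec = CoevSpec(sampler_cfg=SamplerConfig(chains=1, draws=150,
                                                  warmup=200, seed=1))
        fit = fit_coevolution(table, trees, spec, tmap)
        assert (fit.draws["A[1,1]"] < 0).all()
        assert (fit.draws["A[2,2]"] < 0).all()
        # cutpoints remain ordered
        a = fit.draws[[f"alpha[{k}]" for k in range(1, 5)]].to_numpy()
        assert (np.diff(a, axis=1) >= 0).all()

    def test_spatial_scale_zero_matches_uncontrolled(self):
        from scipy.stats import ks_2samp

        table, trees, tmap, _, _ = coev_dataset(n=20, rep=3)
        cfg = SamplerConfig(chains=1, draws=3500, warmup=800, seed=5, mh_sweeps=4)
        plain = fit_coevolution(
            table, trees, CoevSpec(root_prior="informed", sampler_cfg=cfg), tmap)
        gp0 = fit_coevolution(
            table, trees,
            CoevSpec(root_prior="informed", spatial_control=True,
                     fixed_gp_scale=0.0, sampler_cfg=cfg),
            tmap)
        d_plain = delta_theta(plain, (1, 2)).draws
        d_gp0 = delta_theta(gp0, (1, 2)).draws
        assert ks_2samp(d_plain, d_gp0).statistic < 0.1

    def test_spatial_control_runs(self):
        table, trees, tmap, _, _ = coev_dataset(n=30, rep=4)
        spec = CoevSpec(spatial_control=True, rho=0.02,
                        sampler_cfg=SamplerConfig(chains=1, draws=100,
                                                  warmup=150, seed=2))
        fit = fit_coevolution(table, trees, spec, tmap)
        assert "gp_scale[1]" in fit.draws.columns
        assert (fit.draws["gp_scale[1]"] > 0).all()

    def test_root_prior_choice(self):
        spec = CoevSpec(root_prior="informed")
        np.testing.assert_array_equal(spec.eta_anc(), [-2.0, -2.0])
        with pytest.raises(ConfigError):
            CoevSpec(root_prior="wat").eta_anc()

    def test_pooling_concatenates_trees(self):
        table, trees, tmap, _, _ = coev_dataset(n=30, rep=5)
        two = type(trees)([trees.trees[0], trees.trees[0].clone(depth=1)],
                          kind="posterior_sample")
        spec = CoevSpec(n_trees=2,
                        sampler_cfg=SamplerConfig(chains=1, draws=60,
                                                  warmup=100, seed=2))
        fit = fit_coevolution(table, two, spec, tmap)
        assert set(fit.draws["tree"].unique()) == {0, 1}


class TestSimulationRoundTrip:
    def test_seeded_reproducibility(self):
        table, trees, tmap, _, _ = coev_dataset(n=30, rep=6)
        spec = CoevSpec(sampler_cfg=SamplerConfig(chains=1, draws=50,
                                                  warmup=80, seed=9))
        f1 = fit_coevolution(table, trees, spec, tmap)
        f2 = fit_coevolution(table, trees, spec, tmap)
        pd.testing.assert_frame_equal(f1.draws, f2.draws)
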