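"""Phylogenetic correlation and signal from a bivariate latent model.

A binary trait (Bernoulli, logit link) and a 5-level ordinal trait
(cumulative logit) are given society-level random effects that covary both
across traits (a 2x2 trait covariance with correlation ``r``) and across
societies (the phylogenetic correlation matrix of the tree).  Writing the
society-by-trait latent matrix as ``U = L_K Z C'`` with ``Z ~ N(0, I)``,
``L_K`` the Cholesky factor of the phylogenetic correlation and ``C`` the
Cholesky factor of the trait covariance, the model is fitted per tree over
a posterior tree sample and the draws pooled with equal weight.

The phylogenetic signal of each trait is the variance-partition proportion
``lambda = sigma_phylo^2 / (sigma_phylo^2 + pi^2 / 3)`` on the latent logit
scale (the logistic link contributes residual variance pi^2/3).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kernels, likelihoods
from .data_model import ORDINAL_LEVELS, PhyloSet, SocietyTable, TaxonMap
from .exceptions import ConfigError, DegenerateInputError
from .mcmc import SamplerConfig, check_convergence, sample_hmc, summarize_draws
from .regression import PosteriorSummary, PriorConfig

logger = logging.getLogger(__name__)

LOGIT_RESIDUAL_VAR = np.pi ** 2 / 3.0

__all__ = [
    "SignalEstimate",
    "PhyloCorrelation",
    "fit_bivariate_latent",
    "phylogenetic_signal",
    "phylo_correlation_estimate",
]


@dataclass
class SignalEstimate:
    trait: str
    draws: np.ndarray  # lambda in [0, 1]
    summary: pd.Series


@dataclass
class PhyloCorrelation:
    trait_pair: tuple[str, str]
    draws: np.ndarray  # r in [-1, 1]
    summary: pd.Series


class _BivariateLatentModel:
    """Log density + gradient; layout [a, cut_raw(K-1), logs1, logs2, t_r, Z(2n)]."""

    def __init__(self, y1, mask1, y2, mask2, L_phylo, priors: PriorConfig,
                 n_levels: int = ORDINAL_LEVELS, lkj_eta: float = 2.0):
        self.y1, self.mask1 = y1, mask1
        self.y2, self.mask2 = y2, mask2
        self.L = L_phylo
        self.n = L_phylo.shape[0]
        self.K = n_levels
        self.priors = priors
        self.lkj_eta = lkj_eta
        self.n_cut = n_levels - 1
        self.dim = 1 + self.n_cut + 3 + 2 * self.n

    def unpack(self, q):
        a = q[0]
        raw = q[1:1 + self.n_cut]
        logs1, logs2, t = q[1 + self.n_cut:4 + self.n_cut]
        Z = q[4 + self.n_cut:].reshape(self.n, 2)
        return a, raw, logs1, logs2, t, Z

    @staticmethod
    def _trait_chol(s1, s2, r):
        w = np.sqrt(1.0 - r ** 2)
        return np.array([[s1, 0.0], [r * s2, w * s2]])

    def logp_grad(self, q):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad(q)

    def _logp_grad(self, q):
        pr = self.priors
        a, raw, logs1, logs2, t, Z = self.unpack(q)
        s1, s2 = np.exp(logs1), np.exp(logs2)
        r = float(np.clip(np.tanh(t), -1 + 1e-10, 1 - 1e-10))
        C = self._trait_chol(s1, s2, r)
        M = self.L @ Z  # (n, 2)
        U = M @ C.T
        eta1 = a + U[:, 0]
        eta2 = U[:, 1]
        alpha = likelihoods.ordered_from_raw(raw)

        ll1, g1 = likelihoods.bernoulli_logit(self.y1, eta1, self.mask1)
        ll2, g2, g_alpha = likelihoods.ordinal_logit(self.y2, eta2, alpha, self.mask2)
        lp = ll1 + ll2

        # priors
        lp += -0.5 * a ** 2 / pr.intercept_sd ** 2
        lp += -0.5 * np.sum(alpha ** 2) / pr.cutpoint_sd ** 2
        lp += likelihoods.ordered_log_jacobian(raw)
        lp += -0.5 * (s1 ** 2 + s2 ** 2) / pr.re_scale_sd ** 2 + logs1 + logs2
        lp += self.lkj_eta * np.log1p(-r ** 2)  # LKJ(eta) density + tanh Jacobian
        lp += -0.5 * np.sum(Z * Z)

        G = np.column_stack([g1, g2])  # dll/dU
        grad = np.zeros_like(q)
        grad[0] = g1.sum() - a / pr.intercept_sd ** 2
        g_alpha = g_alpha - alpha / pr.cutpoint_sd ** 2
        grad[1:1 + self.n_cut] = likelihoods.ordered_transform_grad(g_alpha, raw)

        gC = G.T @ M  # (2, 2): dll/dC
        w = np.sqrt(1.0 - r ** 2)
        # chain rule into (logs1, logs2, t)
        g_logs1 = gC[0, 0] * s1 - s1 ** 2 / pr.re_scale_sd ** 2 + 1.0
        g_logs2 = (gC[1, 0] * r + gC[1, 1] * w) * s2 - s2 ** 2 / pr.re_scale_sd ** 2 + 1.0
        dC_dr = np.array([[0.0, 0.0], [s2, -r / w * s2]])
        g_t = np.sum(gC * dC_dr) * (1.0 - r ** 2) - 2.0 * self.lkj_eta * r
        grad[1 + self.n_cut:4 + self.n_cut] = (g_logs1, g_logs2, g_t)

        gZ = self.L.T @ (G @ C) - Z
        grad[4 + self.n_cut:] = gZ.ravel()
        return lp, grad

    def initial(self, rng):
        q = 0.1 * rng.standard_normal(self.dim)
        yv = self.y2[self.mask2].astype(int)
        counts = np.bincount(yv, minlength=self.K).astype(float) + 0.5
        cum = np.cumsum(counts)[:-1] / counts.sum()
        alpha = np.log(cum / (1 - cum))
        q[1] = alpha[0]
        q[2:1 + self.n_cut] = np.log(np.clip(np.diff(alpha), 1e-3, None))
        q[1 + self.n_cut] = np.log(0.5)
        q[2 + self.n_cut] = np.log(0.5)
        q[3 + self.n_cut] = 0.0
        return q


def fit_bivariate_latent(
    table: SocietyTable,
    trait: str,
    trees: PhyloSet,
    taxon_map: TaxonMap,
    sampler_cfg: SamplerConfig = SamplerConfig(),
    prior_cfg: PriorConfig = PriorConfig(intercept_sd=2.5),
    n_trees: int | None = None,
    binary_trait: str = "kava",
) -> PosteriorSummary:
    """Fit the bivariate latent model per tree and pool the draws.

    ``trait`` is the ordinal trait paired with the binary trait.  Missing
    trait values are marginalized (their latent values stay in the model).
    Fits one model per tree (optionally subsampled to ``n_trees``) and
    concatenates draws with equal weight; the pooled summary is invariant
    to tree order.
    """
    if trait not in ("political_complexity", "social_stratification"):
        raise ConfigError(f"{trait!r} is not an ordinal trait")
    ids = table.society_ids
    tip_to_soc = taxon_map.tip_to_society()
    y1 = table.trait(binary_trait)
    y2 = table.trait(trait)
    mask1 = ~np.isnan(y1)
    mask2 = ~np.isnan(y2)
    logger.info("marginalizing %d missing %s and %d missing %s values",
                (~mask1).sum(), binary_trait, (~mask2).sum(), trait)

    use_trees = trees.trees if n_trees is None else trees.trees[:n_trees]
    frames = []
    total_div = 0
    for t_idx, tree in enumerate(use_trees):
        if sum(1 for _ in tree.leaf_node_iter()) < 2:
            raise DegenerateInputError(f"tree {t_idx} has fewer than 2 tips")
        spec = kernels.phylo_correlation(tree).rename(tip_to_soc).align(ids)
        model = _BivariateLatentModel(y1, mask1, y2, mask2, spec.cholesky(), prior_cfg)
        cfg = replace(sampler_cfg, seed=(sampler_cfg.seed or 0) + 1000 * t_idx)
        draws3, diag = sample_hmc(model.logp_grad, model.initial, cfg)
        total_div += diag["divergences"]
        n_chain, n_draw, _ = draws3.shape
        flat = draws3.reshape(-1, model.dim)
        logs1 = flat[:, 1 + model.n_cut]
        logs2 = flat[:, 2 + model.n_cut]
        t_r = flat[:, 3 + model.n_cut]
        df = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(n_chain), n_draw),
                "tree": t_idx,
                "intercept": flat[:, 0],
                "sigma_phylo_binary": np.exp(logs1),
                "sigma_phylo_ordinal": np.exp(logs2),
                "r": np.tanh(t_r),
            }
        )
        raw = flat[:, 1:1 + model.n_cut]
        alpha_draws = np.column_stack(
            [raw[:, :1], raw[:, :1] + np.cumsum(np.exp(raw[:, 1:]), axis=1)])
        for k in range(1, model.n_cut + 1):
            df[f"alpha[{k}]"] = alpha_draws[:, k - 1]
        frames.append(df)
    draws = pd.concat(frames, ignore_index=True)
    draws["lambda_binary"] = _lambda(draws["sigma_phylo_binary"].to_numpy())
    draws["lambda_ordinal"] = _lambda(draws["sigma_phylo_ordinal"].to_numpy())

    main = ["intercept", "sigma_phylo_binary", "sigma_phylo_ordinal", "r",
            "lambda_binary", "lambda_ordinal"]
    summary = summarize_draws(draws[main])
    check_convergence(summary.iloc[:4], total_div,
                      sampler_cfg.rhat_threshold, n_total=len(draws))
    meta = {
        "trait_pair": (binary_trait, trait),
        "n_trees": len(use_trees),
        "missing": {binary_trait: int((~mask1).sum()), trait: int((~mask2).sum())},
        "prior_cfg": prior_cfg,
    }
    return PosteriorSummary(draws, summary, {"divergences": total_div}, meta)


def _lambda(sigma: np.ndarray) -> np.ndarray:
    v = sigma ** 2
    return v / (v + LOGIT_RESIDUAL_VAR)


def phylogenetic_signal(post: PosteriorSummary, trait: str) -> SignalEstimate:
    """Variance-partition phylogenetic signal for one trait of a bivariate fit.

    ``lambda = sigma_phylo^2 / (sigma_phylo^2 + pi^2/3)`` per draw; draws lie
    in [0, 1] by construction.
    """
    binary_trait, ordinal_trait = post.meta["trait_pair"]
    if trait == binary_trait:
        sigma = post.param("sigma_phylo_binary")
    elif trait == ordinal_trait:
        sigma = post.param("sigma_phylo_ordinal")
    else:
        raise ConfigError(f"trait {trait!r} not in fitted pair {post.meta['trait_pair']}")
    lam = _lambda(sigma)
    row = summarize_draws(lam[None, :, None], [f"lambda_{trait}"]).iloc[0]
    return SignalEstimate(trait, lam, row)


def phylo_correlation_estimate(post: PosteriorSummary) -> PhyloCorrelation:
    """Cross-trait phylogenetic random-effect correlation."""
    r = post.param("r")
    row = summarize_draws(r[None, :, None], ["r"]).iloc[0]
    return PhyloCorrelation(post.meta["trait_pair"], r, row)
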