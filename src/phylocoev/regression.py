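"""Bayesian ordinal / binary regressions with structured random effects.

The response is either a 5-level ordinal trait (cumulative-logit family:
``P(y <= k) = logistic(alpha_k - mu)`` with ordered cutpoints ``alpha``) or a
binary trait (Bernoulli-logit).  Society-level random effects enter the
latent predictor as ``sigma_s * L_s z_s`` with ``L_s`` the Cholesky factor
of a phylogenetic or spatial correlation matrix and ``z_s ~ N(0, I)``
(non-centered).  When both structures are present they enter additively
with independent scales.  Rows with a missing response or predictor are
excluded per model (complete-case) and the exclusion counts logged.

Default regularizing priors: slope ~ N(0, 2.5), cutpoints ~ N(0, 4)
(ordered), random-effect scale ~ half-N(0, 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from . import kernels
from .data_model import ORDINAL_LEVELS, SocietyTable
from .exceptions import AlignmentError, ConfigError, SchemaError, ValidationError
from .mcmc import SamplerConfig, check_convergence, sample_hmc, summarize_draws

logger = logging.getLogger(__name__)

__all__ = [
    "PriorConfig",
    "RegressionSpec",
    "PosteriorSummary",
    "fit_structured_regression",
    "ordinal_category_probs",
    "predicted_contrast",
    "rho_sensitivity",
]


@dataclass(frozen=True)
class PriorConfig:
    slope_sd: float = 2.5
    cutpoint_sd: float = 4.0
    intercept_sd: float = 4.0
    re_scale_sd: float = 1.0  # half-normal


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress on what, with which structured controls."""

    response: str
    predictors: tuple[str, ...] = ("kava",)
    family: str | None = None  # auto: bernoulli for binary response, else cumulative
    random_structures: tuple[str, ...] = ()
    kernel_cfg: kernels.KernelConfig = field(default_factory=kernels.KernelConfig)
    prior_cfg: PriorConfig = field(default_factory=PriorConfig)
    sampler_cfg: SamplerConfig = field(default_factory=SamplerConfig)
    n_levels: int = ORDINAL_LEVELS
    fixed_re_scale: float | None = None  # testing hook: clamp all RE scales

    def resolved_family(self) -> str:
        if self.family is not None:
            if self.family not in ("cumulative_logit", "bernoulli_logit"):
                raise ConfigError(f"unknown family {self.family!r}")
            return self.family
        return "bernoulli_logit" if self.response == "kava" else "cumulative_logit"


@dataclass
class PosteriorSummary:
    """Posterior draws plus the standard summary table and diagnostics."""

    draws: pd.DataFrame  # one row per draw; includes a 'chain' column
    summary: pd.DataFrame
    diagnostics: dict
    meta: dict

    def param(self, name: str) -> np.ndarray:
        if name not in self.draws.columns:
            raise KeyError(f"no parameter {name!r}; have {list(self.draws.columns)}")
        return self.draws[name].to_numpy(dtype=float)


def ordinal_category_probs(latent_mean, alpha) -> np.ndarray:
    """Category probabilities of the cumulative-logit model.

    ``P(y = k) = logistic(alpha_k - mu) - logistic(alpha_{k-1} - mu)`` with
    ``alpha_0 = -inf`` and ``alpha_K = +inf``.  ``latent_mean`` may be scalar
    or an array; the last axis of the result indexes the K categories.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or np.any(np.diff(alpha) <= 0):
        raise ValidationError("cutpoints must be a strictly increasing vector")
    mu = np.atleast_1d(np.asarray(latent_mean, dtype=float))
    cum = expit(alpha[None, :] - mu[..., None])
    ones = np.ones(mu.shape + (1,))
    zeros = np.zeros(mu.shape + (1,))
    cdf = np.concatenate([zeros, cum, ones], axis=-1)
    probs = np.diff(cdf, axis=-1)
    if np.isscalar(latent_mean) or np.asarray(latent_mean).ndim == 0:
        return probs[0]
    return probs


# ---------------------------------------------------------------------------
# log posterior with analytic gradient
# ---------------------------------------------------------------------------

class _StructuredGLM:
    """Joint log density and gradient for the structured regression."""

    def __init__(self, y, X, family, n_levels, chols, priors, fixed_re_scale=None):
        self.y = np.asarray(y, dtype=int)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.family = family
        self.K = n_levels
        self.chols = chols  # list of (name, L) pairs
        self.priors = priors
        self.fixed_re_scale = fixed_re_scale
        self.n_cut = (n_levels - 1) if family == "cumulative_logit" else 0
        self.n_int = 1 if family == "bernoulli_logit" else 0
        self.sample_scales = fixed_re_scale is None
        per_struct = (1 if self.sample_scales else 0) + self.n
        self.dim = self.p + self.n_cut + self.n_int + per_struct * len(chols)
        if family == "cumulative_logit":
            yv = self.y
            self._up_idx = np.where(yv < self.K - 1, yv, 0)
            self._lo_idx = np.where(yv > 0, yv - 1, 0)
            self._has_up = yv < self.K - 1
            self._has_lo = yv > 0

    # layout: [beta | cut_raw or intercept | (logsigma, z) per structure]
    def unpack(self, q):
        pos = 0
        beta = q[pos:pos + self.p]; pos += self.p
        head = q[pos:pos + self.n_cut + self.n_int]; pos += self.n_cut + self.n_int
        structs = []
        for _name, L in self.chols:
            if self.sample_scales:
                logsig = q[pos]; pos += 1
            else:
                logsig = None
            z = q[pos:pos + self.n]; pos += self.n
            structs.append((logsig, z))
        return beta, head, structs

    @staticmethod
    def _alpha_from_raw(raw):
        alpha = np.empty_like(raw)
        alpha[0] = raw[0]
        if raw.size > 1:
            alpha[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
        return alpha

    def logp_grad(self, q):
        with np.errstate(over="ignore", invalid="ignore"):
            return self._logp_grad(q)

    def _logp_grad(self, q):
        pr = self.priors
        beta, head, structs = self.unpack(q)
        grad = np.zeros_like(q)
        mu = self.X @ beta
        sig = []
        lz = []
        for (logsig, z), (_name, L) in zip(structs, self.chols):
            s = np.exp(logsig) if logsig is not None else self.fixed_re_scale
            v = L @ z
            mu = mu + s * v
            sig.append(s)
            lz.append(v)

        lp = 0.0
        if self.family == "cumulative_logit":
            alpha = self._alpha_from_raw(head)
            a_up = np.where(self._has_up, alpha[self._up_idx], np.inf)
            a_lo = np.where(self._has_lo, alpha[self._lo_idx], -np.inf)
            F_up = np.where(self._has_up, expit(a_up - mu), 1.0)
            F_lo = np.where(self._has_lo, expit(a_lo - mu), 0.0)
            p_obs = np.clip(F_up - F_lo, 1e-300, None)
            lp += np.sum(np.log(p_obs))
            f_up = np.where(self._has_up, F_up * (1.0 - F_up), 0.0)
            f_lo = np.where(self._has_lo, F_lo * (1.0 - F_lo), 0.0)
            gmu = (f_lo - f_up) / p_obs
            galpha = np.zeros(self.n_cut)
            np.add.at(galpha, self._up_idx[self._has_up],
                      (f_up / p_obs)[self._has_up])
            np.add.at(galpha, self._lo_idx[self._has_lo],
                      (-f_lo / p_obs)[self._has_lo])
            # prior on cutpoint values
            lp += -0.5 * np.sum(alpha ** 2) / pr.cutpoint_sd ** 2
            galpha += -alpha / pr.cutpoint_sd ** 2
            # chain through the ordered transform + log-Jacobian
            graw = np.zeros(self.n_cut)
            graw[0] = galpha.sum()
            if self.n_cut > 1:
                rev = np.cumsum(galpha[::-1])[::-1]
                graw[1:] = np.exp(head[1:]) * rev[1:] + 1.0
                lp += np.sum(head[1:])
        else:
            intercept = head[0]
            eta = mu + intercept
            lp += np.sum(np.where(self.y == 1, log_expit(eta), log_expit(-eta)))
            gmu = self.y - expit(eta)
            lp += -0.5 * intercept ** 2 / pr.intercept_sd ** 2
            graw = np.array([gmu.sum() - intercept / pr.intercept_sd ** 2])
            gmu = gmu.copy()

        # slopes
        lp += -0.5 * np.sum(beta ** 2) / pr.slope_sd ** 2
        gbeta = self.X.T @ gmu - beta / pr.slope_sd ** 2

        pos = 0
        grad[pos:pos + self.p] = gbeta; pos += self.p
        grad[pos:pos + graw.size] = graw; pos += graw.size
        for (logsig, z), (_name, L), s, v in zip(structs, self.chols, sig, lz):
            if self.sample_scales:
                # half-normal prior on s with log transform (+ Jacobian)
                lp += -0.5 * s ** 2 / pr.re_scale_sd ** 2 + logsig
                grad[pos] = s * np.dot(gmu, v) - s ** 2 / pr.re_scale_sd ** 2 + 1.0
                pos += 1
            lp += -0.5 * np.dot(z, z)
            grad[pos:pos + self.n] = s * (L.T @ gmu) - z
            pos += self.n
        return lp, grad

    def initial(self, rng):
        q = 0.1 * rng.standard_normal(self.dim)
        if self.family == "cumulative_logit":
            counts = np.bincount(self.y, minlength=self.K).astype(float) + 0.5
            cum = np.cumsum(counts)[:-1] / counts.sum()
            alpha = np.log(cum / (1 - cum))
            q[self.p] = alpha[0]
            if self.n_cut > 1:
                q[self.p + 1:self.p + self.n_cut] = np.log(
                    np.clip(np.diff(alpha), 1e-3, None))
        pos = self.p + self.n_cut + self.n_int
        for _ in self.chols:
            if self.sample_scales:
                q[pos] = np.log(0.5) + 0.1 * rng.standard_normal()
                pos += 1
            pos += self.n
        return q

    def names(self, xnames, struct_names):
        out = [f"b_{x}" for x in xnames]
        if self.family == "cumulative_logit":
            out += [f"alpha[{k}]" for k in range(1, self.n_cut + 1)]
        else:
            out += ["b_intercept"]
        for name in struct_names:
            if self.sample_scales:
                out += [f"sigma_{name}"]
            out += [f"z_{name}[{i}]" for i in range(self.n)]
        return out


def _complete_case(table: SocietyTable, columns: Sequence[str]):
    cols = []
    for c in columns:
        cols.append(table.trait(c))
    mask = ~np.any([np.isnan(v) for v in cols], axis=0)
    return mask


def fit_structured_regression(
    table: SocietyTable,
    spec: RegressionSpec,
    cov: Sequence[kernels.CovarianceSpec] = (),
) -> PosteriorSummary:
    """Fit the structured regression and return draws + summaries.

    ``cov`` supplies one :class:`~phylocoev.kernels.CovarianceSpec` per entry
    of ``spec.random_structures`` (matched by ``kind``); labels must cover
    the societies retained after complete-case filtering.
    """
    family = spec.resolved_family()
    used_cols = (spec.response, *spec.predictors)
    mask = _complete_case(table, used_cols)
    n_excluded = int((~mask).sum())
    if n_excluded:
        logger.info(
            "excluding %d rows with missing %s", n_excluded, list(used_cols)
        )
    sub = table.data.loc[mask]
    ids = sub["society_id"].astype(str).tolist()
    y = sub[spec.response].to_numpy(dtype=float)
    if family == "cumulative_logit":
        y = y.astype(int)
    else:
        y = y.astype(int)
    X = np.column_stack([sub[p].to_numpy(dtype=float) for p in spec.predictors])

    by_kind = {c.kind: c for c in cov}
    chols = []
    for s in spec.random_structures:
        if s not in by_kind:
            raise AlignmentError(
                f"no covariance of kind {s!r} supplied (have {list(by_kind)})"
            )
        chols.append((s, by_kind[s].align(ids).cholesky()))

    model = _StructuredGLM(
        y, X, family, spec.n_levels, chols, spec.prior_cfg,
        fixed_re_scale=spec.fixed_re_scale,
    )
    draws3, diag = sample_hmc(model.logp_grad, model.initial, spec.sampler_cfg)
    names = model.names(spec.predictors, [s for s, _ in chols])
    n_chain, n_draw, dim = draws3.shape
    flat = draws3.reshape(-1, dim)

    # transform to interpretable scale: cut_raw -> alpha, logsigma -> sigma
    out = pd.DataFrame(flat, columns=names)
    if family == "cumulative_logit":
        acols = [f"alpha[{k}]" for k in range(1, model.n_cut + 1)]
        raw = out[acols].to_numpy()
        alpha = np.column_stack(
            [raw[:, 0]] + [raw[:, 0] + np.cumsum(np.exp(raw[:, 1:]), axis=1)[:, k - 1]
                           for k in range(1, model.n_cut)]
        )
        out[acols] = alpha
    for s, _ in chols:
        if model.sample_scales:
            out[f"sigma_{s}"] = np.exp(out[f"sigma_{s}"])
    out.insert(0, "chain", np.repeat(np.arange(n_chain), n_draw))

    main = [c for c in out.columns if not c.startswith("z_") and c != "chain"]
    arr = out[main].to_numpy().reshape(n_chain, n_draw, len(main))
    summary = summarize_draws(arr, main)
    check_convergence(summary, diag["divergences"],
                      spec.sampler_cfg.rhat_threshold,
                      n_total=n_chain * n_draw)

    re_offset = np.zeros((len(out), len(ids)))
    for s, L in chols:
        zcols = [f"z_{s}[{i}]" for i in range(len(ids))]
        sigma = (out[f"sigma_{s}"].to_numpy()[:, None]
                 if model.sample_scales else spec.fixed_re_scale)
        re_offset += sigma * (out[zcols].to_numpy() @ L.T)

    meta = {
        "spec": spec,
        "family": family,
        "predictors": list(spec.predictors),
        "X": X,
        "society_ids": ids,
        "n_excluded": n_excluded,
        "n_used": len(ids),
        "re_offset": re_offset,
        "n_levels": spec.n_levels,
        "prior_cfg": spec.prior_cfg,
    }
    return PosteriorSummary(out, summary, diag, meta)


def predicted_contrast(post: PosteriorSummary, predictor: str):
    """Expected change on the original ordinal scale when ``predictor`` flips 0->1.

    Per draw the fitted expected category value (sum_k k * p_k, including
    each society's random-effect offset) is averaged over the observed
    societies with the predictor set to 1 and to 0; the difference is the
    sample-average marginal contrast.  Returns ``(draws, summary_row)``.
    """
    meta = post.meta
    if meta["family"] != "cumulative_logit":
        raise ConfigError("predicted_contrast requires a cumulative-logit fit")
    if predictor not in meta["predictors"]:
        raise SchemaError(f"predictor {predictor!r} not in model {meta['predictors']}")
    j = meta["predictors"].index(predictor)
    X = meta["X"]
    K = meta["n_levels"]
    acols = [f"alpha[{k}]" for k in range(1, K)]
    alpha = post.draws[acols].to_numpy()  # (D, K-1)
    beta = post.draws[[f"b_{p}" for p in meta["predictors"]]].to_numpy()  # (D, p)
    off = meta["re_offset"]  # (D, n)

    def expected(x_value):
        Xc = X.copy()
        Xc[:, j] = x_value
        mu = beta @ Xc.T + off  # (D, n)
        cum = expit(alpha[:, None, :] - mu[:, :, None])  # (D, n, K-1)
        cdf = np.concatenate(
            [np.zeros(mu.shape + (1,)), cum, np.ones(mu.shape + (1,))], axis=-1
        )
        probs = np.diff(cdf, axis=-1)
        scale = np.arange(K)
        return (probs * scale).sum(axis=-1).mean(axis=1)  # (D,)

    contrast = expected(1.0) - expected(0.0)
    row = summarize_draws(contrast[None, :, None], ["contrast"]).iloc[0]
    return contrast, row


def rho_sensitivity(
    table: SocietyTable,
    spec: RegressionSpec,
    rhos: Sequence[float],
    extra_cov: Sequence[kernels.CovarianceSpec] = (),
):
    """Refit the model across a grid of spatial decay lengths ``rho``.

    Returns ``(table, fits)`` where ``table`` has one row per rho with the
    kava-slope posterior mean and CI bounds.
    """
    if len(rhos) == 0:
        raise ConfigError("empty rho grid")
    if "spatial" not in spec.random_structures:
        raise ConfigError("rho_sensitivity requires 'spatial' in random_structures")
    rows = []
    fits = {}
    for rho in rhos:
        cfg = replace(spec.kernel_cfg, rho=rho)
        cov = [kernels.spatial_covariance(table, cfg), *extra_cov]
        fit = fit_structured_regression(table, replace(spec, kernel_cfg=cfg), cov)
        slope = f"b_{spec.predictors[0]}"
        row = fit.summary.set_index("parameter").loc[slope]
        rows.append({"rho": rho, "parameter": slope, **row.to_dict()})
        fits[rho] = fit
    return pd.DataFrame(rows), fits
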