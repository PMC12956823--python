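"""Observation-layer log likelihoods with analytic gradients.

Shared by the bivariate signal model and the dynamic coevolution model.
Missing observations are handled with a boolean mask: masked entries
contribute zero log-likelihood and zero gradient (the latent values remain
in the model and are marginalized by the sampler).
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit

from .exceptions import ValidationError


def bernoulli_logit(y, eta, mask=None):
    """Bernoulli log likelihood on the logit scale.

    Returns ``(ll, dll_deta)``; entries where ``mask`` is False contribute 0.
    """
    y = np.asarray(y)
    eta = np.asarray(eta, dtype=float)
    if mask is None:
        mask = np.ones(eta.shape, dtype=bool)
    yv = np.where(mask, y, 0.0).astype(float)
    ll_terms = np.where(yv == 1, log_expit(eta), log_expit(-eta))
    g = np.where(mask, yv - expit(eta), 0.0)
    ll = float(np.sum(np.where(mask, ll_terms, 0.0)))
    return ll, g


def ordinal_logit(y, eta, alpha, mask=None):
    """Cumulative-logit log likelihood: P(y <= k) = logistic(alpha_k - eta).

    ``y`` holds integer categories 0..K-1 (any value where masked).  Returns
    ``(ll, dll_deta, dll_dalpha)``.
    """
    alpha = np.asarray(alpha, dtype=float)
    # ties can arise from underflowed increments during sampler exploration;
    # they yield zero-probability categories (clipped below), which the
    # sampler rejects — only genuinely decreasing cutpoints are an error
    if np.any(np.diff(alpha) < 0):
        raise ValidationError("cutpoints must be increasing")
    eta = np.asarray(eta, dtype=float)
    K = alpha.size + 1
    if mask is None:
        mask = np.ones(eta.shape, dtype=bool)
    yv = np.where(mask, np.asarray(y), 0).astype(int)
    if mask.any() and (yv[mask].min() < 0 or yv[mask].max() > K - 1):
        raise ValidationError(f"ordinal values outside 0..{K - 1}")
    has_up = yv < K - 1
    has_lo = yv > 0
    up_idx = np.where(has_up, yv, 0)
    lo_idx = np.where(has_lo, yv - 1, 0)
    F_up = np.where(has_up, expit(alpha[up_idx] - eta), 1.0)
    F_lo = np.where(has_lo, expit(alpha[lo_idx] - eta), 0.0)
    p = np.clip(F_up - F_lo, 1e-300, None)
    ll = float(np.sum(np.where(mask, np.log(p), 0.0)))
    f_up = np.where(has_up, F_up * (1 - F_up), 0.0)
    f_lo = np.where(has_lo, F_lo * (1 - F_lo), 0.0)
    g_eta = np.where(mask, (f_lo - f_up) / p, 0.0)
    g_alpha = np.zeros(K - 1)
    sel_up = mask & has_up
    sel_lo = mask & has_lo
    np.add.at(g_alpha, up_idx[sel_up], (f_up / p)[sel_up])
    np.add.at(g_alpha, lo_idx[sel_lo], (-f_lo / p)[sel_lo])
    return ll, g_eta, g_alpha


def ordered_from_raw(raw):
    """Map unconstrained raw vector to strictly increasing cutpoints."""
    raw = np.asarray(raw, dtype=float)
    alpha = np.empty_like(raw)
    alpha[0] = raw[0]
    if raw.size > 1:
        alpha[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
    return alpha


def raw_from_ordered(alpha):
    alpha = np.asarray(alpha, dtype=float)
    raw = np.empty_like(alpha)
    raw[0] = alpha[0]
    if alpha.size > 1:
        raw[1:] = np.log(np.diff(alpha))
    return raw


def ordered_transform_grad(g_alpha, raw, include_jacobian=True):
    """Chain a gradient w.r.t. cutpoints back to the raw parameterization.

    Adds the gradient of the transform's log-Jacobian (sum of raw[1:]) when
    ``include_jacobian``.
    """
    g_alpha = np.asarray(g_alpha, dtype=float)
    raw = np.asarray(raw, dtype=float)
    g_raw = np.zeros_like(raw)
    g_raw[0] = g_alpha.sum()
    if raw.size > 1:
        rev = np.cumsum(g_alpha[::-1])[::-1]
        g_raw[1:] = np.exp(raw[1:]) * rev[1:]
        if include_jacobian:
            g_raw[1:] += 1.0
    return g_raw


def ordered_log_jacobian(raw):
    raw = np.asarray(raw, dtype=float)
    return float(raw[1:].sum()) if raw.size > 1 else 0.0
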