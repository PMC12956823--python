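"""Samplers and posterior summaries.

The package fits every model with gradient-based Hamiltonian Monte Carlo
(adaptive step size via dual averaging, diagonal mass-matrix adaptation)
and, for the dynamic coevolution model, an adaptive random-walk Metropolis
update for the low-dimensional structural-parameter block interleaved with
HMC on the latent field.  All samplers are plain numpy and fully seeded.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import ConvergenceWarning

__all__ = [
    "SamplerConfig",
    "sample_hmc",
    "AdaptiveMH",
    "DualAveraging",
    "split_rhat",
    "ess_bulk",
    "summarize_draws",
]

_DIVERGENCE_ENERGY = 1000.0


@dataclass(frozen=True)
class SamplerConfig:
    """Chain/draw settings shared by all model fits."""

    chains: int = 2
    draws: int = 500
    warmup: int = 500
    seed: int | None = None
    target_accept: float = 0.85
    max_leapfrog: int = 64
    path_length: float = 1.5
    mh_sweeps: int = 3  # structural-parameter MH updates per iteration (blocked sampler)
    rhat_threshold: float = 1.01

    def rng(self, chain: int = 0) -> np.random.Generator:
        seed = self.seed if self.seed is not None else np.random.SeedSequence().entropy
        return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**63), chain]))


class DualAveraging:
    """Nesterov dual averaging of log step size (Stan's defaults)."""

    def __init__(self, eps0: float, target: float = 0.85,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = math.log(eps0)
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_prob: float) -> float:
        self.t += 1
        eta = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_prob)
        self.log_eps = self.mu - math.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    def restart(self, eps0: float) -> None:
        self.mu = math.log(10.0 * eps0)
        self.log_eps = math.log(eps0)
        self.log_eps_bar = math.log(eps0)
        self.h_bar = 0.0
        self.t = 0

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)

    @property
    def current(self) -> float:
        return math.exp(self.log_eps)


def leapfrog(q, p, grad, logp_grad, eps, n_steps, inv_mass):
    """Standard leapfrog integrator; returns (q, p, logp, grad, diverged)."""
    with np.errstate(over="ignore", invalid="ignore"):
        p = p + 0.5 * eps * grad
        for step in range(n_steps):
            q = q + eps * inv_mass * p
            if not np.all(np.isfinite(q)):
                return q, p, -np.inf, grad, True
            lp, grad = logp_grad(q)
            if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
                return q, p, -np.inf, grad, True
            if step != n_steps - 1:
                p = p + eps * grad
        p = p + 0.5 * eps * grad
    return q, p, lp, grad, False


def hamiltonian(lp, inv_mass, p):
    """Total energy; -inf on kinetic overflow (treated as divergence)."""
    with np.errstate(over="ignore", invalid="ignore"):
        k = 0.5 * float(np.sum(inv_mass * p * p))
    return lp - k if np.isfinite(k) else -np.inf


def _find_initial_eps(q, logp_grad, inv_mass, rng, target=0.85):
    eps = 0.1
    lp0, grad0 = logp_grad(q)
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0 * p0)
    _, p1, lp1, _, div = leapfrog(q, p0, grad0, logp_grad, eps, 1, inv_mass)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1) if not div else -np.inf
    ratio = h1 - h0
    direction = 1 if ratio > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, lp1, _, div = leapfrog(q, p0, grad0, logp_grad, eps, 1, inv_mass)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1) if not div else -np.inf
        ratio = h1 - h0
        if (direction == 1 and ratio <= math.log(0.5)) or (
            direction == -1 and ratio >= math.log(0.5)
        ):
            break
    return max(eps, 1e-8)


def hmc_chain(logp_grad: Callable, init: np.ndarray, cfg: SamplerConfig,
              rng: np.random.Generator):
    """One HMC chain: warmup with step-size and diagonal-mass adaptation."""
    q = np.asarray(init, dtype=float).copy()
    dim = q.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    eps = _find_initial_eps(q, logp_grad, inv_mass, rng, cfg.target_accept)
    da = DualAveraging(eps, target=cfg.target_accept)

    total = cfg.warmup + cfg.draws
    mass_updates = {int(0.4 * cfg.warmup), int(0.75 * cfg.warmup)}
    win_sum = np.zeros(dim)
    win_sq = np.zeros(dim)
    win_n = 0

    draws = np.empty((cfg.draws, dim))
    logps = np.empty(cfg.draws)
    divergences = 0
    accept_sum = 0.0

    for it in range(total):
        warm = it < cfg.warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = hamiltonian(lp, inv_mass, p0)
        jitter = rng.uniform(0.7, 1.3)
        n_steps = int(np.clip(round(jitter * cfg.path_length / eps), 1, cfg.max_leapfrog))
        q1, p1, lp1, grad1, div = leapfrog(q, p0, grad, logp_grad, eps, n_steps, inv_mass)
        h1 = hamiltonian(lp1, inv_mass, p1) if not div else -np.inf
        delta = h1 - h0
        if div or delta < -_DIVERGENCE_ENERGY:
            accept_prob, accept = 0.0, False
            if not warm:
                divergences += 1
        else:
            accept_prob = min(1.0, math.exp(min(delta, 0.0)))
            accept = rng.uniform() < accept_prob
        if accept:
            q, lp, grad = q1, lp1, grad1
        if warm:
            eps = da.update(accept_prob)
            win_sum += q
            win_sq += q * q
            win_n += 1
            if it in mass_updates and win_n > 10:
                var = win_sq / win_n - (win_sum / win_n) ** 2
                var = np.clip(var, 1e-10, None)
                # shrink toward unity for stability with short windows
                inv_mass = (win_n * var + 5.0) / (win_n + 5.0)
                win_sum[:] = 0.0
                win_sq[:] = 0.0
                win_n = 0
                eps = _find_initial_eps(q, logp_grad, inv_mass, rng, cfg.target_accept)
                da.restart(eps)
            if it == cfg.warmup - 1:
                eps = da.adapted
        else:
            accept_sum += accept_prob
            draws[it - cfg.warmup] = q
            logps[it - cfg.warmup] = lp
    return {
        "draws": draws,
        "logp": logps,
        "accept_rate": accept_sum / max(cfg.draws, 1),
        "divergences": divergences,
        "step_size": eps,
        "inv_mass": inv_mass,
    }


def sample_hmc(logp_grad: Callable, init: np.ndarray | Callable, cfg: SamplerConfig):
    """Run ``cfg.chains`` HMC chains; returns stacked draws and diagnostics.

    ``init`` is either a point (jittered per chain) or a callable
    ``init(rng) -> point``.
    """
    chains = []
    for c in range(cfg.chains):
        rng = cfg.rng(c)
        if callable(init):
            q0 = np.asarray(init(rng), dtype=float)
        else:
            q0 = np.asarray(init, dtype=float) + 0.1 * rng.standard_normal(len(init))
        chains.append(hmc_chain(logp_grad, q0, cfg, rng))
    draws = np.stack([ch["draws"] for ch in chains])  # (chain, draw, dim)
    diagnostics = {
        "divergences": int(sum(ch["divergences"] for ch in chains)),
        "accept_rate": float(np.mean([ch["accept_rate"] for ch in chains])),
        "step_size": [float(ch["step_size"]) for ch in chains],
    }
    return draws, diagnostics


class AdaptiveMH:
    """Haario-style adaptive random-walk Metropolis for a small block.

    The proposal is N(q, s^2 * C) with C the running empirical covariance
    (regularized) and log s tuned toward a target acceptance rate during
    warmup only.
    """

    def __init__(self, dim: int, target: float = 0.3, init_scale: float = 0.1):
        self.dim = dim
        self.target = target
        self.log_s = math.log(init_scale)
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.eye(dim) * 1e-4
        self.chol = np.eye(dim)
        self.t = 0

    def _update_moments(self, q: np.ndarray) -> None:
        self.n += 1
        delta = q - self.mean
        self.mean += delta / self.n
        self.m2 += np.outer(delta, q - self.mean)
        if self.n >= 2 * self.dim and self.n % 25 == 0:
            cov = self.m2 / (self.n - 1) + 1e-8 * np.eye(self.dim)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def step(self, q, lp, logp, rng, adapt: bool):
        prop = q + math.exp(self.log_s) * (self.chol @ rng.standard_normal(self.dim))
        lp_prop = logp(prop)
        accept_prob = math.exp(min(0.0, lp_prop - lp)) if np.isfinite(lp_prop) else 0.0
        if rng.uniform() < accept_prob:
            q, lp = prop, lp_prop
        if adapt:
            self.t += 1
            self.log_s += (accept_prob - self.target) / self.t ** 0.6
            self._update_moments(q)
        return q, lp, accept_prob


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction for draws shaped (chain, draw)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([x[:, :n], x[:, n: 2 * n]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _autocov(y: np.ndarray) -> np.ndarray:
    n = y.size
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(y - y.mean(), m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    return acov


def ess_bulk(x: np.ndarray) -> float:
    """Effective sample size via Geyer initial monotone sequence, (chain, draw)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 4:
        return float(m * n)
    acovs = np.stack([_autocov(x[c]) for c in range(m)])
    w = acovs[:, 0].mean()
    b = x.mean(axis=1).var(ddof=1) * n if m > 1 else 0.0
    var_plus = w * (n - 1) / n + b / n
    if var_plus <= 0:
        return float(m * n)
    rho = 1.0 - (w - acovs.mean(axis=0)) / var_plus
    # Geyer: sum consecutive pairs while positive and monotone
    t_sum = 0.0
    prev_pair = np.inf
    for t in range(0, n - 1, 2):
        pair = rho[t] + rho[t + 1] if t + 1 < n else rho[t]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        prev_pair = pair
        t_sum += pair
    tau = max(2.0 * t_sum - 1.0, 1.0 / (m * n))
    return float(m * n / tau)


def summarize_draws(draws, names: list[str] | None = None,
                    ppm_reference: float = 0.0) -> pd.DataFrame:
    """Posterior summary table: mean, median, 66%/95% CIs, PPM, diagnostics.

    ``draws`` is (chain, draw, dim), (draw, dim) or a DataFrame of draws.
    PPM is the fraction of draws strictly greater than ``ppm_reference``.
    """
    if isinstance(draws, pd.DataFrame):
        names = list(draws.columns)
        arr = draws.to_numpy(dtype=float)[None, :, :]
    else:
        arr = np.asarray(draws, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :, None]
        elif arr.ndim == 2:
            arr = arr[None, :, :]
    n_chain, n_draw, dim = arr.shape
    if n_draw == 0:
        raise ValueError("no draws to summarize")
    if names is None:
        names = [f"param_{i}" for i in range(dim)]
    flat = arr.reshape(-1, dim)
    q = np.percentile(flat, [2.5, 17.0, 50.0, 83.0, 97.5], axis=0)
    rows = []
    for j, name in enumerate(names):
        rows.append(
            {
                "parameter": name,
                "mean": flat[:, j].mean(),
                "median": q[2, j],
                "ci66_lower": q[1, j],
                "ci66_upper": q[3, j],
                "ci95_lower": q[0, j],
                "ci95_upper": q[4, j],
                "ppm": float(np.mean(flat[:, j] > ppm_reference)),
                "rhat": split_rhat(arr[:, :, j]) if n_chain * n_draw >= 4 else np.nan,
                "ess": ess_bulk(arr[:, :, j]),
            }
        )
    return pd.DataFrame(rows)


def check_convergence(summary: pd.DataFrame, divergences: int = 0,
                      rhat_threshold: float = 1.01,
                      divergence_fraction: float = 0.0,
                      n_total: int = 1) -> None:
    """Emit :class:`ConvergenceWarning` when diagnostics exceed thresholds."""
    bad = summary.loc[summary["rhat"] > rhat_threshold, "parameter"].tolist()
    if bad:
        warnings.warn(
            f"split R-hat above {rhat_threshold} for: {bad}", ConvergenceWarning,
            stacklevel=2,
        )
    if n_total > 0 and divergences / n_total > max(divergence_fraction, 0.02):
        warnings.warn(
            f"{divergences} divergent transitions out of {n_total}",
            ConvergenceWarning, stacklevel=2,
        )
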