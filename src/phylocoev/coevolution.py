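"""Generalized dynamic phylogenetic model: latent bivariate OU coevolution.

Two latent traits ``eta = (eta_1, eta_2)`` evolve along the branches of a
rooted phylogeny following the stochastic differential equation

    d eta_t = (b + A eta_t) dt + G dW_t,        G G' = Q,

with a 2x2 selection matrix ``A`` (diagonal: autoregressive selection,
off-diagonal: cross-trait selection), continuous-time intercepts ``b`` and
correlated drift ``Q = diag(sigma) R diag(sigma)``.  Tips are observed
through a Bernoulli-logit layer for the binary trait and a cumulative-logit
layer (ordered cutpoints ``alpha``) for the ordinal trait; optional
Matern-3/2 spatial Gaussian-process intercepts enter each trait's
observational predictor.

Priors: b ~ N(0,1); diag(A) ~ N(0,1) truncated negative; off-diag(A) ~
N(0,2); sigma ~ half-N(0,1); R ~ LKJ(4); alpha ~ N(0,2); the root state has
prior N(eta_anc, 1) per trait with eta_anc = 0 (default) or -2 (informed).

Inference is per tree (pooled by concatenation): the latent states are
sampled jointly with the parameters using a non-centered parameterization —
Hamiltonian updates with an analytic tree-backpropagated gradient for the
latent increments, and adaptive random-walk Metropolis updates for the
structural parameter block.  Branch lengths are rescaled to unit tree
height (with a 1e-6 floor) so A and Q are in per-tree-height units.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg

from . import kernels, likelihoods
from .data_model import ORDINAL_LEVELS, PhyloSet, SocietyTable, TaxonMap
from .exceptions import ConfigError, DegenerateInputError, StabilityError, ValidationError
from .mcmc import AdaptiveMH, DualAveraging, SamplerConfig, check_convergence, hamiltonian, leapfrog, summarize_draws
from .regression import PosteriorSummary, PriorConfig

logger = logging.getLogger(__name__)

MIN_BRANCH_FRACTION = 1e-6
_STABILITY_TOL = -1e-8

__all__ = [
    "OUParams",
    "DeltaTheta",
    "TreeIndex",
    "CoevSpec",
    "ou_equilibrium",
    "ou_stationary_cov",
    "ou_transition_moments",
    "tree_latent_loglik",
    "fit_coevolution",
    "delta_theta",
]


# ---------------------------------------------------------------------------
# parameters and closed-form OU quantities
# ---------------------------------------------------------------------------

@dataclass
class OUParams:
    """Structural parameters of the latent bivariate OU process."""

    b: np.ndarray            # (2,) continuous-time intercepts
    A: np.ndarray            # (2,2) selection matrix, diagonal <= 0
    sigma: np.ndarray        # (2,) positive drift scales
    R: np.ndarray            # (2,2) drift correlation
    alpha: np.ndarray        # ordered cutpoints of the ordinal trait
    eta_anc: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).reshape(2)
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(2)
        self.R = np.asarray(self.R, dtype=float).reshape(2, 2)
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.eta_anc = np.asarray(self.eta_anc, dtype=float).reshape(2)
        if np.any(np.diag(self.A) > 0):
            raise ValidationError("diagonal of A must be <= 0 (stationarity)")
        if np.any(self.sigma <= 0):
            raise ValidationError("sigma must be positive")
        if not np.allclose(np.diag(self.R), 1.0) or abs(self.R[0, 1]) > 1:
            raise ValidationError("R must be a correlation matrix")
        if self.alpha.size and np.any(np.diff(self.alpha) <= 0):
            raise ValidationError("cutpoints must be strictly increasing")

    @property
    def Q(self) -> np.ndarray:
        D = np.diag(self.sigma)
        return D @ self.R @ D

    @property
    def G(self) -> np.ndarray:
        return np.linalg.cholesky(self.Q + 1e-12 * np.eye(2))


def _check_stable(A: np.ndarray) -> None:
    eig = np.linalg.eigvals(A)
    if np.max(eig.real) > _STABILITY_TOL:
        raise StabilityError(
            f"selection matrix is not stable (eigenvalues {eig})"
        )


def ou_equilibrium(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Equilibrium trait value theta = -A^-1 b (solves A theta + b = 0)."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_stable(A)
    return np.linalg.solve(A, -b)


def ou_stationary_cov(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Stationary covariance: solves A S + S A' + Q = 0."""
    _check_stable(np.asarray(A, dtype=float))
    S = scipy.linalg.solve_continuous_lyapunov(np.asarray(A, float),
                                               -np.asarray(Q, float))
    return 0.5 * (S + S.T)


def ou_transition_moments(params: OUParams, dt: float, eta_parent):
    """Mean and covariance of eta(child) given eta(parent) along a branch.

    mean = theta + expm(A dt) (eta_parent - theta)
    cov  = S_inf - expm(A dt) S_inf expm(A dt)'
    with S_inf the stationary covariance.
    """
    if dt < 0:
        raise ValidationError("branch length must be nonnegative")
    A = params.A
    _check_stable(A)
    theta = ou_equilibrium(A, params.b)
    E = scipy.linalg.expm(A * dt)
    S = ou_stationary_cov(A, params.Q)
    mean = theta + E @ (np.asarray(eta_parent, float) - theta)
    cov = S - E @ S @ E.T
    return mean, 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------

class TreeIndex:
    """Array view of a rooted tree for the latent model.

    Nodes are numbered in preorder (root = 0) so every parent precedes its
    children; ``levels`` groups nodes by depth for vectorized propagation.
    Edge lengths are rescaled to unit tree height with a minimum-length
    floor of ``MIN_BRANCH_FRACTION``.
    """

    def __init__(self, tree: dendropy.Tree, normalize_height: bool = True):
        nodes = list(tree.preorder_node_iter())
        if sum(1 for n in nodes if n.is_leaf()) < 1:
            raise DegenerateInputError("tree has no tips")
        index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        edge = np.zeros(self.n_nodes)
        depth_level = np.zeros(self.n_nodes, dtype=int)
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                self.parent[i] = index[id(n.parent_node)]
                if n.edge.length is None:
                    raise ValidationError("tree has edges without branch lengths")
                edge[i] = float(n.edge.length)
                depth_level[i] = depth_level[self.parent[i]] + 1
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + edge[i]
        height = depth.max()
        if height <= 0:
            if self.n_nodes > 1:
                raise DegenerateInputError("tree has zero height")
            height = 1.0  # single-node tree: root prior + observations only
        self.height = height
        if normalize_height:
            self.edge = np.maximum(edge / height, MIN_BRANCH_FRACTION)
        else:
            self.edge = np.maximum(edge, MIN_BRANCH_FRACTION * height)
        self.edge[0] = 0.0
        self.tip_indices = np.array([i for i, n in enumerate(nodes) if n.is_leaf()])
        self.tip_labels = [nodes[i].taxon.label if nodes[i].taxon else str(i)
                           for i in self.tip_indices]
        self.levels = [np.flatnonzero(depth_level == lvl)
                       for lvl in range(1, depth_level.max() + 1)]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)


# ---------------------------------------------------------------------------
# branch moments, vectorized over all branches (internal; cross-checked
# against ou_transition_moments in the test suite)
# ---------------------------------------------------------------------------

def _branch_system(A: np.ndarray, b: np.ndarray, Q: np.ndarray, dts: np.ndarray):
    """theta, expm(A dt) and chol(V(dt)) for every branch at once.

    Uses the eigendecomposition of A (possibly complex); valid for any
    stable, diagonalizable A.
    """
    w, S = np.linalg.eig(A)
    if abs(w[0] - w[1]) < 1e-10:
        # defective/near-defective: nudge the diagonal (measure-zero event)
        A = A + np.diag([1e-8, -1e-8])
        w, S = np.linalg.eig(A)
    Sinv = np.linalg.inv(S)
    theta = np.linalg.solve(A, -b)
    Sigma = scipy.linalg.solve_continuous_lyapunov(A, -Q)
    Sigma = 0.5 * (Sigma + Sigma.T)
    ew = np.exp(np.outer(dts, w))                      # (m, 2)
    E = np.einsum("ab,mb,bc->mac", S, ew, Sinv).real   # (m, 2, 2)
    ESE = np.einsum("mab,bc,mdc->mad", E, Sigma, E)
    V = Sigma[None, :, :] - ESE
    l11 = np.sqrt(np.clip(V[:, 0, 0], 1e-14, None))
    l21 = V[:, 1, 0] / l11
    l22 = np.sqrt(np.clip(V[:, 1, 1] - l21 ** 2, 1e-14, None))
    L = np.zeros_like(V)
    L[:, 0, 0] = l11
    L[:, 1, 0] = l21
    L[:, 1, 1] = l22
    return theta, E, L


def propagate_eta(tree: TreeIndex, theta, E, L, eta_anc, z) -> np.ndarray:
    """Non-centered forward pass: latent states at all nodes from increments z."""
    eta = np.empty((tree.n_nodes, 2))
    eta[0] = np.asarray(eta_anc, float) + z[0]
    for lvl in tree.levels:
        par = tree.parent[lvl]
        dev = eta[par] - theta
        eta[lvl] = (theta
                    + np.einsum("mab,mb->ma", E[lvl], dev)
                    + np.einsum("mab,mb->ma", L[lvl], z[lvl]))
    return eta


def backprop_eta(tree: TreeIndex, E, L, g_eta_nodes: np.ndarray):
    """Reverse pass: gradient w.r.t. z given gradient w.r.t. node states."""
    g = g_eta_nodes.copy()
    for lvl in reversed(tree.levels):
        pullback = np.einsum("mba,mb->ma", E[lvl], g[lvl])
        np.add.at(g, tree.parent[lvl], pullback)
    gz = np.einsum("mba,mb->ma", L, g)
    gz[0] = g[0]
    return gz


# ---------------------------------------------------------------------------
# public log density (centered form, used as an oracle-friendly reference)
# ---------------------------------------------------------------------------

def tree_latent_loglik(tree: TreeIndex, params: OUParams, eta: np.ndarray,
                       y_binary, y_ordinal, mask_binary=None, mask_ordinal=None,
                       spatial_effects: np.ndarray | None = None) -> float:
    """Joint log density of latent node states and tip observations.

    Sum of (i) the root prior N(eta_anc, 1) per trait, (ii) branchwise OU
    transition log densities child | parent, and (iii) tip observation log
    likelihoods (Bernoulli-logit for the binary trait, cumulative-logit
    with cutpoints ``alpha`` for the ordinal trait).  ``eta`` is indexed
    like ``tree`` (preorder); tip observations are aligned with
    ``tree.tip_indices``; missing observations contribute zero terms.
    ``spatial_effects`` (n_tips, 2), when given, offsets the observational
    predictors.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (tree.n_nodes, 2):
        raise ValidationError(
            f"eta must have shape ({tree.n_nodes}, 2), got {eta.shape}"
        )
    lp = float(-0.5 * np.sum((eta[0] - params.eta_anc) ** 2) - np.log(2 * np.pi))
    for i in range(1, tree.n_nodes):
        mean, cov = ou_transition_moments(params, tree.edge[i], eta[tree.parent[i]])
        dev = eta[i] - mean
        cov = cov + 1e-14 * np.eye(2)
        (sign, logdet) = np.linalg.slogdet(cov)
        if sign <= 0:
            return -np.inf
        lp += float(-0.5 * (dev @ np.linalg.solve(cov, dev) + logdet)
                    - np.log(2 * np.pi))
    obs = eta[tree.tip_indices]
    if spatial_effects is not None:
        obs = obs + spatial_effects
    ll1, _ = likelihoods.bernoulli_logit(y_binary, obs[:, 0], mask_binary)
    ll2, _, _ = likelihoods.ordinal_logit(y_ordinal, obs[:, 1], params.alpha,
                                          mask_ordinal)
    return lp + ll1 + ll2


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoevSpec:
    """Configuration of a coevolution fit."""

    ordinal_trait: str = "political_complexity"
    binary_trait: str = "kava"
    spatial_control: bool = False
    rho: float = 0.02
    root_prior: str = "default"  # {"default": N(0,1), "informed": N(-2,1)}
    n_trees: int | None = None
    n_levels: int = ORDINAL_LEVELS
    lkj_eta: float = 4.0
    cutpoint_sd: float = 2.0
    offdiag_sd: float = 2.0
    fixed_gp_scale: float | None = None  # testing hook: clamp the GP scales
    sampler_cfg: SamplerConfig = field(default_factory=SamplerConfig)

    def eta_anc(self) -> np.ndarray:
        if self.root_prior == "default":
            return np.zeros(2)
        if self.root_prior == "informed":
            return np.full(2, -2.0)
        raise ConfigError(f"unknown root prior {self.root_prior!r}")


class _CoevModel:
    """Blocked sampler target for one tree.

    Structural block phi: [b(2), log(-A11), log(-A22), A12, A21,
    logsigma(2), t_r, cut_raw(K-1), (log gp_scale(2) if spatial)].
    Latent block z: node increments (n_nodes, 2) then, if spatial,
    GP increments (n_tips, 2).
    """

    def __init__(self, tree: TreeIndex, y1, mask1, y2, mask2, spec: CoevSpec,
                 L_spatial: np.ndarray | None = None):
        self.tree = tree
        self.y1, self.mask1 = y1, mask1
        self.y2, self.mask2 = y2, mask2
        self.spec = spec
        self.K = spec.n_levels
        self.n_cut = self.K - 1
        self.L_spatial = L_spatial
        self.spatial = L_spatial is not None
        self.sample_gp = self.spatial and spec.fixed_gp_scale is None
        self.eta_anc = spec.eta_anc()
        self.dim_phi = 9 + self.n_cut + (2 if self.sample_gp else 0)
        self.dim_z = 2 * tree.n_nodes + (2 * tree.n_tips if self.spatial else 0)

    # ---- phi handling ----
    def unpack_phi(self, phi):
        b = phi[0:2]
        A = np.array([[-math.exp(phi[2]), phi[4]],
                      [phi[5], -math.exp(phi[3])]])
        sigma = np.exp(phi[6:8])
        r = float(np.clip(math.tanh(phi[8]), -1 + 1e-10, 1 - 1e-10))
        raw = phi[9:9 + self.n_cut]
        if self.sample_gp:
            gp = np.exp(phi[9 + self.n_cut:11 + self.n_cut])
        elif self.spatial:
            gp = np.full(2, self.spec.fixed_gp_scale)
        else:
            gp = None
        return b, A, sigma, r, raw, gp

    def phi_logprior(self, phi):
        b, A, sigma, r, raw, gp = self.unpack_phi(phi)
        lp = -0.5 * np.sum(b ** 2)
        # half-normal on -diag(A), log transform Jacobian
        d = np.array([-A[0, 0], -A[1, 1]])
        lp += np.sum(-0.5 * d ** 2 + np.log(d))
        lp += -0.5 * (A[0, 1] ** 2 + A[1, 0] ** 2) / self.spec.offdiag_sd ** 2
        lp += np.sum(-0.5 * sigma ** 2 + np.log(sigma))
        lp += self.spec.lkj_eta * math.log1p(-r ** 2)
        alpha = likelihoods.ordered_from_raw(raw)
        lp += -0.5 * np.sum(alpha ** 2) / self.spec.cutpoint_sd ** 2
        lp += likelihoods.ordered_log_jacobian(raw)
        if self.sample_gp:
            lp += np.sum(-0.5 * gp ** 2 + np.log(gp))
        return lp

    def build_cache(self, phi):
        b, A, sigma, r, raw, gp = self.unpack_phi(phi)
        if A[0, 1] * A[1, 0] >= A[0, 0] * A[1, 1]:  # det <= 0 -> unstable
            return None
        Q = np.diag(sigma) @ np.array([[1.0, r], [r, 1.0]]) @ np.diag(sigma)
        theta, E, L = _branch_system(A, b, Q, self.tree.edge)
        alpha = likelihoods.ordered_from_raw(raw)
        return {"theta": theta, "E": E, "L": L, "alpha": alpha, "gp": gp,
                "A": A, "b": b, "sigma": sigma, "r": r}

    # ---- z handling ----
    def split_z(self, z):
        nz = 2 * self.tree.n_nodes
        z_nodes = z[:nz].reshape(self.tree.n_nodes, 2)
        z_gp = (z[nz:].reshape(self.tree.n_tips, 2) if self.spatial else None)
        return z_nodes, z_gp

    def _observed_eta(self, cache, z_nodes, z_gp):
        eta = propagate_eta(self.tree, cache["theta"], cache["E"], cache["L"],
                            self.eta_anc, z_nodes)
        obs = eta[self.tree.tip_indices].copy()
        if self.spatial:
            gp_eff = cache["gp"] * (self.L_spatial @ z_gp)
            obs += gp_eff
        return eta, obs

    def loglik_given_z(self, cache, z):
        """Observation log likelihood (z-prior terms excluded) for MH on phi."""
        z_nodes, z_gp = self.split_z(z)
        _, obs = self._observed_eta(cache, z_nodes, z_gp)
        ll1, _ = likelihoods.bernoulli_logit(self.y1, obs[:, 0], self.mask1)
        ll2, _, _ = likelihoods.ordinal_logit(self.y2, obs[:, 1], cache["alpha"],
                                              self.mask2)
        return ll1 + ll2

    def phi_logp(self, phi, z):
        cache = self.build_cache(phi)
        if cache is None:
            return -np.inf
        return self.phi_logprior(phi) + self.loglik_given_z(cache, z)

    def z_logp_grad(self, cache, z):
        z_nodes, z_gp = self.split_z(z)
        eta, obs = self._observed_eta(cache, z_nodes, z_gp)
        ll1, g1 = likelihoods.bernoulli_logit(self.y1, obs[:, 0], self.mask1)
        ll2, g2, _ = likelihoods.ordinal_logit(self.y2, obs[:, 1], cache["alpha"],
                                               self.mask2)
        lp = ll1 + ll2 - 0.5 * float(z @ z)
        g_nodes = np.zeros((self.tree.n_nodes, 2))
        g_nodes[self.tree.tip_indices, 0] = g1
        g_nodes[self.tree.tip_indices, 1] = g2
        gz_nodes = backprop_eta(self.tree, cache["E"], cache["L"], g_nodes)
        grad = np.empty_like(z)
        nz = 2 * self.tree.n_nodes
        grad[:nz] = gz_nodes.ravel() - z[:nz]
        if self.spatial:
            g_obs = np.column_stack([g1, g2])
            gz_gp = cache["gp"] * (self.L_spatial.T @ g_obs)
            grad[nz:] = gz_gp.ravel() - z[nz:]
        return lp, grad

    def eta_tips(self, cache, z):
        z_nodes, z_gp = self.split_z(z)
        eta, _ = self._observed_eta(cache, z_nodes, z_gp)
        return eta[self.tree.tip_indices]

    # ---- centered (sufficient) parameterization helpers -------------------
    def z_from_eta(self, cache, eta):
        """Invert the forward pass: increments z and the transition log density.

        Returns ``(z_nodes, lp_trans)`` with ``lp_trans`` the centered OU
        transition density of the node states (root prior included,
        constants dropped).
        """
        theta, E, L = cache["theta"], cache["E"], cache["L"]
        par = self.tree.parent.copy()
        par[0] = 0
        dev = eta - theta - np.einsum("mab,mb->ma", E, eta[par] - theta)
        z = np.empty_like(eta)
        z[:, 0] = dev[:, 0] / L[:, 0, 0]
        z[:, 1] = (dev[:, 1] - L[:, 1, 0] * z[:, 0]) / L[:, 1, 1]
        z[0] = eta[0] - self.eta_anc
        logdet = np.sum(np.log(L[1:, 0, 0]) + np.log(L[1:, 1, 1]))
        lp_trans = -0.5 * float(np.sum(z * z)) - float(logdet)
        return z, lp_trans

    def centered_logp(self, phi, eta, z_gp):
        """prior(phi) + OU transition density of fixed eta + observation terms."""
        cache = self.build_cache(phi)
        if cache is None:
            return -np.inf, None, None
        _z, lp_trans = self.z_from_eta(cache, eta)
        obs = eta[self.tree.tip_indices].copy()
        if self.spatial:
            obs = obs + cache["gp"] * (self.L_spatial @ z_gp)
        ll1, _ = likelihoods.bernoulli_logit(self.y1, obs[:, 0], self.mask1)
        ll2, _, _ = likelihoods.ordinal_logit(self.y2, obs[:, 1], cache["alpha"],
                                              self.mask2)
        return self.phi_logprior(phi) + lp_trans + ll1 + ll2, cache, _z

    def initial_phi(self, rng):
        phi = np.zeros(self.dim_phi)
        phi[0:2] = 0.1 * rng.standard_normal(2)
        phi[2:4] = math.log(0.7) + 0.1 * rng.standard_normal(2)
        phi[4:6] = 0.1 * rng.standard_normal(2)
        phi[6:8] = math.log(0.5)
        phi[8] = 0.0
        yv = self.y2[self.mask2].astype(int)
        counts = np.bincount(yv, minlength=self.K).astype(float) + 0.5
        cum = np.cumsum(counts)[:-1] / counts.sum()
        alpha = np.log(cum / (1 - cum))
        phi[9] = alpha[0]
        phi[10:9 + self.n_cut] = np.log(np.clip(np.diff(alpha), 1e-3, None))
        if self.sample_gp:
            phi[9 + self.n_cut:11 + self.n_cut] = math.log(0.3)
        return phi

    def param_names(self):
        names = ["b[1]", "b[2]", "A[1,1]", "A[2,2]", "A[1,2]", "A[2,1]",
                 "sigma[1]", "sigma[2]", "r"]
        names += [f"alpha[{k}]" for k in range(1, self.n_cut + 1)]
        if self.sample_gp:
            names += ["gp_scale[1]", "gp_scale[2]"]
        return names

    def phi_to_params(self, phi):
        b, A, sigma, r, raw, gp = self.unpack_phi(phi)
        alpha = likelihoods.ordered_from_raw(raw)
        out = [b[0], b[1], A[0, 0], A[1, 1], A[0, 1], A[1, 0],
               sigma[0], sigma[1], r, *alpha]
        if self.sample_gp:
            out += [gp[0], gp[1]]
        return np.array(out)


def _swap_offdiag(phi):
    out = phi.copy()
    out[4], out[5] = phi[5], phi[4]
    return out


def _swap_roles(phi):
    out = phi.copy()
    out[0], out[1] = phi[1], phi[0]      # b
    out[2], out[3] = phi[3], phi[2]      # log(-diag A)
    out[4], out[5] = phi[5], phi[4]      # off-diagonals (transpose)
    out[6], out[7] = phi[7], phi[6]      # log sigma
    return out


def _fit_single_tree(model: _CoevModel, cfg: SamplerConfig, chain: int):
    """Interweaved blocked sampler for one tree.

    Each iteration alternates (i) adaptive MH on the structural block in the
    non-centered parameterization (latent increments fixed), (ii) an HMC
    trajectory on the latent increments, and (iii) adaptive MH on the
    structural block in the centered parameterization (latent states fixed,
    increments recomputed).  The interweaving (ASIS) breaks the strong
    coupling between the OU scales and the latent field.
    """
    rng = cfg.rng(chain)
    phi = model.initial_phi(rng)
    z = 0.1 * rng.standard_normal(model.dim_z)
    cache = model.build_cache(phi)
    mh_nc = AdaptiveMH(model.dim_phi, target=0.3, init_scale=0.05)
    mh_c = AdaptiveMH(model.dim_phi, target=0.3, init_scale=0.05)
    eps = 0.2
    da = DualAveraging(eps, target=cfg.target_accept)
    inv_mass = np.ones(model.dim_z)
    win_sum = np.zeros(model.dim_z)
    win_sq = np.zeros(model.dim_z)
    win_n = 0

    total = cfg.warmup + cfg.draws
    mass_updates = {int(0.4 * cfg.warmup), int(0.75 * cfg.warmup)}
    rows = np.empty((cfg.draws, len(model.param_names())))
    mads = np.empty((cfg.draws, 2))
    sds = np.empty((cfg.draws, 2))
    logps = np.empty(cfg.draws)
    divergences = 0
    nz = 2 * model.tree.n_nodes

    for it in range(total):
        warm = it < cfg.warmup
        # (i) structural block, non-centered: latent increments held fixed
        lp_phi = model.phi_logp(phi, z)
        for _ in range(cfg.mh_sweeps):
            phi, lp_phi, _acc = mh_nc.step(
                phi, lp_phi, lambda p: model.phi_logp(p, z), rng, adapt=warm)
        cache = model.build_cache(phi)

        # (ii) latent block: HMC trajectories given phi
        for _rep in range(2):
            lp_z, grad = model.z_logp_grad(cache, z)
            p0 = rng.standard_normal(model.dim_z) / np.sqrt(inv_mass)
            h0 = hamiltonian(lp_z, inv_mass, p0)
            n_steps = int(np.clip(round(rng.uniform(0.7, 1.3) * cfg.path_length / eps),
                                  1, cfg.max_leapfrog))
            q1, p1, lp1, _g1, div = leapfrog(
                z, p0, grad, lambda q: model.z_logp_grad(cache, q), eps, n_steps,
                inv_mass)
            h1 = hamiltonian(lp1, inv_mass, p1) if not div else -np.inf
            delta = h1 - h0
            if div or delta < -1000.0:
                accept_prob = 0.0
                if not warm:
                    divergences += 1
            else:
                accept_prob = min(1.0, math.exp(min(delta, 0.0)))
                if rng.uniform() < accept_prob:
                    z = q1
            if warm:
                eps = da.update(accept_prob)
                if it == cfg.warmup - 1:
                    eps = da.adapted
        if warm:
            win_sum += z
            win_sq += z * z
            win_n += 1
            if it in mass_updates and win_n > 20:
                var = win_sq / win_n - (win_sum / win_n) ** 2
                inv_mass = np.clip((win_n * var + 5.0) / (win_n + 5.0), 1e-3, 1e3)
                win_sum[:] = 0.0
                win_sq[:] = 0.0
                win_n = 0
                da.restart(max(eps, 1e-4))

        # (iii) structural block, centered: latent states held fixed
        z_nodes, z_gp = model.split_z(z)
        eta = propagate_eta(model.tree, cache["theta"], cache["E"], cache["L"],
                            model.eta_anc, z_nodes)
        lp_c, _, _ = model.centered_logp(phi, eta, z_gp)
        for _ in range(cfg.mh_sweeps):
            phi, lp_c, _acc = mh_c.step(
                phi, lp_c, lambda p: model.centered_logp(p, eta, z_gp)[0],
                rng, adapt=warm)
        # mode-jump moves (involutions with unit Jacobian) so chains can
        # cross between the two direction-attribution modes: (a) transpose
        # the off-diagonals only, (b) mirror the dynamic roles of the two
        # latent traits (transpose A, swap b, diagonal and sigma)
        for swapper in (_swap_offdiag, _swap_roles):
            phi_swap = swapper(phi)
            lp_swap, _, _ = model.centered_logp(phi_swap, eta, z_gp)
            if np.isfinite(lp_swap) and rng.uniform() < math.exp(min(0.0, lp_swap - lp_c)):
                phi, lp_c = phi_swap, lp_swap

        cache = model.build_cache(phi)
        z_new, _lp_trans = model.z_from_eta(cache, eta)
        z[:nz] = z_new.ravel()

        if not warm:
            k = it - cfg.warmup
            rows[k] = model.phi_to_params(phi)
            tips = eta[model.tree.tip_indices]
            med = np.median(tips, axis=0)
            mads[k] = 1.4826 * np.median(np.abs(tips - med), axis=0)
            sds[k] = tips.std(axis=0)
            logps[k] = lp_c
    return rows, mads, sds, logps, divergences


def fit_coevolution(
    table: SocietyTable,
    trees: PhyloSet,
    spec: CoevSpec,
    taxon_map: TaxonMap,
) -> PosteriorSummary:
    """Fit the dynamic coevolution model per tree and pool draws.

    Returns a :class:`PosteriorSummary` whose draws include the structural
    parameters plus per-draw robust scales (``mad_eta1``, ``mad_eta2``,
    ``sd_eta1``, ``sd_eta2``) of the latent tip values, used by
    :func:`delta_theta`.
    """
    ids = table.society_ids
    soc_of_tip = taxon_map.tip_to_society()
    y1_all = dict(zip(ids, table.trait(spec.binary_trait)))
    y2_all = dict(zip(ids, table.trait(spec.ordinal_trait)))

    L_spatial_by_soc = None
    if spec.spatial_control:
        cfg = kernels.KernelConfig(rho=spec.rho)
        spat = kernels.spatial_covariance(table, cfg)
        L_spatial_by_soc = spat

    use_trees = trees.trees if spec.n_trees is None else trees.trees[:spec.n_trees]
    frames = []
    total_div = 0
    for t_idx, tree in enumerate(use_trees):
        index = TreeIndex(tree)
        if index.n_tips < 2:
            raise DegenerateInputError("coevolution fit needs trees with >= 2 tips")
        socs = [soc_of_tip.get(lbl, lbl) for lbl in index.tip_labels]
        y1 = np.array([y1_all[s] for s in socs])
        y2 = np.array([y2_all[s] for s in socs])
        mask1, mask2 = ~np.isnan(y1), ~np.isnan(y2)
        L_spatial = (L_spatial_by_soc.align(socs).cholesky()
                     if spec.spatial_control else None)
        model = _CoevModel(index, y1, mask1, y2, mask2, spec, L_spatial)
        cfg = replace(spec.sampler_cfg,
                      seed=(spec.sampler_cfg.seed or 0) + 1000 * t_idx)
        for chain in range(cfg.chains):
            rows, mads, sds, logps, div = _fit_single_tree(model, cfg, chain)
            total_div += div
            df = pd.DataFrame(rows, columns=model.param_names())
            df.insert(0, "chain", chain)
            df.insert(0, "tree", t_idx)
            df["mad_eta1"], df["mad_eta2"] = mads[:, 0], mads[:, 1]
            df["sd_eta1"], df["sd_eta2"] = sds[:, 0], sds[:, 1]
            df["lp"] = logps
            frames.append(df)
    draws = pd.concat(frames, ignore_index=True)
    main = [c for c in draws.columns
            if c not in ("chain", "tree", "lp")]
    summary = summarize_draws(draws[main])
    n_total = len(draws)
    check_convergence(summary, total_div, spec.sampler_cfg.rhat_threshold,
                      n_total=n_total)
    meta = {
        "spec": spec,
        "n_trees": len(use_trees),
        "trait_pair": (spec.binary_trait, spec.ordinal_trait),
        "missing": {
            spec.binary_trait: int(np.isnan(list(y1_all.values())).sum()),
            spec.ordinal_trait: int(np.isnan(list(y2_all.values())).sum()),
        },
    }
    return PosteriorSummary(draws, summary, {"divergences": total_div}, meta)


@dataclass
class DeltaTheta:
    """Standardized equilibrium shift of trait j per unit increase of trait i."""

    direction: tuple[int, int]
    draws: np.ndarray
    ppm: float
    summary: pd.Series


def delta_theta(post: PosteriorSummary, direction: tuple[int, int] = (1, 2),
                scale: str = "mad") -> DeltaTheta:
    """Equilibrium change of trait j when trait i sits one scaled unit high.

    Per draw: ``delta_theta_j = -A[j,i] * delta_i / A[j,j]`` where
    ``delta_i`` is the robust scale (median absolute deviation by default,
    standard deviation with ``scale="sd"``) of trait i's latent tip values
    in that draw.  PPM is the fraction of draws > 0 (0.5 when the
    off-diagonal is identically zero).
    """
    i, j = direction
    if {i, j} != {1, 2}:
        raise ConfigError("direction must be (1, 2) or (2, 1)")
    if scale not in ("mad", "sd"):
        raise ConfigError(f"unknown scale {scale!r}")
    a_ji = post.param(f"A[{j},{i}]")
    a_jj = post.param(f"A[{j},{j}]")
    col = ("mad" if scale == "mad" else "sd") + f"_eta{i}"
    delta_i = post.param(col)
    if np.any(delta_i == 0):
        raise DegenerateInputError("zero latent scale in some draws")
    d = -a_ji * delta_i / a_jj
    if np.all(a_ji == 0):
        ppm = 0.5
    else:
        ppm = float(np.mean(d > 0))
    row = summarize_draws(d[None, :, None], [f"delta_theta[{i}->{j}]"]).iloc[0]
    return DeltaTheta((i, j), d, ppm, row)
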