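"""Synthetic phylogenies, latent OU trajectories and observed trait tables.

Everything the other modules consume can be generated here with known
ground truth: pure-birth trees (height-normalized), latent bivariate OU
trajectories simulated branchwise with the exact transition moments,
binary/ordinal observations through the same logit observation layers the
fitting code assumes, island-cluster geography with an optional spatial
Gaussian-process confounder, and a full table+tree-sample preset
(``dataset_s1_like``) with 83 societies, two 5-level ordinal traits, an
atoll indicator in {0, 0.5, 1} and the study-like missingness counts
(5 binary, 1 ordinal).

Seeds are split hierarchically (tree / latent / observation / geography)
so components can be varied independently; every generator is
bit-reproducible given (config, seed).
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from types import SimpleNamespace

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.special import expit

from . import kernels
from .coevolution import OUParams, TreeIndex, ou_transition_moments
from .data_model import PhyloSet, SocietyTable, TaxonMap, prune_and_match
from .exceptions import ConfigError

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_ou_tips",
    "latent_to_observed",
    "simulate_geography",
    "dataset_s1_like",
]

DEFAULT_OU = OUParams(
    b=np.array([0.0, 0.0]),
    A=np.array([[-1.0, 0.3], [0.5, -1.0]]),
    sigma=np.array([1.0, 1.0]),
    R=np.array([[1.0, 0.3], [0.3, 1.0]]),
    alpha=np.array([-1.5, -0.5, 0.5, 1.5]),
    eta_anc=np.array([0.0, 0.0]),
)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth settings of a full synthetic dataset."""

    n_tips: int = 83
    birth_rate: float = 1.0
    ou_params: OUParams = field(default_factory=lambda: DEFAULT_OU)
    gp_scale: float = 0.0
    rho: float = 0.02
    missing_binary: int = 0
    missing_ordinal: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ConfigError("n_tips must be >= 3")
        if self.birth_rate <= 0:
            raise ConfigError("birth_rate must be positive")
        if self.missing_binary < 0 or self.missing_ordinal < 0:
            raise ConfigError("missing counts must be nonnegative")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0,
                  tip_labels: list[str] | None = None,
                  pendant_scale_range: tuple[float, float] | None = None) -> dendropy.Tree:
    """Pure-birth tree with ``n_tips`` tips, height rescaled to 1.

    ``pendant_scale_range=(lo, hi)`` multiplies each pendant (tip) edge by an
    independent uniform draw, producing a non-ultrametric tree with tips at
    varying depths (serially-sampled style); directional coevolution is much
    better identified on such trees because the transient mean path varies
    across tips.
    """
    if n_tips < 3:
        raise ConfigError("n_tips must be >= 3")
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(int(seed)),
    )
    tree.is_rooted = True
    height = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height
    if pendant_scale_range is not None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
        lo, hi = pendant_scale_range
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = leaf.edge.length * rng.uniform(lo, hi)
    leaves = list(tree.leaf_node_iter())
    labels = tip_labels or [f"t{i + 1:03d}" for i in range(len(leaves))]
    if len(labels) != len(leaves):
        raise ConfigError(f"need {len(leaves)} tip labels, got {len(labels)}")
    for leaf, label in zip(leaves, labels):
        leaf.taxon.label = label
    return tree


def simulate_ou_tips(tree: dendropy.Tree | TreeIndex, params: OUParams,
                     seed: int, include_internal: bool = False):
    """Latent tip states from recursive parent-to-child OU transition draws.

    Uses the tree's branch lengths as-is (no height rescaling).  Returns
    ``(labels, eta)`` with ``eta`` of shape (n_tips, 2) — or all nodes in
    preorder when ``include_internal``.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, normalize_height=False)
    rng = np.random.default_rng(seed)
    eta = np.empty((index.n_nodes, 2))
    eta[0] = params.eta_anc + rng.standard_normal(2)
    moment_cache: dict[float, tuple] = {}
    for i in range(1, index.n_nodes):
        dt = float(index.edge[i])
        if dt not in moment_cache:
            # mean at eta_parent = 0 and the full covariance characterize the
            # affine transition: mean(eta_p) = mean0 + (theta-shift) * E eta_p
            mean0, cov = ou_transition_moments(params, dt, np.zeros(2))
            mean_unit0, _ = ou_transition_moments(params, dt, np.eye(2)[0])
            mean_unit1, _ = ou_transition_moments(params, dt, np.eye(2)[1])
            E = np.column_stack([mean_unit0 - mean0, mean_unit1 - mean0])
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
            moment_cache[dt] = (mean0, E, L)
        mean0, E, L = moment_cache[dt]
        eta[i] = mean0 + E @ eta[index.parent[i]] + L @ rng.standard_normal(2)
    if include_internal:
        return index, eta
    return index.tip_labels, eta[index.tip_indices]


def latent_to_observed(eta_tips: np.ndarray, alpha: np.ndarray, seed: int,
                       missing_binary: int = 0, missing_ordinal: int = 0):
    """Observe latent tip states through the logit observation layers.

    Binary: ``Bernoulli(logistic(eta_1))``.  Ordinal: cumulative-logit
    categories under cutpoints ``alpha``.  Exactly ``missing_*`` entries are
    masked to NaN (reproducibly under ``seed``).
    """
    from .regression import ordinal_category_probs

    rng_b, rng_o, rng_m = _spawn(seed, 3)
    eta_tips = np.asarray(eta_tips, dtype=float)
    n = eta_tips.shape[0]
    p = expit(eta_tips[:, 0])
    binary = (rng_b.uniform(size=n) < p).astype(float)
    probs = ordinal_category_probs(eta_tips[:, 1], alpha)
    cdf = np.cumsum(probs, axis=-1)
    u = rng_o.uniform(size=n)
    ordinal = (u[:, None] > cdf).sum(axis=1).astype(float)
    if missing_binary:
        idx = rng_m.choice(n, size=missing_binary, replace=False)
        binary[idx] = np.nan
    if missing_ordinal:
        idx = rng_m.choice(n, size=missing_ordinal, replace=False)
        ordinal[idx] = np.nan
    return binary, ordinal


def simulate_geography(n: int, seed: int, gp_scale: float = 0.0,
                       rho: float = 0.02, n_clusters: int = 8):
    """Island-cluster coordinates over a Pacific-like box plus optional GP effect.

    Returns ``(latitude, longitude, effect)`` where ``effect`` is a draw
    from a zero-mean Matern-3/2 Gaussian process over the generated
    coordinates scaled by ``gp_scale`` (identically zero when the scale
    is 0); adding it to both traits' predictors induces spurious spatial
    correlation.
    """
    if n < 2:
        raise ConfigError("need at least 2 societies")
    rng_c, rng_p, rng_g = _spawn(seed, 3)
    centers_lat = rng_c.uniform(-28.0, 15.0, size=n_clusters)
    centers_lon = rng_c.uniform(130.0, 210.0, size=n_clusters)
    which = rng_p.integers(0, n_clusters, size=n)
    lat = np.clip(centers_lat[which] + 2.5 * rng_p.standard_normal(n), -60.0, 60.0)
    lon = centers_lon[which] + 2.5 * rng_p.standard_normal(n)
    lon = (lon + 180.0) % 360.0 - 180.0
    if gp_scale == 0.0:
        return lat, lon, np.zeros(n)
    shim = SimpleNamespace(
        society_ids=[str(i) for i in range(n)], latitude=lat, longitude=lon
    )
    cfg = kernels.KernelConfig(rho=rho)
    K = kernels.matern32(
        kernels.normalize_distances(kernels.haversine_matrix(shim)).to_numpy(), cfg
    )
    L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
    effect = gp_scale * (L @ rng_g.standard_normal(n))
    return lat, lon, effect


def dataset_s1_like(seed: int = 0, n_societies: int = 83, n_trees: int = 100,
                    n_extra_tips: int = 17, ou_params: OUParams = DEFAULT_OU,
                    gp_scale: float = 0.0, rho: float = 0.02,
                    missing_binary: int = 5, missing_ordinal: int = 1,
                    n_half_atolls: int = 7, n_atolls: int = 10):
    """Full emulation preset: trait table + posterior-like tree sample.

    Produces ``n_trees`` pure-birth trees on ``n_societies + n_extra_tips``
    shared tip labels (the extras exercise pruning), an injective taxon
    map, and a validated :class:`SocietyTable` whose binary trait and first
    ordinal trait are generated from the latent OU model on the first
    pruned tree (the second ordinal trait comes from an independent OU run
    on the same tree).  Returns a dict with ``table``, ``trees``,
    ``taxon_map``, ``pruned_trees`` and ``ground_truth``.
    """
    seeds = np.random.SeedSequence(seed).spawn(6)
    tree_seed, lat1_seed, lat2_seed, obs_seed, geo_seed, misc_seed = (
        int(s.generate_state(1)[0]) % (2**31) for s in seeds
    )

    soc_ids = [f"soc{i + 1:03d}" for i in range(n_societies)]
    taxa = [f"lang{i + 1:03d}" for i in range(n_societies)]
    extra = [f"xlang{i + 1:03d}" for i in range(n_extra_tips)]
    all_labels = taxa + extra

    trees = [
        simulate_tree(n_societies + n_extra_tips, tree_seed + k,
                      tip_labels=all_labels)
        for k in range(n_trees)
    ]
    phylo = PhyloSet(trees, kind="posterior_sample" if n_trees > 1 else "summary")
    taxon_map = TaxonMap(dict(zip(soc_ids, taxa)))
    pruned = prune_and_match(phylo, taxon_map)

    base = TreeIndex(pruned.trees[0], normalize_height=False)
    labels1, eta1 = simulate_ou_tips(base, ou_params, lat1_seed)
    _labels2, eta2 = simulate_ou_tips(base, ou_params, lat2_seed)

    lat, lon, effect = simulate_geography(n_societies, geo_seed,
                                          gp_scale=gp_scale, rho=rho)
    if gp_scale != 0.0:
        eta1 = eta1 + effect[:, None]
        eta2 = eta2 + effect[:, None]

    kava, polcomp = latent_to_observed(
        eta1, ou_params.alpha, obs_seed,
        missing_binary=missing_binary, missing_ordinal=0)
    _b2, strat = latent_to_observed(
        eta2, ou_params.alpha, obs_seed + 1,
        missing_binary=0, missing_ordinal=missing_ordinal)

    rng = np.random.default_rng(misc_seed)
    atoll = np.zeros(n_societies)
    idx = rng.permutation(n_societies)
    atoll[idx[:n_atolls]] = 1.0
    atoll[idx[n_atolls:n_atolls + n_half_atolls]] = 0.5

    # tip order of the pruned tree defines the latent order; align to ids
    tip_to_soc = taxon_map.tip_to_society()
    order = [tip_to_soc[lbl] for lbl in base.tip_labels]
    frame = pd.DataFrame(
        {
            "society_id": order,
            "language_taxon": [taxon_map.pairs[s] for s in order],
            "kava": kava,
            "political_complexity": polcomp,
            "social_stratification": strat,
            "atoll_raw": atoll,
            "latitude": lat,
            "longitude": lon,
        }
    ).sort_values("society_id").reset_index(drop=True)
    table = SocietyTable(frame)

    ground_truth = {
        "ou_params": ou_params,
        "gp_scale": gp_scale,
        "rho": rho,
        "seed": seed,
        "latent_order": order,
        "eta1": eta1,
        "eta2": eta2,
        "spatial_effect": effect,
    }
    return {
        "table": table,
        "trees": phylo,
        "taxon_map": taxon_map,
        "pruned_trees": pruned,
        "ground_truth": ground_truth,
    }
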