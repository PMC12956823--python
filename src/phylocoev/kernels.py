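"""Spatial and phylogenetic correlation matrices.

Two structured covariances are used as group-level ("random") effect
correlation matrices throughout the package:

* a spatial kernel: great-circle (Haversine) distances between society
  coordinates, max-normalized to [0, 1], passed through a Matern 3/2
  covariance function with decay length ``rho``;
* a phylogenetic correlation matrix: shared root-to-tip path length between
  two tips divided by the geometric mean of their root-to-tip depths (the
  standard variance-covariance-to-correlation conversion, valid also for
  non-ultrametric trees).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    ConfigError,
    DegenerateInputError,
    KernelError,
    ValidationError,
)

EARTH_RADIUS_KM = 6371.0
#: jitter added to kernel diagonals before any factorization
DIAG_JITTER = 1e-9
_PSD_TOL = -1e-8


@dataclass(frozen=True)
class KernelConfig:
    """Settings of the Matern 3/2 kernel on the normalized-distance scale."""

    rho: float = 0.02
    sigma_sq: float = 1.0
    earth_radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ConfigError(f"rho must be positive, got {self.rho}")
        if not self.sigma_sq > 0:
            raise ConfigError(f"sigma_sq must be positive, got {self.sigma_sq}")


@dataclass
class CovarianceSpec:
    """A labeled symmetric PSD matrix keyed by society (or tip) labels."""

    labels: list[str]
    matrix: np.ndarray
    kind: str = "spatial"  # {"spatial", "phylogenetic"}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise KernelError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise KernelError("covariance matrix is not symmetric")
        w = np.linalg.eigvalsh(0.5 * (self.matrix + self.matrix.T))
        if w.min() < _PSD_TOL:
            raise KernelError(
                f"covariance matrix is not PSD (min eigenvalue {w.min():.3g})"
            )
        if self.kind not in ("spatial", "phylogenetic"):
            raise ConfigError(f"unknown covariance kind {self.kind!r}")

    def rename(self, mapping: Mapping[str, str]) -> "CovarianceSpec":
        """Relabel rows/columns, e.g. tip label -> society id."""
        labels = [mapping.get(l, l) for l in self.labels]
        return CovarianceSpec(labels, self.matrix.copy(), self.kind)

    def align(self, order: Sequence[str]) -> "CovarianceSpec":
        """Subset and reorder to ``order``; unknown labels raise AlignmentError."""
        index = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in order if l not in index]
        if missing:
            raise AlignmentError(f"labels absent from covariance: {missing}")
        idx = np.array([index[l] for l in order])
        return CovarianceSpec(list(order), self.matrix[np.ix_(idx, idx)], self.kind)

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor after adding the diagonal jitter."""
        m = self.matrix + DIAG_JITTER * np.eye(len(self.labels))
        return np.linalg.cholesky(m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def haversine_matrix(table, earth_radius_km: float = EARTH_RADIUS_KM) -> pd.DataFrame:
    """All-pairs great-circle distances (km) between society coordinates.

    Parameters
    ----------
    table:
        A :class:`~phylocoev.data_model.SocietyTable` (or any object with
        ``society_ids``, ``latitude`` and ``longitude`` array attributes).
    """
    lat = np.asarray(table.latitude, dtype=float)
    lon = np.asarray(table.longitude, dtype=float)
    ids = list(table.society_ids)
    bad = np.flatnonzero(~np.isfinite(lat) | ~np.isfinite(lon))
    if bad.size:
        raise ValidationError(
            "missing coordinates for societies: "
            + ", ".join(ids[i] for i in bad)
        )
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    d = 2.0 * earth_radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return pd.DataFrame(d, index=ids, columns=ids)


def normalize_distances(D: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Max-scale a distance matrix so the largest entry is exactly 1."""
    values = D.to_numpy() if isinstance(D, pd.DataFrame) else np.asarray(D, dtype=float)
    if (values < 0).any():
        raise ValidationError("distance matrix has negative entries")
    dmax = values.max()
    if dmax <= 0:
        raise DegenerateInputError("all pairwise distances are zero; cannot normalize")
    out = values / dmax
    if isinstance(D, pd.DataFrame):
        return pd.DataFrame(out, index=D.index, columns=D.columns)
    return out


def matern32(dnorm, cfg: KernelConfig):
    """Matern 3/2 covariance k(d) = sigma^2 (1 + sqrt(3) d / rho) exp(-sqrt(3) d / rho)."""
    d = np.asarray(dnorm, dtype=float)
    if (d < 0).any():
        raise ValidationError("distances must be nonnegative")
    s = np.sqrt(3.0) * d / cfg.rho
    out = cfg.sigma_sq * (1.0 + s) * np.exp(-s)
    return out if out.ndim else float(out)


def spatial_covariance(table, cfg: KernelConfig) -> CovarianceSpec:
    """Haversine -> max-normalize -> Matern 3/2, as a labeled CovarianceSpec."""
    D = haversine_matrix(table, earth_radius_km=cfg.earth_radius_km)
    K = matern32(normalize_distances(D).to_numpy(), cfg)
    return CovarianceSpec(list(D.index), K, kind="spatial")


def phylo_correlation(tree: dendropy.Tree) -> CovarianceSpec:
    """Phylogenetic correlation matrix from a rooted tree with branch lengths.

    Entry (i, j) is the root-to-MRCA path length shared by tips i and j,
    divided by the geometric mean of the two root-to-tip depths; the diagonal
    is exactly 1.  For an ultrametric tree this equals the classic
    variance-covariance matrix rescaled to unit diagonal.
    """
    depths: dict = {}
    for node in tree.preorder_node_iter():
        elen = node.edge.length if node.edge.length is not None else 0.0
        if elen < 0:
            raise ValidationError("negative branch length in tree")
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + elen

    leaves = [nd for nd in tree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon is not None else str(i) for i, lf in enumerate(leaves)]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    tip_depth = np.array([depths[lf] for lf in leaves])
    if (tip_depth <= 0).any():
        zero = [labels[i] for i in np.flatnonzero(tip_depth <= 0)]
        raise DegenerateInputError(f"zero root-to-tip depth for tips: {zero}")

    shared = np.zeros((n, n))
    # postorder: a pair's MRCA is the first node whose leaf sets merge them
    leafset: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[node] = [index[id(node)]]
            continue
        children = [leafset.pop(ch) for ch in node.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    shared[i, children[b]] = depths[node]
                    shared[children[b], i] = depths[node]
        leafset[node] = [i for grp in children for i in grp]

    corr = shared / np.sqrt(np.outer(tip_depth, tip_depth))
    np.fill_diagonal(corr, 1.0)
    return CovarianceSpec(labels, corr, kind="phylogenetic")
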