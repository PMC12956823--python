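"""Trait-table and phylogeny data structures, I/O, validation and pruning.

The canonical on-disk trait format is a delimited text file (CSV) with one
row per society and the columns listed in :data:`CANONICAL_COLUMNS`.  Trees
are read from Newick or NEXUS files and are interpreted as rooted as
written; every non-root edge must carry a branch length.  Societies are tied
to tree tips through an explicit :class:`TaxonMap` (one tip per society),
never by heuristics.
"""
from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    MatchingError,
    SchemaError,
    TreeError,
    ValidationError,
)

CANONICAL_COLUMNS = (
    "society_id",
    "language_taxon",
    "kava",
    "political_complexity",
    "social_stratification",
    "atoll_raw",
    "latitude",
    "longitude",
)

ORDINAL_TRAITS = ("political_complexity", "social_stratification")
ORDINAL_LEVELS = 5


@dataclass
class SocietyTable:
    """One row per society: traits, coordinates, explicit missingness.

    Trait columns are stored as floats with ``NaN`` marking missing values;
    validation enforces integrality and range for the non-missing entries.
    Extra columns (e.g. a derived binary ``atoll``) are carried through
    untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise SchemaError(f"missing required columns: {missing_cols}")
        df = self.data.reset_index(drop=True).copy()
        for col in ("kava", *ORDINAL_TRAITS, "atoll_raw", "latitude", "longitude"):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"non-numeric value in column {col!r}: {exc}") from exc
        self.data = df
        self._validate()

    def _validate(self) -> None:
        df = self.data
        if df["society_id"].duplicated().any():
            dupes = df.loc[df["society_id"].duplicated(), "society_id"].tolist()
            raise ValidationError(f"duplicate society_id values: {dupes}")
        self._check_discrete("kava", {0.0, 1.0})
        for col in ORDINAL_TRAITS:
            self._check_discrete(col, set(float(k) for k in range(ORDINAL_LEVELS)))
        self._check_discrete("atoll_raw", {0.0, 0.5, 1.0}, allow_missing=False)
        lat = df["latitude"].to_numpy(dtype=float)
        lon = df["longitude"].to_numpy(dtype=float)
        if np.nanmin(lat, initial=0) < -90 or np.nanmax(lat, initial=0) > 90:
            raise ValidationError("latitude outside [-90, 90]")
        if np.nanmin(lon, initial=0) < -180 or np.nanmax(lon, initial=0) > 180:
            raise ValidationError("longitude outside [-180, 180]")

    def _check_discrete(self, col: str, allowed: set, allow_missing: bool = True) -> None:
        values = self.data[col].to_numpy(dtype=float)
        mask = np.isnan(values)
        if mask.any() and not allow_missing:
            rows = self.data.loc[mask, "society_id"].tolist()
            raise ValidationError(f"column {col!r} may not be missing (rows {rows})")
        bad = np.array([v not in allowed for v in values[~mask]])
        if bad.any():
            rows = self.data.loc[~mask].loc[bad, "society_id"].tolist()
            raise ValidationError(
                f"column {col!r} has values outside {sorted(allowed)} in rows {rows}"
            )

    # -- convenient accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def society_ids(self) -> list[str]:
        return self.data["society_id"].astype(str).tolist()

    @property
    def latitude(self) -> np.ndarray:
        return self.data["latitude"].to_numpy(dtype=float)

    @property
    def longitude(self) -> np.ndarray:
        return self.data["longitude"].to_numpy(dtype=float)

    def trait(self, name: str) -> np.ndarray:
        """Trait values as a float array with NaN for missing."""
        if name not in self.data.columns:
            raise SchemaError(f"unknown trait column {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def missing_counts(self) -> dict[str, int]:
        return {
            c: int(self.data[c].isna().sum())
            for c in ("kava", *ORDINAL_TRAITS)
        }

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False, na_rep="")


def read_society_table(path, column_spec: Mapping[str, str] | None = None) -> SocietyTable:
    """Read and validate a society trait table from a delimited text file.

    ``column_spec`` maps canonical column names to the names used in the
    file; unmapped canonical names are looked up verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty trait file: {path}") from exc
    if column_spec:
        rename = {v: k for k, v in column_spec.items()}
        df = df.rename(columns=rename)
    return SocietyTable(df)


def binarize_atolls(table: SocietyTable, mode: str) -> SocietyTable:
    """Resolve half-coded "almost atolls" into a binary ``atoll`` column.

    ``mode="exclude_half"`` maps 0.5 to missing; ``mode="half_as_atoll"``
    maps 0.5 to 1.
    """
    if mode not in ("exclude_half", "half_as_atoll"):
        raise ConfigError(f"unknown atoll binarization mode {mode!r}")
    df = table.data.copy()
    raw = df["atoll_raw"].to_numpy(dtype=float)
    atoll = raw.copy()
    half = raw == 0.5
    atoll[half] = np.nan if mode == "exclude_half" else 1.0
    df["atoll"] = atoll
    return SocietyTable(df)


@dataclass(frozen=True)
class TaxonMap:
    """Injective mapping society_id -> tip label (exactly one tip per society)."""

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        tips = list(self.pairs.values())
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValidationError(f"taxon map is not injective; repeated tips: {dupes}")

    @classmethod
    def from_csv(cls, path) -> "TaxonMap":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise SchemaError("taxon map CSV needs two columns: society_id, tip_label")
        cols = df.columns[:2]
        return cls(dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str))))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"society_id": list(self.pairs), "tip_label": list(self.pairs.values())}
        ).to_csv(path, index=False)

    @property
    def tip_labels(self) -> list[str]:
        return list(self.pairs.values())

    def tip_to_society(self) -> dict[str, str]:
        return {tip: soc for soc, tip in self.pairs.items()}


@dataclass
class PhyloSet:
    """A list of rooted trees with branch lengths sharing a tip-label set."""

    trees: list[dendropy.Tree]
    kind: str = "posterior_sample"  # or "summary"

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("PhyloSet needs at least one tree")
        for idx, tree in enumerate(self.trees):
            _check_tree(tree, idx)

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def tip_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.trees[0].leaf_node_iter())

    def common_tip_set(self) -> set[str]:
        sets = [
            {lf.taxon.label for lf in t.leaf_node_iter()} for t in self.trees
        ]
        common = set.intersection(*sets)
        return common


def _check_tree(tree: dendropy.Tree, idx: int) -> None:
    seed = tree.seed_node
    if len(seed.child_nodes()) > 2:
        raise TreeError(f"tree {idx} appears unrooted (basal polytomy)")
    for node in tree.preorder_node_iter():
        if node is seed:
            continue
        if node.edge.length is None:
            raise TreeError(f"tree {idx} has edges without branch lengths")
        if node.edge.length < 0:
            raise TreeError(f"tree {idx} has a negative branch length")


def read_trees(path, kind: str | None = None) -> PhyloSet:
    """Read rooted trees (Newick or NEXUS, detected by content) into a PhyloSet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    try:
        trees = dendropy.TreeList.get(
            data=text, schema=schema, rooting="force-rooted"
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"could not parse tree file {path}: {exc}") from exc
    if len(trees) == 0:
        raise TreeError(f"no trees found in {path}")
    if kind is None:
        kind = "posterior_sample" if len(trees) > 1 else "summary"
    return PhyloSet(list(trees), kind=kind)


def prune_and_match(phylo: PhyloSet, taxon_map: TaxonMap) -> PhyloSet:
    """Prune every tree down to exactly the mapped tips.

    Degree-2 internal nodes left by pruning are collapsed with branch
    lengths summed, so patristic distances among retained tips are
    preserved.  Raises :class:`MatchingError` listing any mapped label that
    is absent from some tree.
    """
    wanted = set(taxon_map.tip_labels)
    pruned: list[dendropy.Tree] = []
    for idx, tree in enumerate(phylo.trees):
        have = {lf.taxon.label for lf in tree.leaf_node_iter()}
        missing = sorted(wanted - have)
        if missing:
            raise MatchingError(
                f"tree {idx} is missing mapped tip labels: {missing}"
            )
        work = tree.clone(depth=1)
        work.retain_taxa_with_labels(sorted(wanted))
        work.purge_taxon_namespace()
        pruned.append(work)
    return PhyloSet(pruned, kind=phylo.kind)
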