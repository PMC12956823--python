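"""End-to-end orchestration: model menu, summary tables, manifest.

``run_pipeline`` executes the full analysis menu on a dataset (either
loaded from files or generated by the synthetic preset): the regression
grid over confounder structures (a-f), the bivariate signal fits, and the
coevolution fits with and without spatial control.  Outputs are CSV/JSON
only: one summary table per stage, per-model draws archives, a
machine-readable manifest with checksums, and a JSON-lines log.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, kernels
from .coevolution import CoevSpec, delta_theta, fit_coevolution
from .data_model import (
    SocietyTable,
    TaxonMap,
    binarize_atolls,
    prune_and_match,
    read_society_table,
    read_trees,
)
from .exceptions import ConfigError
from .mcmc import SamplerConfig, summarize_draws
from .regression import RegressionSpec, fit_structured_regression, predicted_contrast
from .signal import fit_bivariate_latent, phylo_correlation_estimate, phylogenetic_signal
from .synthetic_data import dataset_s1_like

#: confounder structures of the regression menu; "atoll" adds the binary
#: atoll covariate, the others add structured random effects
CONFOUNDER_MENU: dict[str, tuple[str, ...]] = {
    "a": (),
    "b": ("phylogenetic",),
    "c": ("spatial",),
    "d": ("phylogenetic", "spatial"),
    "e": ("atoll",),
    "f": ("atoll", "phylogenetic", "spatial"),
}

ORDINAL_RESPONSES = ("political_complexity", "social_stratification")


@dataclass
class RunConfig:
    """Inputs, model menu and sampler settings of one pipeline run."""

    out_dir: str = "results"
    seed: int = 1
    # data: file paths, or synthetic preset when table_csv is None
    table_csv: str | None = None
    trees_file: str | None = None
    taxon_map_csv: str | None = None
    synthetic_n_societies: int = 83
    synthetic_n_trees: int = 5
    # menu
    regression_models: tuple[str, ...] = ("a", "b", "c", "d", "e", "f")
    responses: tuple[str, ...] = ORDINAL_RESPONSES
    signal_traits: tuple[str, ...] = ORDINAL_RESPONSES
    coevolution_traits: tuple[str, ...] = ORDINAL_RESPONSES
    coevolution_models: tuple[str, ...] = ("model0", "model1")  # model1: +spatial GP
    rho: float = 0.02
    root_prior: str = "informed"
    atoll_mode: str = "half_as_atoll"
    n_trees_fit: int = 1
    chains: int = 1
    draws: int = 300
    warmup: int = 300

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regression_models", "responses", "signal_traits",
                    "coevolution_traits", "coevolution_models"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def sampler(self, seed_offset: int = 0) -> SamplerConfig:
        return SamplerConfig(chains=self.chains, draws=self.draws,
                             warmup=self.warmup, seed=self.seed + seed_offset)


def summarize_posterior(draws) -> pd.Series:
    """Summary row (mean, median, CI66, CI95, PPM) of a 1-D draw vector."""
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size == 0:
        raise ConfigError("cannot summarize an empty draw vector")
    return summarize_draws(arr[None, :, None], ["draws"]).iloc[0]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def write(self, **record) -> None:
        record.setdefault("time", round(time.time(), 3))
        with self.path.open("a") as fh:
            fh.write(json.dumps(record) + "\n")


def _load_inputs(cfg: RunConfig):
    if cfg.table_csv is not None:
        table = read_society_table(cfg.table_csv)
        trees = read_trees(cfg.trees_file)
        taxon_map = TaxonMap.from_csv(cfg.taxon_map_csv)
        pruned = prune_and_match(trees, taxon_map)
        return table, trees, taxon_map, pruned
    sim = dataset_s1_like(seed=cfg.seed, n_societies=cfg.synthetic_n_societies,
                          n_trees=cfg.synthetic_n_trees,
                          missing_binary=5, missing_ordinal=1)
    return sim["table"], sim["trees"], sim["taxon_map"], sim["pruned_trees"]


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured menu; returns the output directory.

    Stage failures are caught and recorded in the manifest so partial
    results remain usable.
    """
    out = Path(cfg.out_dir)
    (out / "draws").mkdir(parents=True, exist_ok=True)
    log = _Log(out / "log.jsonl")
    failures: list[dict] = []
    t0 = time.time()
    log.write(stage="start", seed=cfg.seed)

    table, trees, taxon_map, pruned = _load_inputs(cfg)
    table = binarize_atolls(table, cfg.atoll_mode)
    log.write(stage="data", n_societies=len(table), n_trees=len(trees),
              missing=table.missing_counts())

    phylo_cov = kernels.phylo_correlation(pruned.trees[0]).rename(
        taxon_map.tip_to_society())
    spatial_cov = kernels.spatial_covariance(
        table, kernels.KernelConfig(rho=cfg.rho))

    # ---- stage: regressions ------------------------------------------------
    reg_rows, contrast_rows = [], []
    offset = 0
    for response in cfg.responses:
        for key in cfg.regression_models:
            if key not in CONFOUNDER_MENU:
                raise ConfigError(f"unknown regression menu entry {key!r}")
            parts = CONFOUNDER_MENU[key]
            predictors = ["kava"] + (["atoll"] if "atoll" in parts else [])
            structures = tuple(p for p in parts if p != "atoll")
            spec = RegressionSpec(
                response=response,
                predictors=tuple(predictors),
                random_structures=structures,
                kernel_cfg=kernels.KernelConfig(rho=cfg.rho),
                sampler_cfg=cfg.sampler(offset),
            )
            offset += 1
            name = f"regression_{response}_{key}"
            try:
                start = time.time()
                fit = fit_structured_regression(
                    table, spec, [phylo_cov, spatial_cov])
                for _, row in fit.summary.iterrows():
                    if row["parameter"].startswith("z_"):
                        continue
                    reg_rows.append({"model": key, "response": response,
                                     **row.to_dict()})
                cdraws, crow = predicted_contrast(fit, "kava")
                contrast_rows.append({"model": key, "response": response,
                                      **crow.to_dict()})
                fit.draws[[c for c in fit.draws.columns
                           if not c.startswith("z_")]].to_csv(
                    out / "draws" / f"{name}.csv", index=False)
                log.write(stage=name, seconds=round(time.time() - start, 2),
                          n_used=fit.meta["n_used"])
            except Exception as exc:  # noqa: BLE001 - recorded, not silenced
                failures.append({"stage": name, "error": repr(exc)})
                log.write(stage=name, error=repr(exc))
    pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
    pd.DataFrame(contrast_rows).to_csv(out / "contrasts.csv", index=False)

    # ---- stage: signal -----------------------------------------------------
    signal_rows = []
    for trait in cfg.signal_traits:
        name = f"signal_{trait}"
        try:
            start = time.time()
            fit = fit_bivariate_latent(
                table, trait, pruned, taxon_map,
                sampler_cfg=cfg.sampler(offset), n_trees=cfg.n_trees_fit)
            offset += 1
            corr = phylo_correlation_estimate(fit)
            signal_rows.append({"trait_pair": f"kava:{trait}",
                                "quantity": "phylo_correlation",
                                **corr.summary.to_dict()})
            for tr in ("kava", trait):
                sig = phylogenetic_signal(fit, tr)
                signal_rows.append({"trait_pair": f"kava:{trait}",
                                    "quantity": f"lambda_{tr}",
                                    **sig.summary.to_dict()})
            fit.draws.to_csv(out / "draws" / f"{name}.csv", index=False)
            log.write(stage=name, seconds=round(time.time() - start, 2))
        except Exception as exc:  # noqa: BLE001
            failures.append({"stage": name, "error": repr(exc)})
            log.write(stage=name, error=repr(exc))
    pd.DataFrame(signal_rows).to_csv(out / "signal.csv", index=False)

    # ---- stage: coevolution ------------------------------------------------
    coev_rows = []
    for trait in cfg.coevolution_traits:
        for model in cfg.coevolution_models:
            if model not in ("model0", "model1"):
                raise ConfigError(f"unknown coevolution model {model!r}")
            name = f"coevolution_{trait}_{model}"
            spec = CoevSpec(
                ordinal_trait=trait,
                spatial_control=(model == "model1"),
                rho=cfg.rho,
                root_prior=cfg.root_prior,
                n_trees=cfg.n_trees_fit,
                sampler_cfg=cfg.sampler(offset),
            )
            offset += 1
            try:
                start = time.time()
                fit = fit_coevolution(table, pruned, spec, taxon_map)
                for direction, tag in (((1, 2), f"kava->{trait}"),
                                       ((2, 1), f"{trait}->kava")):
                    dt = delta_theta(fit, direction)
                    coev_rows.append({"model": model, "trait_pair": tag,
                                      "ppm": dt.ppm, **dt.summary.to_dict()})
                fit.draws.to_csv(out / "draws" / f"{name}.csv", index=False)
                log.write(stage=name, seconds=round(time.time() - start, 2),
                          divergences=fit.diagnostics["divergences"])
            except Exception as exc:  # noqa: BLE001
                failures.append({"stage": name, "error": repr(exc)})
                log.write(stage=name, error=repr(exc))
    pd.DataFrame(coev_rows).to_csv(out / "coevolution.csv", index=False)

    # ---- manifest ----------------------------------------------------------
    outputs = sorted(p for p in out.rglob("*")
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "elapsed_seconds": round(time.time() - t0, 2),
        "outputs": [{"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                    for p in outputs],
        "failures": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.write(stage="done", failures=len(failures))
    return out
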