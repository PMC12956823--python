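import numpy as np
import pandas as pd
import pytest

from phylocoev.data_model import PhyloSet, SocietyTable, TaxonMap
from phylocoev import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_table(n=12, seed=0, missing_kava=0, missing_strat=0):
    r = np.random.default_rng(seed)
    ids = [f"soc{i:03d}" for i in range(n)]
    kava = r.integers(0, 2, n).astype(float)
    pol = r.integers(0, 5, n).astype(float)
    strat = r.integers(0, 5, n).astype(float)
    if missing_kava:
        kava[r.choice(n, missing_kava, replace=False)] = np.nan
    if missing_strat:
        strat[r.choice(n, missing_strat, replace=False)] = np.nan
    atoll = r.choice([0.0, 0.5, 1.0], n, p=[0.7, 0.1, 0.2])
    return SocietyTable(pd.DataFrame({
        "society_id": ids,
        "language_taxon": [f"lang{i:03d}" for i in range(n)],
        "kava": kava,
        "political_complexity": pol,
        "social_stratification": strat,
        "atoll_raw": atoll,
        "latitude": r.uniform(-25, 10, n),
        "longitude": r.uniform(140, 180, n),
    }))


@pytest.fixture
def small_table():
    return make_table(n=12, seed=3, missing_kava=1, missing_strat=1)


@pytest.fixture(scope="session")
def sim_small():
    """Small dataset-s1-like preset shared by the slower model tests."""
    return sd.dataset_s1_like(seed=42, n_societies=30, n_trees=3,
                              n_extra_tips=5, missing_binary=2,
                              missing_ordinal=1)


def coev_dataset(n=80, rep=0, true=None, pendant=(0.02, 0.5)):
    """Simulate a trait table + tree from the latent OU model (known truth)."""
    from phylocoev.coevolution import OUParams

    if true is None:
        true = OUParams(b=[3.0, 0.0], A=[[-2.0, 0.0], [1.5, -0.7]],
                        sigma=[1.5, 0.25], R=np.eye(2),
                        alpha=[-1.0, -0.2, 0.6, 1.6], eta_anc=[-2, -2])
    tree = sd.simulate_tree(n, seed=100 + rep, pendant_scale_range=pendant)
    labels, eta = sd.simulate_ou_tips(tree, true, seed=200 + rep)
    kava, pol = sd.latent_to_observed(eta, true.alpha, seed=300 + rep)
    ids = [f"s{i:03d}" for i in range(n)]
    lat, lon, _ = sd.simulate_geography(n, 400 + rep)
    table = SocietyTable(pd.DataFrame({
        "society_id": ids,
        "language_taxon": labels,
        "kava": kava,
        "political_complexity": pol,
        "social_stratification": pol,
        "atoll_raw": 0.0,
        "latitude": lat,
        "longitude": lon,
    }))
    taxon_map = TaxonMap(dict(zip(ids, labels)))
    trees = PhyloSet([tree], kind="summary")
    return table, trees, taxon_map, true, eta
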