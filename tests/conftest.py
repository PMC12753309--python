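import numpy as np
import pandas as pd
import pytest

import sedabench as sb


@pytest.fixture(scope="session")
def small_counts() -> pd.DataFrame:
    """Random 6 x 10 integer counts with some zeros (seeded)."""
    rng = np.random.default_rng(42)
    x = rng.integers(0, 30, size=(6, 10))
    x[2, :5] = 0
    return pd.DataFrame(x, index=[f"s{i}" for i in range(6)],
                        columns=[f"t{j}" for j in range(10)])


@pytest.fixture(scope="session")
def annotations_10():
    return sb.simulate_taxa_annotations(10, seq_length=60, seed=11,
                                        taxon_ids=[f"t{j}" for j in range(10)])


@pytest.fixture(scope="session")
def cluster_dataset() -> sb.CommunityDataset:
    """Small, well-separated 3-cluster dataset."""
    params = sb.draw_sim_params(7, "cluster", overrides={
        "n_samples": 30, "n_taxa": 60, "n_clusters": 3,
        "de_prob_range": (0.3, 0.3), "de_factor_range": (4.0, 6.0)})
    return sb.simulate_community(params)


@pytest.fixture(scope="session")
def gradient_dataset() -> sb.CommunityDataset:
    params = sb.draw_sim_params(8, "path", overrides={
        "n_samples": 30, "n_taxa": 60,
        "de_prob_range": (0.3, 0.3), "de_factor_range": (4.0, 6.0)})
    return sb.simulate_community(params)


@pytest.fixture(scope="session")
def degraded_pair(cluster_dataset):
    plan = sb.assign_effect_levels(cluster_dataset.metadata, "cluster", seed=9)
    ancient, realized = sb.degrade_matrix(cluster_dataset, plan)
    return cluster_dataset, ancient, realized
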