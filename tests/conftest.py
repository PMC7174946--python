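import numpy as np
import pandas as pd
import pytest

from cernapipe import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design():
    return synthetic.generate_design(5, seed=0)


@pytest.fixture(scope="session")
def small_study():
    """One desk-scale simulated study shared by read-only tests."""
    design = synthetic.generate_design(5, seed=7)
    config = synthetic.SimulationConfig(
        n_features={"mRNA": 300, "ncRNA": 80, "circRNA": 80, "miRNA": 60},
        n_target_pairs=12,
    )
    matrices, truth = synthetic.generate_multiomics(design, config, seed=7)
    return design, config, matrices, truth


def truth_profile_means(truth, config, base=8.0):
    """Exact (noise-free) per-feature group-mean table implied by a TruthBundle.

    Reconstructs the planted log2 offsets: NC at ``base``; features
    differential in DM vs NC shifted by ±log2fc in DM; treatment arms
    restored iff the feature is in that arm's efficacy set.
    """
    dm_truth = truth.de_features["DM vs NC"]
    features = sorted({f for f, _ in dm_truth})
    direction = {f: (1 if d == "up" else -1) for f, d in dm_truth}
    rows = {}
    for f in features:
        shift = direction[f] * config.log2fc
        row = {"NC": base, "DM": base + shift}
        for t in synthetic.TREATMENTS:
            row[t] = base if f in truth.efficacy_features[t] else base + shift
        rows[f] = row
    return pd.DataFrame.from_dict(rows, orient="index")
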