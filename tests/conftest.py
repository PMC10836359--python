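import numpy as np
import pandas as pd
import pytest

from qmpipe.synthetic import SimulationConfig, simulate_cohort


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A scaled-down cohort configuration for fast tests."""
    kwargs = dict(
        group_sizes={
            "control": 40,
            "high_genetic_risk": 12,
            "autoimmunity": 12,
            "symptomatic": 12,
        },
        n_taxa=40,
        depth_distribution=(8000.0, 10.0),
        min_depth=1500,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture
def tiny_counts():
    """A hand-sized ASV count matrix with three samples."""
    return pd.DataFrame(
        np.array([[40, 10, 0], [60, 30, 5], [0, 60, 95]]),
        index=["ASV_1", "ASV_2", "ASV_3"],
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def tiny_taxonomy():
    return pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * 3,
            "phylum": ["Bacteroidota"] * 2 + ["Bacillota"],
            "class": ["Bacteroidia"] * 2 + ["Clostridia"],
            "order": ["Bacteroidales"] * 2 + ["Oscillospirales"],
            "family": ["Prevotellaceae", "Prevotellaceae", "Ruminococcaceae"],
            "genus": ["Prevotella", "Prevotella", "Faecalibacterium"],
        },
        index=pd.Index(["ASV_1", "ASV_2", "ASV_3"], name="taxon_id"),
    )
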