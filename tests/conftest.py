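import numpy as np
import pandas as pd
import pytest

from lakemicro import CommunityMatrix, SimulationConfig, simulate_metacommunity
from lakemicro.io import read_tree


def make_cm(counts, sample_ids=None, otu_ids=None, groups=None) -> CommunityMatrix:
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"S{i+1}" for i in range(counts.shape[0])]
    otu_ids = otu_ids or [f"OTU{j+1}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=sample_ids, columns=otu_ids)
    g = pd.Series(groups, index=sample_ids) if groups is not None else pd.Series(
        ["G1"] * len(sample_ids), index=sample_ids)
    return CommunityMatrix(df, g)


@pytest.fixture
def small_tree():
    return read_tree("(A:1,(B:1,C:1):1);")


@pytest.fixture(scope="session")
def neutral_survey():
    """A small neutral survey shared by read-only tests."""
    cfg = SimulationConfig(n_groups=4, samples_per_group=3, n_taxa=150,
                           library_size=2000, regime="neutral", seed=11)
    return simulate_metacommunity(cfg)
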