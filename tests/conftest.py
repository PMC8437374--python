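import numpy as np
import pandas as pd
import pytest

from guildscope import synthio, tabio


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    cfg = synthio.SynthConfig(
        n_case=30, n_control=70, n_taxa=40, n_blocks=4, within_block_corr=0.7,
        depth_mean=5000, timepoints=("T2",), seed=7,
    )
    counts, meta, truth = synthio.generate_community(cfg)
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_relative(small_cohort):
    counts, meta, truth = small_cohort
    return tabio.to_relative(counts), meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_counts():
    return pd.DataFrame(
        [[5, 0], [3, 7]],
        index=pd.Index(["g__A", "g__B"], name="taxon"),
        columns=["s1", "s2"],
    )
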