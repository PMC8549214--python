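import logging

import numpy as np
import pandas as pd
import pytest

from zhengomics.syndata import SynConfig, gen_knowledgebase, gen_metabolomics, gen_proteomics
from zhengomics.tables import OmicsTable

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def default_cfg() -> SynConfig:
    return SynConfig(seed=1)


@pytest.fixture(scope="session")
def proteomics_run(default_cfg):
    return gen_proteomics(default_cfg)


@pytest.fixture(scope="session")
def metabolomics_run(default_cfg):
    return gen_metabolomics(default_cfg)


@pytest.fixture(scope="session")
def knowledgebase_run(default_cfg):
    return gen_knowledgebase(default_cfg)


@pytest.fixture
def tiny_table() -> OmicsTable:
    """4 features x 6 samples (2 groups + 2 standards), no missing values."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.lognormal(10, 0.2, size=(4, 6)),
        index=[f"F{i}" for i in range(4)],
        columns=["A1", "A2", "B1", "B2", "STD_1", "STD_2"],
    )
    groups = pd.Series(
        ["CCQS", "CCQS", "HC", "HC", "STD", "STD"], index=values.columns
    )
    return OmicsTable(values, groups)
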