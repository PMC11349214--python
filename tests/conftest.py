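import numpy as np
import pandas as pd
import pytest

from copdgraph.dataset import MixedDataset, build_meta


def make_dataset(columns, kinds, levels=None, outcome=None, roles=None):
    """Build a MixedDataset from plain arrays (test convenience)."""
    values = pd.DataFrame({k: np.asarray(v, dtype=object if kinds[k] == "categorical"
                                         else float)
                           for k, v in columns.items()})
    meta = build_meta(kinds, levels or {}, roles or {})
    return MixedDataset(values, meta, outcome_name=outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def copd_cohort():
    """One default-condition synthetic cohort shared across tests."""
    from copdgraph.simulate import CohortSpec, make_copd_like

    return make_copd_like(CohortSpec(seed=42))
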