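import numpy as np
import pandas as pd
import pytest

from dietomics import AbundanceMatrix, Semantics, SynthConfig


@pytest.fixture
def small_synth_config():
    """Desk-scale generator settings shared by pipeline-level tests."""
    return SynthConfig(seed=11, n_ecs=40, n_taxa=80, n_metabolites=30)


@pytest.fixture
def rel_matrix():
    """A tiny valid relative-abundance matrix."""
    values = pd.DataFrame(
        {"s1": [0.5, 0.3, 0.2], "s2": [0.25, 0.25, 0.5]},
        index=["f1", "f2", "f3"],
    )
    return AbundanceMatrix(values, Semantics.RELATIVE_ABUNDANCE)
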