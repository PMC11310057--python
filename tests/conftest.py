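import numpy as np
import pandas as pd
import pytest


def make_sumstats(**overrides) -> pd.DataFrame:
    """Small well-formed summary-statistics table; columns overridable."""
    base = {
        "snp": ["rs1", "rs2", "rs3"],
        "chr": ["1", "1", "1"],
        "pos": [100, 200, 300],
        "ea": ["A", "C", "G"],
        "oa": ["G", "T", "A"],
        "eaf": [0.3, 0.4, 0.2],
        "beta": [0.5, -0.2, 0.1],
        "se": [0.05, 0.04, 0.06],
        "p": [1e-10, 1e-6, 0.01],
        "n": [30000, 30000, 30000],
    }
    base.update(overrides)
    return pd.DataFrame(base)


def row(**overrides) -> pd.DataFrame:
    """One-row summary-statistics record with defaults."""
    base = {
        "snp": "rs1", "chr": "1", "pos": 100, "ea": "A", "oa": "G",
        "eaf": 0.3, "beta": 0.5, "se": 0.05, "p": 1e-10, "n": 30000,
    }
    base.update(overrides)
    return pd.DataFrame([base])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
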