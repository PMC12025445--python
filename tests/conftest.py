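import numpy as np
import pytest

from glycoval import (ComparisonSimConfig, PairedDataset, UnitSystem,
                      simulate_comparison)


@pytest.fixture
def ifcc_unit():
    return UnitSystem.IFCC_MMOL_PER_MOL


@pytest.fixture
def study_like_dataset():
    """One seeded dataset mimicking the study conditions: n=178, true values
    uniform on 30-73 mmol/mol, candidate = true - 1, 2 % CV on both methods."""
    return simulate_comparison(ComparisonSimConfig(seed=42))


def make_pairs(x, y, unit=UnitSystem.IFCC_MMOL_PER_MOL):
    return PairedDataset(np.asarray(x, dtype=float),
                         np.asarray(y, dtype=float), unit)
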