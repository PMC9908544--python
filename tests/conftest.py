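import numpy as np
import pandas as pd
import pytest

from permomics import GroupDesign, QuantMatrix


@pytest.fixture
def design_5v5() -> GroupDesign:
    return GroupDesign(
        case_ids=[f"KO{i}" for i in range(1, 6)],
        ctrl_ids=[f"WT{i}" for i in range(1, 6)],
    )


@pytest.fixture
def null_matrix_5v5(design_5v5) -> QuantMatrix:
    """200 i.i.d. log-normal features with no group effect."""
    rng = np.random.default_rng(42)
    log2 = rng.normal(20, 2, size=(200, 10))
    data = pd.DataFrame(
        2.0 ** log2, index=[f"F{i:03d}" for i in range(200)], columns=design_5v5.sample_ids
    )
    return QuantMatrix(data=data, layer="peptide", scale="raw")


def make_matrix(values, layer="peptide", scale="raw", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return QuantMatrix(
        data=pd.DataFrame(values, index=features, columns=samples), layer=layer, scale=scale
    )
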