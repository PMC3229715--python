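import numpy as np
import pandas as pd
import pytest

from mirct import ArraySimConfig, CtMatrix, GroupDesign, generate_array_dataset


@pytest.fixture
def small_dataset():
    """Complete (no-missingness) 30-assay, 6 vs 10 dataset with 4 planted effects."""
    cfg = ArraySimConfig(
        n_assays=30,
        n_group1=6,
        n_group2=10,
        n_true_de=4,
        effect_range_ct=(1.0, 2.0),
        missing_logistic_midpoint=60.0,  # effectively no dropout
        seed=11,
    )
    return generate_array_dataset(cfg)


@pytest.fixture
def default_dataset():
    """Study-scale dataset at the default configuration."""
    return generate_array_dataset(ArraySimConfig(seed=7))


def make_matrix(values, stage="raw", prefix="a"):
    """Tiny helper: build a CtMatrix from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )
    return CtMatrix(df, stage=stage)


def make_design(n1, n2, tissue="cortex"):
    ids = [f"s{j}" for j in range(n1 + n2)]
    return GroupDesign(
        pd.DataFrame(
            {
                "group": ["PGRN+"] * n1 + ["PGRN-"] * n2,
                "tissue": tissue,
                "subtype": ["type1"] * n1 + [f"type{1 + j % 3}" for j in range(n2)],
            },
            index=pd.Index(ids, name="sample_id"),
        )
    )
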