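import numpy as np
import pandas as pd
import pytest

from neuromito import kinetics as K
from neuromito import proteomics as P
from neuromito import synthetic as S


@pytest.fixture(scope="session")
def lfq_cohort():
    """6 control vs 5 case cohort with planted TCA/ETC depletion and
    moderate left-censoring (two technical replicates per sample)."""
    design = S.default_design(censor_quantile=0.15, seed=11)
    matrix, annot, truth = S.simulate_lfq(design)
    return design, matrix, annot, truth


@pytest.fixture(scope="session")
def imputed_cohort(lfq_cohort):
    design, matrix, annot, truth = lfq_cohort
    averaged = P.average_technical_replicates(matrix)
    imputed, tier = P.impute(averaged.log2(), seed=13)
    return averaged, imputed, tier


@pytest.fixture(scope="session")
def reference_model():
    return K.build_reference_model()


@pytest.fixture()
def small_matrix():
    """Tiny two-group log2 matrix with no missing values."""
    rng = np.random.default_rng(5)
    vals = pd.DataFrame(
        rng.normal(25.0, 2.0, size=(50, 6)),
        index=[f"P{i:03d}" for i in range(50)],
        columns=[f"c{i}" for i in range(3)] + [f"e{i}" for i in range(3)],
    )
    design = pd.DataFrame(
        {
            "group": ["control"] * 3 + ["case"] * 3,
            "biosample": vals.columns,
        },
        index=vals.columns,
    )
    return P.LfqMatrix(vals, design, scale="log2")
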