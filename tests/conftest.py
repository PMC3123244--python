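import numpy as np
import pandas as pd
import pytest

from netanim.core import ExpressionMatrix, StudyDesign, canonical_comparisons
from netanim.synthetic import SyntheticConfig, simulate_study


def make_design(replicates: int = 3) -> StudyDesign:
    rows = []
    for geno in ("WT", "d_p23"):
        for treat in ("vehicle", "hsp90i"):
            for rep in range(1, replicates + 1):
                rows.append(
                    {"sample_id": f"{geno}_{treat}_r{rep}", "genotype": geno,
                     "treatment": treat, "replicate": rep}
                )
    return StudyDesign(pd.DataFrame(rows))


def make_matrix(design: StudyDesign, values: np.ndarray, genes=None) -> ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=design.sample_ids))


@pytest.fixture
def design3():
    return make_design(3)


@pytest.fixture(scope="session")
def specs():
    return canonical_comparisons()


@pytest.fixture(scope="session")
def small_study():
    """A compact study with every pattern planted; shared across tests."""
    config = SyntheticConfig(
        genes_per_pattern={"A": 10, "B": 10, "C": 10, "D": 10, "E": 10, "unresponsive": 10},
    )
    return simulate_study(config, seed=1)
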