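import numpy as np
import pandas as pd
import pytest

from radresponse import CohortConfig, simulate_cohort
from radresponse.expr import ExpressionMatrix


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    """A reduced cohort that keeps every structural feature of the default."""
    return CohortConfig(
        n_patients=12, group_sizes={"good": 5, "intermediate": 4, "poor": 3},
        n_genes=120, n_housekeeping=10, baseline_de_genes=10,
        longitudinal_de_genes=20, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


def make_matrix(values: np.ndarray, classes: list[str], state: str = "raw",
                samples: pd.DataFrame | None = None,
                gene_names: list[str] | None = None) -> ExpressionMatrix:
    """Hand-rolled ExpressionMatrix from an array and per-gene classes."""
    genes = gene_names or [f"g{i}" for i in range(values.shape[0])]
    cols = (samples.index if samples is not None
            else [f"s{j}" for j in range(values.shape[1])])
    df = pd.DataFrame(values, index=genes, columns=cols)
    return ExpressionMatrix(values=df,
                            gene_classes=pd.Series(classes, index=genes),
                            samples=samples, state=state)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
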