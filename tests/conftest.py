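import numpy as np
import pandas as pd
import pytest

from consig.io_model import DEGCollection, DEGRecord, GeneSet, SurvivalDataset
from consig.synthetic_data import SurvGenConfig, gen_survival_cohort


@pytest.fixture
def tiny_collection() -> DEGCollection:
    """Three cohorts over five genes with known occurrence counts.

    occurrence: JUN=3, MPO=2, FOS=2, IL1B=1, THBS1=1.
    """

    def rec(g, lfc, p=0.01):
        return DEGRecord(gene=g, logfc=lfc, adj_p=p)

    return DEGCollection(
        datasets=[
            ("AML1", [rec("JUN", 2.0), rec("MPO", -1.5), rec("IL1B", 1.0)]),
            ("AML2", [rec("JUN", 2.5), rec("MPO", -1.0), rec("FOS", 1.2)]),
            ("AML3", [rec("JUN", 1.5), rec("FOS", 0.8), rec("THBS1", -2.0)]),
        ]
    )


@pytest.fixture
def planted_cohort() -> SurvivalDataset:
    """n=500 cohort with one strong hazard gene (beta = 0.8) among 20."""
    return gen_survival_cohort(
        SurvGenConfig(
            n_samples=500, n_genes=20, planted=(("G0001", 0.8),), seed=11,
            cohort_id="planted",
        )
    )


@pytest.fixture
def signature_set() -> GeneSet:
    return GeneSet(name="sig", genes=frozenset(f"SG{i:03d}" for i in range(20)))


def make_survival(time, event, x=None, genes=None) -> SurvivalDataset:
    """Hand-built survival dataset from raw vectors (helper, not a fixture)."""
    time = np.asarray(time, dtype=float)
    n = len(time)
    if x is None:
        x = np.zeros((1, n))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    genes = genes or [f"g{i}" for i in range(x.shape[0])]
    expr = pd.DataFrame(x, index=genes, columns=[f"s{i}" for i in range(n)])
    return SurvivalDataset(expression=expr, time=time, event=np.asarray(event), cohort_id="hand")
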