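import numpy as np
import pandas as pd
import pytest

from rbppairsig.dataio import ClinicalTable, ExpressionMatrix


def make_expression(values, genes=None, samples=None, group=None) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=samples)
    if group is None:
        grp = pd.Series("tumor", index=samples)
    else:
        grp = pd.Series(group, index=samples)
    return ExpressionMatrix(df, grp)


def make_clinical(os_time, os_event, index=None, **cols) -> ClinicalTable:
    index = index or [f"p{i+1}" for i in range(len(os_time))]
    return ClinicalTable(
        pd.DataFrame({"os_time": os_time, "os_event": os_event, **cols}, index=index)
    )


@pytest.fixture
def six_patient_fixture():
    """All-event toy cohort: high risk dies at 1,2,3; low at 4,5,6."""
    clin = make_clinical([1, 2, 3, 4, 5, 6], [1] * 6, index=list("abcdef"))
    groups = pd.Series(["high"] * 3 + ["low"] * 3, index=list("abcdef"))
    return groups, clin


@pytest.fixture
def small_cohort():
    """Modest planted-signal cohort shared by several tests."""
    from rbppairsig.synthetic import generate_cohort

    return generate_cohort(
        n_tumor=150,
        n_normal=30,
        n_genes=40,
        n_signal_pairs=5,
        gamma=0.8,
        lambda0=1e-5,
        seed=42,
    )
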