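import numpy as np
import pandas as pd
import pytest

from bonescreen import ClinicalTable, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20220530)


@pytest.fixture
def matrix_factory():
    """Build an ExpressionMatrix from a 2-D array with auto-generated names."""

    def make(values, genes=None, samples=None, cohort="TEST"):
        values = np.asarray(values, dtype=float)
        genes = genes or [f"G{i+1}" for i in range(values.shape[0])]
        samples = samples or [f"S{i+1}" for i in range(values.shape[1])]
        return ExpressionMatrix(cohort, pd.DataFrame(values, index=genes, columns=samples))

    return make


@pytest.fixture
def clinical_factory():
    """Build a ClinicalTable from parallel per-sample lists."""

    def make(sample_ids, met_status=None, bmfs_time=None, bmfs_event=None, lesion_site=None):
        data = {"sample_id": sample_ids}
        if met_status is not None:
            data["met_status"] = met_status
        if bmfs_time is not None:
            data["bmfs_time"] = bmfs_time
        if bmfs_event is not None:
            data["bmfs_event"] = bmfs_event
        if lesion_site is not None:
            data["lesion_site"] = lesion_site
        return ClinicalTable(pd.DataFrame(data))

    return make


@pytest.fixture
def two_class_cohort(rng, matrix_factory, clinical_factory):
    """80-sample NONE/BONE cohort with one +2 log2 shifted gene (G1)."""
    n_none, n_bone = 60, 20
    n = n_none + n_bone
    values = rng.normal(8.0, 1.0, size=(30, n))
    values[0, n_none:] += 2.0  # G1 up in BONE
    samples = [f"S{i}" for i in range(n)]
    matrix = matrix_factory(values, samples=samples)
    clinical = clinical_factory(
        samples,
        met_status=["NONE"] * n_none + ["BONE"] * n_bone,
        bmfs_time=list(rng.uniform(1, 60, size=n)),
        bmfs_event=[0] * n_none + [1] * n_bone,
    )
    return matrix, clinical
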