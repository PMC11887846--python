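import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pseudomics.containers import NucleusMatrix, PseudobulkAssay
from pseudomics.synthetic import generate_cohort, generate_prs


@pytest.fixture
def small_nucleus_matrix() -> NucleusMatrix:
    """Three nuclei x two features with hand-set metadata."""
    counts = sp.csr_matrix(np.array([[1, 2], [3, 4], [5, 6]]))
    meta = pd.DataFrame(
        {
            "nucleus_id": ["n1", "n2", "n3"],
            "donor_id": ["d1", "d1", "d1"],
            "cell_type": ["Exc", "Exc", "Ast"],
            "total_counts": [3, 7, 11],
            "n_features_detected": [2, 2, 2],
            "mito_fraction": [0.01, 0.02, 0.03],
        }
    )
    return NucleusMatrix(counts=counts, nucleus_meta=meta, feature_ids=["g1", "g2"])


@pytest.fixture
def cohort40() -> pd.DataFrame:
    return generate_cohort(40, seed=11)


@pytest.fixture
def cohort_with_prs():
    cohort = generate_cohort(90, seed=5)
    prs = generate_prs(cohort, "schizophrenia", liability_correlation=0.3, seed=6)
    return cohort, prs


def make_assay(values: np.ndarray, donors=None, cell_type="Exc", modality="rna_counts",
               n_cells=None, normalized=False) -> PseudobulkAssay:
    """Build a PseudobulkAssay from a plain features x samples array."""
    n_feat, n_samp = values.shape
    donors = donors or [f"d{i}" for i in range(n_samp)]
    sample_ids = [f"{d}|{cell_type}" for d in donors]
    n_cells = n_cells if n_cells is not None else np.ones(n_samp, dtype=int)
    return PseudobulkAssay(
        values=pd.DataFrame(values, index=[f"g{i}" for i in range(n_feat)], columns=sample_ids),
        sample_meta=pd.DataFrame(
            {"donor_id": donors, "cell_type": cell_type, "n_cells": n_cells}, index=sample_ids
        ),
        modality=modality,
        normalized=normalized,
    )
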