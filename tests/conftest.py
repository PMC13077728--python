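import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ctprs.core import FeatureMatrix


def make_cells(n, cell_type="AST", **overrides):
    """Control-compatible cell metadata, overridable per column."""
    base = {
        "cell_id": [f"c{i}" for i in range(n)],
        "donor_id": ["d0"] * n,
        "cell_type": [cell_type] * n,
        "subtype": [None] * n,
        "tss_enrichment": [2.0] * n,
        "braak": [1] * n,
        "neuritic_plaque_status": ["none"] * n,
        "mmse": [28.0] * n,
        "cognitive_status": ["NCI"] * n,
        "control_flag": [True] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


def make_features(n, chrom="chr1", width=500, stride=1000, prefix="f"):
    return pd.DataFrame(
        {
            "feature_id": [f"{prefix}{i}" for i in range(n)],
            "chrom": chrom,
            "start": [i * stride for i in range(n)],
            "end": [i * stride + width for i in range(n)],
            "strand": "+",
        }
    )


def make_matrix(counts, cell_types, modality="RNA", features=None):
    counts = np.asarray(counts)
    n_cells, n_feat = counts.shape
    cells = make_cells(n_cells)
    cells["cell_type"] = list(cell_types)
    if features is None:
        features = make_features(n_feat)
    return FeatureMatrix(
        counts=sp.csr_matrix(counts),
        modality=modality,
        features=features,
        cells=cells,
    )


@pytest.fixture(scope="session")
def small_reference():
    """Planted 3-type reference shared across read-only tests."""
    from ctprs.synthdata import simulate_reference

    return simulate_reference(
        n_types=3, n_cells_per_type=30, n_features=300,
        n_markers_per_type=15, fold=4.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_study():
    """End-to-end synthetic study (AST causal) shared across read-only tests."""
    from ctprs.synthdata import simulate_study

    return simulate_study(causal_type="AST", seed=7, n_samples=600)
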