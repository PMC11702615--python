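import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

import slicefidelity as sf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_count_matrix(dense, gene_ids=None, barcodes=None) -> sf.CountMatrix:
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    return sf.CountMatrix(
        counts=sp.csr_matrix(dense),
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        gene_names=gene_ids or [f"g{i}" for i in range(n_genes)],
        cell_barcodes=barcodes or [f"bc{i}" for i in range(n_cells)],
    )


def make_annotation(barcodes, cell_types, timepoint="day0", sample_id="A") -> sf.CellAnnotation:
    return sf.CellAnnotation(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "sample_id": sample_id,
                "timepoint": timepoint,
                "cell_type": cell_types,
            }
        )
    )


def analyze_pair(sim, alpha=0.05, correlation="pearson"):
    """Significance union -> signatures -> correlation matrix for a simulated pair."""
    tables = {}
    for timepoint in ("day0", "day14"):
        cm, ann = sim[timepoint]
        tables[timepoint] = sf.one_vs_rest_de(cm, ann, timepoint)
    union = sf.significant_gene_union(tables["day0"], tables["day14"], alpha)
    signatures = {}
    for timepoint in ("day0", "day14"):
        cm, ann = sim[timepoint]
        fallback = sf.normalized_group_means(cm, ann, timepoint)
        signatures[timepoint] = sf.build_signature_matrix(
            tables[timepoint], union, timepoint, fallback
        )
    return sf.correlate_signatures(signatures["day0"], signatures["day14"], correlation)


def mean_diagonal(corr) -> float:
    matched, _ = sf.diagonal_fidelity(corr)
    return float(np.mean([r for _, r in matched]))


@pytest.fixture(scope="session")
def small_config():
    """Three balanced cell types at reduced size, for fast end-to-end tests."""
    return sf.SyntheticConfig(
        seed=7,
        n_genes=600,
        cell_types=[
            sf.CellTypeSpec("astrocyte", 300, 300),
            sf.CellTypeSpec("microglia", 300, 300),
            sf.CellTypeSpec("tumor", 300, 300),
        ],
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return sf.simulate_paired_experiment(small_config)
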