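import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import metasig as ms


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort: 4 patients, planted 40-gene program."""
    cfg = ms.SimConfig(
        n_patients=4,
        n_cancer_types=2,
        cells_per_patient=500,
        n_genes=800,
        program_size=40,
        seed=11,
    )
    matrices, truth = ms.gen_pan_cancer(cfg)
    return cfg, matrices, truth


@pytest.fixture()
def toy_counts():
    """Hand-built 4 genes x 3 cells count matrix."""
    counts = np.array(
        [
            [10, 0, 1],
            [0, 5, 1],
            [3, 2, 2],
            [0, 0, 4],
        ]
    )
    meta = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "patient_id": "P1",
            "sample_id": "P1",
            "cancer_type": "lung",
            "cell_type": ["epithelial", "fibroblast", "epithelial"],
        }
    ).set_index("cell_id")
    return ms.CountMatrix(["g1", "g2", "g3", "g4"], ["c1", "c2", "c3"],
                          sp.csr_matrix(counts), meta)


def make_lognorm(values: np.ndarray, genes=None, cells=None, meta=None) -> ms.LogNormMatrix:
    """Wrap a dense array of non-negative values as a LogNormMatrix."""
    n_g, n_c = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    cells = cells or [f"c{j}" for j in range(n_c)]
    return ms.LogNormMatrix(genes, cells, sp.csr_matrix(values), meta)
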