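import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

import nichecoloc as nc


def make_cell_matrix(counts, mito_genes=(), **obs_overrides) -> AnnData:
    """AnnData from a dense cells x genes count array with consistent QC
    metadata (UMI = row sum, n_genes = nonzero count)."""
    counts = np.asarray(counts, dtype=np.int64)
    n_cells, n_genes = counts.shape
    gene_names = [f"g{j}" for j in range(n_genes)]
    for j in mito_genes:
        gene_names[j] = f"MT-{j}"
    mito_idx = list(mito_genes)
    total = counts.sum(axis=1)
    obs = pd.DataFrame(
        {
            "total_counts": total,
            "n_genes": (counts > 0).sum(axis=1),
            "mito_frac": counts[:, mito_idx].sum(axis=1) / np.maximum(total, 1)
            if mito_idx
            else np.zeros(n_cells),
            "doublet": np.zeros(n_cells, dtype=bool),
            "cluster": pd.Categorical(["c0"] * n_cells),
            "condition": pd.Categorical(
                ["control", "disease"] * (n_cells // 2) + ["control"] * (n_cells % 2)
            ),
        },
        index=[f"cell{i}" for i in range(n_cells)],
    )
    for key, val in obs_overrides.items():
        obs[key] = val
    return AnnData(X=sp.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=gene_names))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_spots():
    """Two tiny samples (one per condition) with uniform random coordinates."""
    rng = np.random.default_rng(42)
    frames = []
    for cond in ("control", "disease"):
        n = 60
        frames.append(
            pd.DataFrame(
                {
                    "spot_id": [f"{cond}_{i}" for i in range(n)],
                    "x": rng.uniform(size=n),
                    "y": rng.uniform(size=n),
                    "sample_id": f"{cond}_1",
                    "condition": cond,
                    "score_A": rng.uniform(size=n),
                    "score_B": rng.uniform(size=n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def sim_cells_lowq():
    """Generated matrix with 20% constructed low-quality cells (100 cells)."""
    return nc.generate_cell_matrix(
        nc.ScSimParams(n_cells=100, frac_low_quality=0.2, seed=3)
    )


@pytest.fixture(scope="session")
def roi_table():
    return nc.generate_roi_table(nc.RoiSimParams(seed=7))
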