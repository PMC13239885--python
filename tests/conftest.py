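import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nichesig.synthetic import (
    SimBulkConfig,
    SimSingleCellConfig,
    SimSpatialConfig,
    SubclusterSpec,
    generate_bulk_cohort,
    generate_single_cell,
    generate_spatial_grid,
)
from nichesig.signatures import normalize_counts


def make_grid(width, height, values=None, missing=()):
    """Dense integer-lattice AnnData with one gene; optional holes."""
    coords = [(x, y) for x in range(width) for y in range(height)
              if (x, y) not in set(missing)]
    obs = pd.DataFrame({"x": [c[0] for c in coords], "y": [c[1] for c in coords]},
                       index=[f"s{x}_{y}" for x, y in coords])
    n = len(coords)
    if values is None:
        values = np.ones(n)
    X = sp.csr_matrix(np.asarray(values, dtype=float).reshape(n, 1))
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=["g"]))


@pytest.fixture(scope="session")
def small_cells():
    """Two T subclusters with planted markers plus a B compartment."""
    split = {("tumour", "short"): 40, ("tumour", "long"): 40,
             ("blood", "short"): 20, ("blood", "long"): 20}
    cfg = SimSingleCellConfig(
        n_genes=600,
        subclusters=(
            SubclusterSpec("DPT", "T", dict(split), n_markers=20, marker_fold=4.0),
            SubclusterSpec("Tconv", "T", dict(split), n_markers=20, marker_fold=4.0),
            SubclusterSpec("Bcell", "B", dict(split)),
        ),
        seed=42,
    )
    return cfg, generate_single_cell(cfg)


@pytest.fixture(scope="session")
def normed_cells(small_cells):
    _, adata = small_cells
    return normalize_counts(adata.copy())


@pytest.fixture(scope="session")
def bulk_cohort():
    cfg = SimBulkConfig(n_samples=120, n_genes=80, log_hr_per_sd=np.log(2),
                        response_rate=0.4, response_effect=1.0, seed=7)
    return cfg, generate_bulk_cohort(cfg)


@pytest.fixture(scope="session")
def colocalized_grid():
    cfg = SimSpatialConfig(
        signatures={"DPT": tuple(f"D{i}" for i in range(10)),
                    "capillaryEC": tuple(f"C{i}" for i in range(10))},
        colocalization=1.0, seed=3,
    )
    return cfg, generate_spatial_grid(cfg)
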