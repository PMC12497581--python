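import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import spotsplit as ss


@pytest.fixture(scope="session")
def small_spatial():
    """A compact mixed-type dataset: 3 types, 120 spots, quick to deconvolve."""
    cfg = ss.SpatialSimConfig(
        n_types=3,
        genes_per_module=8,
        n_background_genes=6,
        n_spots=120,
        cells_per_spot_range=(2, 6),
        type_proportions=(0.6, 0.2, 0.2),
        seed=11,
    )
    return cfg, *ss.generate_spatial(cfg)


@pytest.fixture(scope="session")
def default_spatial():
    """The default study conditions (dominant type at 80%, 500 spots)."""
    cfg = ss.SpatialSimConfig(seed=1)
    return cfg, *ss.generate_spatial(cfg)


@pytest.fixture(scope="session")
def small_deconvolution(small_spatial):
    cfg, matrix, layout, truth = small_spatial
    result = ss.run_deconvolution(
        matrix, layout, ss.DeconvolutionConfig(cut_height=0.9, seed=5)
    )
    return matrix, layout, truth, result


def toy_cellset(counts: np.ndarray, clusters: list[str]) -> ss.PutativeCellSet:
    """Wrap a dense genes x cells array into a PutativeCellSet at the origin."""
    n = counts.shape[1]
    return ss.PutativeCellSet(
        cell_ids=[f"c{i}" for i in range(n)],
        clusters=clusters,
        source_barcodes=["SPOT-00000"] * n,
        x=np.zeros(n),
        y=np.zeros(n),
        counts=sp.csr_matrix(counts),
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
    )


def simple_bulk_table(values: np.ndarray, classes: list[str]) -> ss.BulkExpressionTable:
    genes = [f"g{i}" for i in range(values.shape[0])]
    n = values.shape[1]
    samples = [f"s{i}" for i in range(n)]
    groups = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return ss.BulkExpressionTable(
        values=pd.DataFrame(values, index=genes, columns=samples, dtype=float),
        probe_class=pd.Series(classes, index=genes),
        groups=pd.Series(groups, index=samples),
    )
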