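import numpy as np
import pytest

import modfish as mf


def make_views(cell_scaled, gene_ids=None, cell_ids=None, labels=None,
               scale_factor=None, pseudo_count=1.0):
    """NormalizedViews straight from a given cell-scaled matrix (test helper)."""
    cell_scaled = np.asarray(cell_scaled, dtype=float)
    n_genes, n_cells = cell_scaled.shape
    gene_ids = np.array(
        [f"g{i}" for i in range(n_genes)] if gene_ids is None else gene_ids,
        dtype=object,
    )
    cell_ids = np.array(
        [f"c{i}" for i in range(n_cells)] if cell_ids is None else cell_ids,
        dtype=object,
    )
    log_view = np.log(cell_scaled + pseudo_count)
    from modfish.reference import standardize_genes

    return mf.NormalizedViews(
        cell_scaled=cell_scaled,
        log_view=log_view,
        gene_scaled=standardize_genes(log_view),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        scale_factor=scale_factor or cell_scaled.sum(axis=0).mean(),
        pseudo_count=pseudo_count,
        cell_labels=None if labels is None else np.asarray(labels, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_ref(rng):
    """50 genes x 120 cells, 3 cell types, 2 planted modules, 2 mito genes."""
    cfg = mf.SimulationConfig(
        n_cells=120,
        n_genes=50,
        n_cell_types=3,
        modules=[
            mf.ModuleSpec("m0", (0, 1, 2, 3), 0, fold_change=8),
            mf.ModuleSpec("m1", (4, 5, 6, 7), 1, fold_change=8),
        ],
        mito_gene_indices=(48, 49),
        seed=7,
    )
    return mf.simulate_reference(cfg)


@pytest.fixture
def small_views(small_ref):
    return mf.normalize_views(small_ref[0])


@pytest.fixture
def planted_sim():
    """Strong planted structure: 5 types, 5 modules of 8 genes, fold 8."""
    mods = [
        mf.ModuleSpec(f"m{t}", tuple(range(8 * t, 8 * t + 8)), t, fold_change=8)
        for t in range(5)
    ]
    cfg = mf.SimulationConfig(
        n_cells=1500, n_genes=80, n_cell_types=5, modules=mods, seed=11
    )
    return mf.simulate_reference(cfg)
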