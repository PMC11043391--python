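import numpy as np
import pandas as pd
import pytest

from screenkit.pooled import GuideCountMatrix
from screenkit import synthetic as syn


@pytest.fixture
def tiny_matrix():
    """3-guide, 2-sample count matrix."""
    counts = pd.DataFrame(
        {"s1": [10, 20, 30], "s2": [12, 18, 33]},
        index=pd.Index(["gA_sg1", "gA_sg2", "gB_sg1"], name="guide"),
    )
    genes = pd.Series(["GA", "GA", "GB"], index=counts.index, name="gene")
    return GuideCountMatrix(counts=counts, guide_to_gene=genes)


@pytest.fixture
def small_screen():
    """Small pooled screen with planted resistance genes."""
    cfg = syn.ScreenSimConfig(n_genes=100, guides_per_gene=4, n_resistant=5, seed=7)
    return syn.simulate_pooled_screen(cfg)


@pytest.fixture
def cell_plate():
    """One simulated plate: NTC plus a 1.5-fold and a null perturbation."""
    folds = {"NTC": 1.0, "HIT1": 1.5, "NULL1": 1.0}
    cfg = syn.CellSimConfig(cells_per_well=400, planted_fold=folds, seed=11)
    design = syn.default_plate_design(folds, wells_per_condition=2)
    return syn.simulate_cell_table(cfg, design), folds
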