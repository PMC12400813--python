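import numpy as np
import pytest
from sklearn.model_selection import train_test_split

import swarmlda as sw


@pytest.fixture(scope="session")
def counts_fixture():
    """The standard 4-type, 800x1000 count fixture (seed 7) with truth markers."""
    cfg = sw.SimConfig(seed=7)
    matrix, labels, markers = sw.simulate_counts(cfg)
    return {"cfg": cfg, "matrix": matrix, "labels": labels, "markers": markers}


@pytest.fixture(scope="session")
def trained_fixture(counts_fixture):
    """A trained 20-member ensemble on a 75/25 split of the count fixture."""
    matrix, labels = counts_fixture["matrix"], counts_fixture["labels"]
    idx = np.arange(matrix.n_cells)
    tr, te = train_test_split(idx, test_size=0.25, stratify=labels.codes, random_state=7)
    config = sw.RunConfig(n_models=20, min_genes_per_cell=10, seed=7)
    ref, ref_lab = matrix.subset(cell_idx=tr), labels.subset(tr)
    qry, qry_lab = matrix.subset(cell_idx=te), labels.subset(te)
    model, plan, screen, qc, qc_lab = sw.train_pipeline(ref, ref_lab, config)
    return {
        "config": config,
        "model": model,
        "plan": plan,
        "screen": screen,
        "ref_raw": ref,
        "ref_lab": ref_lab,
        "ref_norm": sw.log_normalize(qc, config.scale_factor),
        "qc_lab": qc_lab,
        "query_raw": qry,
        "query_norm": sw.prepare_query(qry, config.scale_factor),
        "query_lab": qry_lab,
    }
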