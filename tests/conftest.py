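import numpy as np
import pytest

import ednacnn as e


@pytest.fixture(scope="session")
def toy_db():
    """Well-separated 10-species reference DB with 2-4 variants each."""
    db, meta = e.simulate_reference_db(
        n_species=10, amplicon_len=60, min_divergence=0.1,
        seqs_per_species_range=(2, 4), seed=3,
    )
    return db


@pytest.fixture(scope="session")
def toy_classifier(toy_db):
    """Classifier trained on the bare toy amplicons (no decoration)."""
    cfg = e.ModelConfig(n_classes=toy_db.n_classes, dense_layers=[64, 64])
    clf = e.build(cfg, dict(toy_db.label_index), seed=3)
    e.train(clf, toy_db, e.AugmentConfig.training(), epochs=30, seed=3)
    return clf


@pytest.fixture(scope="session")
def manifest5():
    """1 river x 2 filters, 5 PCR replicates total (2 + 3)."""
    m = e.simulate_tag_manifest(
        n_rivers=1, filters_per_river=2, replicates_per_filter=2, seed=3
    )
    # add a fifth replicate under the second filter via a fresh manifest
    m2 = e.simulate_tag_manifest(
        n_rivers=1, filters_per_river=1, replicates_per_filter=5, seed=3
    )
    return m2


def tau_b_bruteforce(x, y):
    """O(n^2) pair-counting oracle for the tie-corrected rank correlation."""
    P = Q = Tx = Ty = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                Tx += 1
            elif dy == 0:
                Ty += 1
            elif dx == dy:
                P += 1
            else:
                Q += 1
    denom = np.sqrt((P + Q + Tx) * (P + Q + Ty))
    return np.nan if denom == 0 else (P - Q) / denom
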