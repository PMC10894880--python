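import numpy as np
import pandas as pd
import pytest

from histofuse import patch, synthetic

TEX_A = synthetic.TextureLaw(blob_density=40.0, stripe_frequency=6.0)
TEX_B = synthetic.TextureLaw(blob_density=5.0, stripe_frequency=2.0)


@pytest.fixture(scope="session")
def texture_tiles():
    """300 tiles (64px): two texture classes, half A / half B, interleaved."""
    tiles, labels = [], []
    for i in range(150):
        tiles.append(synthetic.generate_tile_image(TEX_A, seed=i, size=64))
        labels.append("A")
        tiles.append(synthetic.generate_tile_image(TEX_B, seed=1000 + i, size=64))
        labels.append("B")
    return tiles, labels


@pytest.fixture(scope="session")
def trained_patch_model(texture_tiles):
    """CNN trained on the first 200 texture tiles; reused across tests."""
    tiles, labels = texture_tiles
    cfg = patch.TrainConfig(epochs=12, seed=0, input_size=32,
                            eta_max=0.1, batch_size=32)
    model, log = patch.train_patch_classifier(tiles[:200], labels[:200], cfg)
    return model, log, cfg


@pytest.fixture(scope="session")
def binary_cohort():
    """Separable binary likelihood cohort: Beta(8,2) vs Beta(2,8), 30+30 cases."""
    spec = synthetic.SyntheticSpec(
        n_cases_per_class={"A": 30, "B": 30},
        likelihood_law={"A": (8.0, 2.0), "B": (2.0, 8.0)},
        slides_per_case=(1, 3),
        tiles_per_slide=(20, 60),
        seed=7,
    )
    table, cohort = synthetic.generate_likelihood_table(spec)
    return spec, table, cohort


@pytest.fixture()
def tiny_table():
    """Hand-sized two-case table for exact fusion arithmetic."""
    rows = []
    for i, p in enumerate([0.14, 0.17, 0.86]):
        rows.append({"case_id": "c1", "slide_id": "c1_s0", "col": i, "row": 0,
                     "p_A": 1 - p, "p_B": p,
                     "label": "B" if p > 0.5 else "A"})
    rows.append({"case_id": "c2", "slide_id": "c2_s0", "col": 0, "row": 0,
                 "p_A": 0.1, "p_B": 0.9, "label": "B"})
    table = pd.DataFrame(rows)
    cohort = pd.DataFrame({"case_id": ["c1", "c2"],
                           "class_label": ["A", "B"],
                           "recurrence": [0, 1]})
    return table, cohort


def rank_auc(scores, labels) -> float:
    """Brute-force pairwise AUC oracle (ties count half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
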