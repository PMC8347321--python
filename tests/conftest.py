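import numpy as np
import pytest

import cypclass as cc
from cypclass.curate import CypIsozyme


@pytest.fixture(scope="session")
def clean_dataset():
    """100-compound noiseless fixture set, 1:4 substrate ratio."""
    return cc.generate_labeled_set(
        cc.FixtureConfig(n_compounds=100, imbalance_ratio=(1, 4), seed=11)
    )


@pytest.fixture(scope="session")
def cyp3a4():
    return CypIsozyme("3A4")


@pytest.fixture(scope="session")
def small_rf_model(clean_dataset, cyp3a4):
    """A quickly trained RF/MACCS classifier on the clean fixture set."""
    spec = cc.SingleClassifierSpec(
        cyp=cyp3a4,
        algorithm=cc.Algorithm.RF,
        feature_set=cc.FeatureSet.MACCS,
        seed=42,
        n_estimators=60,
    )
    model, train_idx, test_idx, feats = cc.train_classifier(
        clean_dataset, spec, grid=cc.train.FAST_GRID
    )
    X = feats.values.to_numpy(float)
    labels = clean_dataset.subset_for(cyp3a4).labels_for(cyp3a4)
    y = np.array([1 if l is cc.ActivityLabel.SUBSTRATE else 0 for l in labels])
    return {
        "model": model,
        "train_idx": train_idx,
        "test_idx": test_idx,
        "X": X,
        "y": y,
        "subset": clean_dataset.subset_for(cyp3a4),
    }
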