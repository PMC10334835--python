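import numpy as np
import pandas as pd
import pytest

from chpf import (GeneratorConfig, GMMConsensusLabeler,
                  HypoxiaEnsembleClassifier, filter_genes, generate_dataset,
                  normalize_expression, ssgsea_scores)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted-program dataset shared across module tests."""
    cfg = GeneratorConfig(
        n_cells=300, n_genes=400, n_program_genes=60, signature_size=30,
        n_markers_per_celltype=10, seed=3,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_lognorm(small_dataset):
    matrix, _, _, _ = small_dataset
    return normalize_expression(filter_genes(matrix))


@pytest.fixture(scope="session")
def small_scores(small_dataset, small_lognorm):
    _, _, _, signatures = small_dataset
    return ssgsea_scores(small_lognorm, signatures)


@pytest.fixture(scope="session")
def small_labels(small_scores):
    return GMMConsensusLabeler(random_state=0).fit_predict(small_scores.to_frame().T)


@pytest.fixture(scope="session")
def small_model(small_lognorm, small_labels):
    hc = small_labels.index[small_labels != "unclassified"]
    X = small_lognorm.subset_cells(list(hc)).to_cells_by_genes()
    est = HypoxiaEnsembleClassifier(
        n_features=100, n_members=10, k_folds=5, min_child_samples=3, random_state=7
    )
    return est.fit(X, small_labels.loc[hc])


class StubBooster:
    """Minimal committee member with fixed per-cell hypoxia probabilities."""

    def __init__(self, probs, importance=None):
        self.probs = np.asarray(probs, dtype=float)
        self.importance = importance

    def predict(self, X):
        return self.probs[: X.shape[0]]

    def feature_importance(self, importance_type="split"):
        return np.asarray(self.importance)


@pytest.fixture
def make_stub_ensemble():
    """Factory assembling a HypoxiaEnsembleClassifier from stub members."""
    from chpf.classifier import FeaturePanel

    def _make(member_probs, weights, feature_genes=("g1", "g2")):
        est = HypoxiaEnsembleClassifier(n_members=len(weights))
        stats_tbl = pd.DataFrame(
            {"statistic": 0.0, "p_value": 0.5, "log2fc": 0.0}, index=list(feature_genes)
        )
        est.feature_panel_ = FeaturePanel(list(feature_genes), stats_tbl)
        est.classes_ = np.array(["hypoxic", "normoxic"], dtype=object)
        est.members_ = [StubBooster(p) for p in member_probs]
        est.weights_ = np.asarray(weights, dtype=float)
        est.fold_map_ = np.zeros(len(weights), dtype=int)
        est.member_seeds_ = np.zeros(len(weights), dtype=int)
        return est

    return _make
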