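import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chpf import (CellMetadata, ExpressionMatrix, HypoxiaEnsembleClassifier,
                  cell_type_signatures, select_deg_features, vote)
from chpf.classifier import log2_fold_change, rank_sum_test, voting_rate


class TestRankSumTest:
    def test_matches_scipy_per_gene(self):
        """Vectorized tie-corrected normal approximation agrees with the
        per-gene scipy Mann-Whitney asymptotic test."""
        rng = np.random.default_rng(0)
        x = rng.poisson(2, size=(40, 15)).astype(float)  # ties guaranteed
        y = rng.poisson(3, size=(40, 25)).astype(float)
        z, p = rank_sum_test(x, y)
        for i in range(40):
            ref = stats.mannwhitneyu(x[i], y[i], alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
            assert p[i] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_constant_gene_gives_unit_pvalue(self):
        z, p = rank_sum_test(np.ones((1, 5)), np.ones((1, 5)))
        assert z[0] == 0.0 and p[0] == 1.0


class TestFeatureSelection:
    def test_planted_program_recovered(self, small_lognorm, small_dataset):
        _, _, status, _ = small_dataset
        program = [g for g in small_dataset.program_genes
                   if g in set(small_lognorm.gene_ids)]
        panel = select_deg_features(small_lognorm, status, n_features=80)
        recovered = len(set(program) & set(panel.genes)) / len(program)
        assert recovered >= 0.9

    def test_clamps_when_fewer_genes_than_requested(self, small_lognorm, small_labels, caplog):
        with caplog.at_level("WARNING"):
            panel = select_deg_features(small_lognorm, small_labels, n_features=10**6)
        assert len(panel.genes) == small_lognorm.n_genes
        assert "features" in caplog.text

    def test_deterministic_tiebreak(self, small_lognorm, small_labels):
        a = select_deg_features(small_lognorm, small_labels, 50).genes
        b = select_deg_features(small_lognorm, small_labels, 50).genes
        assert a == b

    def test_missing_class_is_error(self, small_lognorm):
        labels = pd.Series("hypoxic", index=small_lognorm.cell_ids)
        with pytest.raises(ValueError, match="class"):
            select_deg_features(small_lognorm, labels)

    def test_nonpositive_n_features_is_error(self, small_lognorm, small_labels):
        with pytest.raises(ValueError):
            select_deg_features(small_lognorm, small_labels, 0)


class TestEnsembleTraining:
    def test_member_and_fold_bookkeeping(self, small_model):
        assert len(small_model.members_) == 10
        np.testing.assert_array_equal(np.bincount(small_model.fold_map_), [2] * 5)

    def test_every_member_trained_class_balanced(self, small_model):
        hyp, norm = small_model.member_train_counts_.T
        np.testing.assert_array_equal(hyp, norm)

    def test_perfectly_separable_classes_give_unit_recall_weights(self):
        rng = np.random.default_rng(1)
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 20)),
                         columns=[f"g{i}" for i in range(20)],
                         index=[f"c{i}" for i in range(n)])
        y = np.array(["hypoxic"] * 50 + ["normoxic"] * 70, dtype=object)
        X.iloc[:50, :5] += 100.0  # perfectly separating block of features
        est = HypoxiaEnsembleClassifier(
            n_features=20, n_members=10, k_folds=5, random_state=0,
        ).fit(X, y)
        np.testing.assert_array_equal(est.weights_, 1.0)

    def test_n_members_divisibility_enforced(self, small_lognorm, small_labels):
        hc = small_labels.index[small_labels != "unclassified"]
        X = small_lognorm.subset_cells(list(hc)).to_cells_by_genes()
        est = HypoxiaEnsembleClassifier(n_members=7, k_folds=5)
        with pytest.raises(ValueError, match="divisible"):
            est.fit(X, small_labels.loc[hc])

    def test_reproducible_fit(self, small_lognorm, small_labels):
        hc = small_labels.index[small_labels != "unclassified"]
        X = small_lognorm.subset_cells(list(hc)).to_cells_by_genes()
        kw = dict(n_features=50, n_members=10, k_folds=5,
                  min_child_samples=3, random_state=11)
        a = HypoxiaEnsembleClassifier(**kw).fit(X, small_labels.loc[hc])
        b = HypoxiaEnsembleClassifier(**kw).fit(X, small_labels.loc[hc])
        assert a.feature_panel_.genes == b.feature_panel_.genes
        np.testing.assert_array_equal(a.weights_, b.weights_)
        np.testing.assert_array_equal(a.decision_function(X), b.decision_function(X))

    def test_shuffled_labels_give_chance_level_weights(self, small_lognorm, small_labels):
        """With permuted training labels the hypoxic-class recall collapses
        toward chance rather than staying near 1."""
        hc = small_labels.index[small_labels != "unclassified"]
        X = small_lognorm.subset_cells(list(hc)).to_cells_by_genes()
        rng = np.random.default_rng(3)
        y = small_labels.loc[hc].to_numpy().copy()
        rng.shuffle(y)
        est = HypoxiaEnsembleClassifier(
            n_features=50, n_members=10, k_folds=5, min_child_samples=3,
            random_state=3,
        ).fit(X, y)
        assert np.median(est.weights_) < 0.8


class TestVoting:
    def test_voting_rate_formula_random_configurations(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t, n = rng.integers(2, 30), rng.integers(1, 10)
            w = rng.uniform(size=t)
            ind = rng.integers(0, 2, size=(t, n))
            got = voting_rate(ind, w)
            want = (w @ ind) / w.sum()
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-15)
            assert np.all((got >= 0) & (got <= 1))

    def test_equal_weights_reduce_to_vote_fraction(self):
        ind = np.array([[1, 0], [1, 1], [0, 0], [1, 0]])
        np.testing.assert_allclose(voting_rate(ind, np.ones(4)), [0.75, 0.25])

    def test_hand_built_committee_asymmetric_weights(self, make_stub_ensemble):
        # weights (0.5, 1.0), predictions (hypoxic, normoxic) -> v = 1/3
        est = make_stub_ensemble([[1.0], [0.0]], [0.5, 1.0])
        X = pd.DataFrame([[0.0, 0.0]], columns=["g1", "g2"], index=["c"])
        assert est.decision_function(X)[0] == pytest.approx(0.5 / 1.5)
        assert est.predict(X)[0] == "normoxic"

    def test_boundary_half_is_hypoxic(self, make_stub_ensemble):
        est = make_stub_ensemble([[1.0], [0.0]], [1.0, 1.0])
        X = pd.DataFrame([[0.0, 0.0]], columns=["g1", "g2"], index=["c"])
        assert est.decision_function(X)[0] == 0.5
        assert est.predict(X)[0] == "hypoxic"

    def test_zero_weight_sum_is_error(self, make_stub_ensemble):
        est = make_stub_ensemble([[1.0]], [0.0])
        X = pd.DataFrame([[0.0, 0.0]], columns=["g1", "g2"], index=["c"])
        with pytest.raises(ValueError, match="uninformative"):
            est.decision_function(X)

    def test_vote_table_and_rate_bounds(self, small_model, small_lognorm):
        out = vote(small_model, small_lognorm)
        assert out["voting_rate"].between(0, 1).all()
        assert set(out["status"]) <= {"hypoxic", "normoxic"}
        hyp = out["voting_rate"] >= 0.5
        assert (out.loc[hyp, "status"] == "hypoxic").all()

    def test_missing_panel_genes_imputed_with_warning(self, small_model, small_lognorm, caplog):
        drop = small_model.feature_panel_.genes[0]
        keep = [g for g in small_lognorm.gene_ids if g != drop]
        reduced = small_lognorm.subset_genes(keep)
        with caplog.at_level("WARNING"):
            out = vote(small_model, reduced)
        assert "imputing zeros" in caplog.text
        assert len(out) == small_lognorm.n_cells


class TestStableFeatures:
    def test_strict_usage_fraction_boundary(self, make_stub_ensemble):
        """A gene used in exactly 90% of members is excluded (strict >);
        one used in every member is included."""
        from conftest import StubBooster

        est = make_stub_ensemble([[0.0]] * 10, np.ones(10),
                                 feature_genes=["exactly90", "always", "never"])
        est.members_ = [
            StubBooster([0.0], importance=[1 if t < 9 else 0, 3, 0])
            for t in range(10)
        ]
        assert est.stable_features(fraction=0.9) == ["always"]

    def test_no_qualifying_gene_warns_empty(self, make_stub_ensemble, caplog):
        from conftest import StubBooster

        est = make_stub_ensemble([[0.0]] * 4, np.ones(4), feature_genes=["a", "b"])
        est.members_ = [StubBooster([0.0], importance=[0, 0]) for _ in range(4)]
        with caplog.at_level("WARNING"):
            assert est.stable_features() == []
        assert "no gene" in caplog.text

    def test_serialization_roundtrip(self, small_model, small_lognorm, tmp_path):
        small_model.save(tmp_path / "model")
        back = HypoxiaEnsembleClassifier.load(tmp_path / "model")
        X = small_lognorm.to_cells_by_genes()
        np.testing.assert_allclose(back.decision_function(X),
                                   small_model.decision_function(X), atol=1e-12)
        assert back.feature_panel_.genes == small_model.feature_panel_.genes


class TestCellTypeSignatures:
    def _planted(self):
        """3 genes x 24 cells; gene g_up is strongly hypoxia-specific."""
        rng = np.random.default_rng(8)
        cells = [f"c{i}" for i in range(24)]
        status = pd.Series(["hypoxic"] * 12 + ["normoxic"] * 12, index=cells)
        vals = rng.uniform(0.1, 0.2, size=(3, 24))
        vals[0, :12] = np.log1p(30.0)  # big fold change, tiny p
        m = ExpressionMatrix(["g_up", "g_a", "g_b"], cells, vals, "lognorm")
        meta = CellMetadata(pd.DataFrame({"cell_type": ["T"] * 24},
                                         index=pd.Index(cells, name="cell_id")))
        return m, status, meta

    def test_planted_gene_detected(self):
        m, status, meta = self._planted()
        tbl = cell_type_signatures(m, status, meta)
        assert ("T", "g_up") in set(zip(tbl.cell_type, tbl.gene))
        assert (tbl.FDR < 0.05).all() and (tbl.log2FC > 1.5).all()

    def test_cell_type_without_both_statuses_skipped(self, caplog):
        m, status, meta = self._planted()
        status[:] = "hypoxic"
        with caplog.at_level("WARNING"):
            tbl = cell_type_signatures(m, status, meta)
        assert tbl.empty
        assert "skipped" in caplog.text
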