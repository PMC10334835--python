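"""The CHPF predictive core.

High-confidence hypoxic vs normoxic cells train a committee of gradient-
boosted tree classifiers: the top differentially expressed genes are the
feature panel, each member trains on a class-balanced undersample of one
cross-validation fold's training portion, and each member's vote is
weighted by its recall for the hypoxic class on its held-out fold. The
voting rate

    v_i = sum_t w_t * I_t(i) / sum_t w_t

(I_t(i) = 1 iff member t predicts cell i hypoxic) is the decision
statistic; v_i >= 0.5 calls the cell hypoxic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .consensus import HYPOXIC, NORMOXIC
from .data import CellMetadata, ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# differential expression


def rank_sum_test(x_pos: np.ndarray, x_neg: np.ndarray):
    """Vectorized two-sided Wilcoxon rank-sum test per gene.

    Parameters
    ----------
    x_pos, x_neg : arrays of shape (n_genes, n1) and (n_genes, n2)

    Returns
    -------
    z, p : arrays of shape (n_genes,)
        Normal-approximation statistic (tie-corrected, no continuity
        correction) and two-sided p-value.
    """
    n1, n2 = x_pos.shape[1], x_neg.shape[1]
    n = n1 + n2
    combined = np.concatenate([x_pos, x_neg], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    expect = n1 * (n + 1) / 2.0
    # permutation variance of the group-1 rank sum; exact under ties
    var = n1 * n2 / (n * (n - 1.0)) * np.sum((ranks - (n + 1) / 2.0) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (r1 - expect) / np.sqrt(var)
    z = np.where(var > 0, z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, np.clip(p, 0.0, 1.0)


def log2_fold_change(x_pos: np.ndarray, x_neg: np.ndarray) -> np.ndarray:
    """log2 fold change on the natural count scale of lognorm data.

    Means are taken over ``expm1`` of the log-normalized values with a
    pseudocount of 1 in numerator and denominator.
    """
    mean_pos = np.expm1(x_pos).mean(axis=1)
    mean_neg = np.expm1(x_neg).mean(axis=1)
    return np.log2((mean_pos + 1.0) / (mean_neg + 1.0))


@dataclass
class FeaturePanel:
    """Ordered DEG feature genes with their test statistics."""

    genes: list
    stats: pd.DataFrame  # index gene; columns statistic, p_value, log2fc

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("feature genes must be unique")


def select_deg_features(
    m: ExpressionMatrix, labels: pd.Series, n_features: int = 500
) -> FeaturePanel:
    """Rank genes by Wilcoxon rank-sum p-value (hypoxic vs normoxic) and keep the top.

    Ties in p-value break by larger \\|log2FC\\|, then lexicographic gene id.
    """
    if n_features <= 0:
        raise ValueError("n_features must be positive")
    if m.layer != "lognorm":
        raise ValueError("select_deg_features expects a lognorm matrix")
    labels = labels.reindex(m.cell_ids)
    pos = (labels == HYPOXIC).to_numpy()
    neg = (labels == NORMOXIC).to_numpy()
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("need >= 2 high-confidence cells in each class")
    z, p = rank_sum_test(m.values[:, pos], m.values[:, neg])
    lfc = log2_fold_change(m.values[:, pos], m.values[:, neg])
    tbl = pd.DataFrame(
        {"statistic": z, "p_value": p, "log2fc": lfc}, index=m.gene_ids
    )
    order = sorted(
        range(m.n_genes),
        key=lambda i: (p[i], -abs(lfc[i]), m.gene_ids[i]),
    )
    if n_features > m.n_genes:
        logger.warning(
            "requested %d features but only %d genes available", n_features, m.n_genes
        )
    top = order[: min(n_features, m.n_genes)]
    genes = [m.gene_ids[i] for i in top]
    return FeaturePanel(genes, tbl.iloc[top])


# ---------------------------------------------------------------------------
# ensemble


def voting_rate(indicators: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """v_i = sum_t w_t * I_t(i) / sum_t w_t.

    ``indicators`` is members x cells (1 = member calls the cell hypoxic),
    ``weights`` the per-member recall weights.
    """
    indicators = np.asarray(indicators, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total == 0:
        raise ValueError("all member weights are zero; ensemble is uninformative")
    # clip float roundoff of the weighted mean of 0/1 indicators
    return np.clip(weights @ indicators / total, 0.0, 1.0)


class HypoxiaEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Recall-weighted committee of gradient-boosted tree classifiers.

    Parameters
    ----------
    n_features : int, default 500
        DEG feature-panel size (selected during fit unless a panel is given).
    n_members : int, default 100
        Committee size; must be divisible by ``k_folds`` (each of the
        ``n_members / k_folds`` repeats re-draws the balanced undersample
        over every fold).
    k_folds : int, default 5
        Stratified cross-validation folds defining train/test portions.
    feature_panel : FeaturePanel, optional
        Pre-computed panel; bypasses internal DEG selection.
    n_estimators, max_depth, learning_rate, min_child_samples :
        Per-member LightGBM hyperparameters.
    random_state : int
        Drives fold assignment, undersampling and member seeds.

    Attributes
    ----------
    classes_ : ndarray, [hypoxic, normoxic]
    feature_panel_ : FeaturePanel
    members_ : list of fitted LightGBM boosters
    weights_ : ndarray, per-member recall of the hypoxic class on its held-out fold
    fold_map_ : ndarray, member -> fold index
    member_seeds_ : ndarray
    """

    def __init__(
        self,
        n_features: int = 500,
        n_members: int = 100,
        k_folds: int = 5,
        feature_panel: FeaturePanel | None = None,
        n_estimators: int = 100,
        max_depth: int = 6,
        num_leaves: int = 31,
        learning_rate: float = 0.1,
        min_child_samples: int = 10,
        max_bin: int = 63,
        random_state: int = 0,
    ):
        self.n_features = n_features
        self.n_members = n_members
        self.k_folds = k_folds
        self.feature_panel = feature_panel
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.num_leaves = num_leaves
        self.learning_rate = learning_rate
        self.min_child_samples = min_child_samples
        self.max_bin = max_bin
        self.random_state = random_state

    # -- helpers

    def _lgbm_params(self, seed: int) -> dict:
        return dict(
            objective="binary",
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            num_leaves=self.num_leaves,
            learning_rate=self.learning_rate,
            min_child_samples=self.min_child_samples,
            max_bin=self.max_bin,
            random_state=int(seed),
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )

    @staticmethod
    def _check_X(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a cells x genes DataFrame")
        if not np.all(np.isfinite(X.to_numpy())):
            raise ValueError("non-finite feature values")
        return X

    def _panel_matrix(self, X: pd.DataFrame) -> np.ndarray:
        genes = self.feature_panel_.genes
        missing = [g for g in genes if g not in X.columns]
        if missing:
            logger.warning(
                "%d panel genes absent from matrix; imputing zeros", len(missing)
            )
        out = np.zeros((X.shape[0], len(genes)))
        present = [g for g in genes if g in X.columns]
        cols = {g: i for i, g in enumerate(genes)}
        out[:, [cols[g] for g in present]] = X[present].to_numpy()
        return out

    # -- estimator API

    def fit(self, X, y):
        """Train the committee on high-confidence cells.

        ``X`` is cells x genes (lognorm), ``y`` per-cell hypoxic/normoxic.
        """
        X = self._check_X(X)
        y = np.asarray(y, dtype=object)
        if set(np.unique(y)) - {HYPOXIC, NORMOXIC}:
            raise ValueError(f"labels must be {HYPOXIC!r}/{NORMOXIC!r}")
        if (y == HYPOXIC).sum() == 0 or (y == NORMOXIC).sum() == 0:
            raise ValueError("both classes must be present")
        if self.n_members % self.k_folds != 0:
            raise ValueError("n_members must be divisible by k_folds")
        self.classes_ = np.array([HYPOXIC, NORMOXIC], dtype=object)

        if self.feature_panel is not None:
            self.feature_panel_ = self.feature_panel
        else:
            m = ExpressionMatrix(
                list(X.columns), list(X.index), X.to_numpy().T, "lognorm"
            )
            self.feature_panel_ = select_deg_features(
                m, pd.Series(y, index=X.index), self.n_features
            )

        Xp = self._panel_matrix(X)
        y_bin = (y == HYPOXIC).astype(int)  # 1 = hypoxic

        skf = StratifiedKFold(
            n_splits=self.k_folds, shuffle=True, random_state=self.random_state
        )
        folds = list(skf.split(Xp, y_bin))
        ss = np.random.SeedSequence(self.random_state)
        self.member_seeds_ = (ss.generate_state(self.n_members) % (2**31)).astype(int)
        rng = np.random.default_rng(ss.spawn(1)[0])

        repeats = self.n_members // self.k_folds
        members, weights, fold_map, train_counts = [], [], [], []
        t = 0
        for _rep in range(repeats):
            for f, (train_idx, test_idx) in enumerate(folds):
                hyp = train_idx[y_bin[train_idx] == 1]
                norm = train_idx[y_bin[train_idx] == 0]
                if hyp.size == 0:
                    raise ValueError(f"fold {f} has no hypoxic training cells")
                take = rng.choice(norm, size=hyp.size, replace=hyp.size > norm.size)
                sel = np.concatenate([hyp, take])
                train_counts.append((hyp.size, take.size))
                clf = lgb.LGBMClassifier(**self._lgbm_params(self.member_seeds_[t]))
                clf.fit(Xp[sel], y_bin[sel])
                pred = (clf.booster_.predict(Xp[test_idx]) >= 0.5).astype(int)
                tp = np.sum((pred == 1) & (y_bin[test_idx] == 1))
                fn = np.sum((pred == 0) & (y_bin[test_idx] == 1))
                recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
                members.append(clf.booster_)
                weights.append(float(recall))
                fold_map.append(f)
                t += 1
        self.members_ = members
        self.weights_ = np.asarray(weights)
        self.fold_map_ = np.asarray(fold_map)
        self.member_train_counts_ = np.asarray(train_counts)  # (hypoxic, normoxic)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Voting rate v_i in [0, 1] per cell."""
        check_is_fitted(self, "members_")
        X = self._check_X(X)
        Xp = self._panel_matrix(X)
        # each booster emits P(hypoxic) under the binary objective
        indicators = np.vstack(
            [booster.predict(Xp) >= 0.5 for booster in self.members_]
        )
        return voting_rate(indicators, self.weights_)

    def predict_proba(self, X) -> np.ndarray:
        v = self.decision_function(X)
        return np.column_stack([v, 1.0 - v])  # columns follow classes_

    def predict(self, X) -> np.ndarray:
        v = self.decision_function(X)
        return np.where(v >= 0.5, HYPOXIC, NORMOXIC).astype(object)

    # -- feature stability

    def stable_features(self, fraction: float = 0.9) -> list:
        """Genes with positive split importance in strictly more than
        ``fraction`` of the committee members."""
        check_is_fitted(self, "members_")
        counts = np.zeros(len(self.feature_panel_.genes))
        for booster in self.members_:
            counts += booster.feature_importance(importance_type="split") > 0
        keep = counts > fraction * len(self.members_)
        genes = [g for g, k in zip(self.feature_panel_.genes, keep) if k]
        if not genes:
            logger.warning("no gene is used in more than %.0f%% of members",
                           100 * fraction)
        return genes

    # -- serialization

    def save(self, path) -> None:
        """Serialize as a JSON manifest plus per-member model text files."""
        check_is_fitted(self, "members_")
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "params": {k: v for k, v in self.get_params().items()
                       if k != "feature_panel"},
            "weights": self.weights_.tolist(),
            "fold_map": self.fold_map_.tolist(),
            "member_seeds": self.member_seeds_.tolist(),
            "feature_genes": self.feature_panel_.genes,
            "feature_stats": self.feature_panel_.stats.reset_index()
                .rename(columns={"index": "gene"}).to_dict(orient="list"),
        }
        (path / "model.json").write_text(json.dumps(manifest, indent=1))
        members = path / "members"
        members.mkdir(exist_ok=True)
        for i, booster in enumerate(self.members_):
            (members / f"member_{i:03d}.txt").write_text(booster.model_to_string())

    @classmethod
    def load(cls, path) -> "HypoxiaEnsembleClassifier":
        path = Path(path)
        manifest = json.loads((path / "model.json").read_text())
        est = cls(**manifest["params"])
        stats_tbl = pd.DataFrame(manifest["feature_stats"]).set_index("gene")
        est.feature_panel_ = FeaturePanel(manifest["feature_genes"], stats_tbl)
        est.classes_ = np.array([HYPOXIC, NORMOXIC], dtype=object)
        est.weights_ = np.asarray(manifest["weights"])
        est.fold_map_ = np.asarray(manifest["fold_map"])
        est.member_seeds_ = np.asarray(manifest["member_seeds"])
        est.members_ = [
            lgb.Booster(model_str=(path / "members" / f"member_{i:03d}.txt").read_text())
            for i in range(len(est.weights_))
        ]
        return est


def vote(model: HypoxiaEnsembleClassifier, m: ExpressionMatrix, cells=None) -> pd.DataFrame:
    """Apply the committee to cells of a lognorm matrix.

    Returns a cell_id-indexed table with ``voting_rate`` and ``status``
    (hypoxic iff the rate is >= 0.5).
    """
    if m.layer != "lognorm":
        raise ValueError("vote expects a lognorm matrix")
    sub = m if cells is None else m.subset_cells(list(cells))
    X = sub.to_cells_by_genes()
    v = model.decision_function(X)
    return pd.DataFrame(
        {"voting_rate": v, "status": np.where(v >= 0.5, HYPOXIC, NORMOXIC)},
        index=sub.cell_ids,
    )


# ---------------------------------------------------------------------------
# cell-type-specific signatures


def cell_type_signatures(
    m: ExpressionMatrix,
    status: pd.Series,
    meta: CellMetadata,
    genes=None,
    fdr: float = 0.05,
    lfc: float = 1.5,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-cell-type hypoxia signatures among the stable feature genes.

    Within each cell type having at least ``min_cells`` cells per status,
    tests every gene (Wilcoxon rank-sum, hypoxic vs normoxic), applies
    Benjamini-Hochberg within the cell type, and retains genes with
    FDR < ``fdr`` and log2FC > ``lfc`` (both strict).
    """
    if m.layer != "lognorm":
        raise ValueError("cell_type_signatures expects a lognorm matrix")
    sub = m if genes is None else m.subset_genes(list(genes))
    meta_tbl = meta.aligned_to(sub.cell_ids)
    status = status.reindex(sub.cell_ids)
    rows = []
    for ct in pd.unique(meta_tbl["cell_type"]):
        in_ct = (meta_tbl["cell_type"] == ct).to_numpy()
        pos = in_ct & (status == HYPOXIC).to_numpy()
        neg = in_ct & (status == NORMOXIC).to_numpy()
        if pos.sum() < min_cells or neg.sum() < min_cells:
            logger.warning(
                "cell type %s skipped: %d hypoxic / %d normoxic cells",
                ct, pos.sum(), neg.sum(),
            )
            continue
        z, p = rank_sum_test(sub.values[:, pos], sub.values[:, neg])
        q = stats.false_discovery_control(p, method="bh")
        l2 = log2_fold_change(sub.values[:, pos], sub.values[:, neg])
        keep = (q < fdr) & (l2 > lfc)
        for i in np.flatnonzero(keep):
            rows.append(
                dict(cell_type=ct, gene=sub.gene_ids[i], log2FC=l2[i],
                     p_value=p[i], FDR=q[i], direction="up")
            )
    if not rows:
        logger.warning("no cell-type-specific signature genes found")
        return pd.DataFrame(
            columns=["cell_type", "gene", "log2FC", "p_value", "FDR", "direction"]
        )
    return pd.DataFrame(rows)
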