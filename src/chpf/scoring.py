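"""Single-sample gene set enrichment (ssGSEA) activity scoring.

Each cell is scored independently against each gene set. Genes are ranked
by expression within the cell (descending, ties broken by gene identifier);
walking down the ranking, the in-set empirical distribution accumulates
rank-position weights ``(G - position)**alpha`` normalized to one, the
out-of-set distribution accumulates uniform steps, and the score is the
sum over positions of their difference. Being rank-based, scores are
invariant to any strictly monotone transform of a cell's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class ActivityScoreMatrix:
    """Gene-set x cell activity scores with the exponent used."""

    set_names: list
    cell_ids: list
    scores: np.ndarray  # sets x cells
    alpha: float

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.set_names), len(self.cell_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("activity scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.cell_ids)


def _rank_order(expr: np.ndarray, gene_ids) -> np.ndarray:
    """Indices ordering genes by descending expression, ties by gene id."""
    lex = np.empty(len(gene_ids), dtype=int)
    lex[np.argsort(np.asarray(gene_ids, dtype=object))] = np.arange(len(gene_ids))
    return np.lexsort((lex, -np.asarray(expr, dtype=float)))


def ssgsea_cell(expr, gene_ids, gene_set, alpha: float = 0.25) -> float:
    """ssGSEA score of one cell for one gene set.

    Parameters
    ----------
    expr : array of shape (G,)
        The cell's expression over ``gene_ids``.
    gene_set : list of str
        Gene symbols; intersected with ``gene_ids`` (case-insensitive).
    alpha : float
        Rank-weight exponent; 0 gives the unweighted KS-style walk.
    """
    expr = np.asarray(expr, dtype=float)
    gene_ids = [str(g) for g in gene_ids]
    G = len(gene_ids)
    upper = {g.upper(): i for i, g in enumerate(gene_ids)}
    hits = sorted({upper[g.upper()] for g in gene_set if g.upper() in upper})
    if not hits:
        raise ValueError("gene set has no gene present in the expression vector")
    if len(hits) == G:
        raise ValueError("gene set covers all genes; out-of-set ECDF undefined")
    in_set = np.zeros(G, dtype=bool)
    in_set[hits] = True
    order = _rank_order(expr, gene_ids)
    ind = in_set[order]
    weights = (G - np.arange(G)).astype(float) ** alpha
    w_in = np.where(ind, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~ind) / (G - ind.sum())
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    min_max: bool = False,
) -> ActivityScoreMatrix:
    """Score every cell of a lognorm matrix against every gene set.

    Columns are scored independently; ``min_max=True`` additionally rescales
    each set's row of scores to [0, 1] across cells (off by default — the
    downstream mixture labeling is scale-free per signature).
    """
    if m.layer != "lognorm":
        raise ValueError("ssgsea_scores expects a lognorm matrix")
    G, C = m.n_genes, m.n_cells
    upper = {}
    for i, g in enumerate(m.gene_ids):
        upper.setdefault(g.upper(), i)

    lex = np.empty(G, dtype=int)
    lex[np.argsort(np.asarray(m.gene_ids, dtype=object))] = np.arange(G)
    # per-cell gene ordering: descending expression, ties by gene id
    order = np.lexsort((np.broadcast_to(lex[:, None], (G, C)), -m.values), axis=0)
    weights = (G - np.arange(G)).astype(float) ** alpha

    scores = np.empty((len(sets), C))
    for s_idx, name in enumerate(sets.names):
        genes = sets[name]
        hits = sorted({upper[g.upper()] for g in genes if g.upper() in upper})
        n_missing = len({g.upper() for g in genes}) - len(hits)
        if n_missing:
            logger.info("set %s: %d signature genes absent from matrix", name, n_missing)
        if not hits:
            raise ValueError(f"gene set {name!r} has no gene present in the matrix")
        if len(hits) == G:
            raise ValueError(f"gene set {name!r} covers all genes")
        in_set = np.zeros(G, dtype=bool)
        in_set[hits] = True
        ind = in_set[order]  # G x C, ordered per cell
        w_in = np.where(ind, weights[:, None], 0.0)
        p_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0)[None, :]
        p_out = np.cumsum(~ind, axis=0) / float(G - len(hits))
        scores[s_idx] = np.sum(p_in - p_out, axis=0)
    if min_max:
        lo = scores.min(axis=1, keepdims=True)
        span = scores.max(axis=1, keepdims=True) - lo
        span[span == 0] = 1.0
        scores = (scores - lo) / span
    return ActivityScoreMatrix(list(sets.names), list(m.cell_ids), scores, alpha)


class SSGSEAScorer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer mapping cells x genes expression to cells x set scores.

    Parameters
    ----------
    gene_sets : GeneSetCollection
    alpha : float, default 0.25
        Canonical ssGSEA rank-weight exponent.
    min_max : bool, default False
        Rescale each signature's scores to [0, 1] across cells.
    """

    def __init__(self, gene_sets=None, alpha: float = 0.25, min_max: bool = False):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.min_max = min_max

    def fit(self, X, y=None):
        if self.gene_sets is None or len(self.gene_sets) == 0:
            raise ValueError("gene_sets must be a non-empty GeneSetCollection")
        X = self._as_frame(X)
        self.gene_ids_ = list(X.columns)
        self.set_names_ = list(self.gene_sets.names)
        return self

    def transform(self, X) -> pd.DataFrame:
        X = self._as_frame(X)
        m = ExpressionMatrix(list(X.columns), list(X.index), X.to_numpy().T, "lognorm")
        asm = ssgsea_scores(m, self.gene_sets, alpha=self.alpha, min_max=self.min_max)
        return asm.to_frame().T  # cells x sets

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        raise TypeError("SSGSEAScorer requires a cells x genes DataFrame "
                        "(gene identifiers are needed for set matching)")
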