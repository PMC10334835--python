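"""Gaussian-mixture high/low assignment and the multi-signature consensus.

For each hypoxia signature, a two-component 1-D Gaussian mixture splits the
per-cell activity scores into a high- and a low-score group (the component
with the larger mean is "high"). A cell is a high-confidence hypoxic cell
iff it falls in the high group for *every* signature, high-confidence
normoxic iff in the low group for every signature, and unclassified
otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

HYPOXIC = "hypoxic"
NORMOXIC = "normoxic"
UNCLASSIFIED = "unclassified"


@dataclass
class GmmAssignment:
    """Fitted two-component mixture and per-cell high/low calls for one signature."""

    set_name: str
    means: np.ndarray            # (2,) ordered [low, high]
    variances: np.ndarray        # (2,)
    mixing_weights: np.ndarray   # (2,) sums to 1
    cell_ids: list
    cell_group: np.ndarray       # per-cell "high"/"low"
    posterior_high: np.ndarray   # per-cell P(high component)
    converged: bool = True

    def __post_init__(self):
        if abs(float(self.mixing_weights.sum()) - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")
        if not self.means[1] >= self.means[0]:
            raise ValueError("high component must have the larger mean")
        if np.any(self.posterior_high < 0) or np.any(self.posterior_high > 1):
            raise ValueError("posterior_high must lie in [0, 1]")


def fit_gmm_1d(scores, cell_ids=None, seed: int = 0, set_name: str = "") -> GmmAssignment:
    """EM fit of a 2-component 1-D Gaussian mixture to per-cell scores.

    k-means initialization from ``seed``, tolerance 1e-6 on mean
    log-likelihood, at most 500 iterations. A cell is "high" iff its
    posterior for the larger-mean component is >= 0.5 (ties go high).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 4:
        raise ValueError("need a 1-D vector of >= 4 scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if np.ptp(scores) == 0:
        raise ValueError("all scores identical; mixture fit is degenerate")
    if cell_ids is None:
        cell_ids = [str(i) for i in range(scores.size)]

    gm = GaussianMixture(
        n_components=2, covariance_type="full", tol=1e-6, max_iter=500,
        n_init=1, init_params="kmeans", random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(scores.reshape(-1, 1))
    if not gm.converged_:
        logger.warning("GMM for %s did not converge within 500 iterations; "
                       "using best iterate", set_name or "<unnamed>")
    means = gm.means_.ravel()
    order = np.argsort(means)  # [low, high]
    post = gm.predict_proba(scores.reshape(-1, 1))[:, order[1]]
    group = np.where(post >= 0.5, "high", "low")
    return GmmAssignment(
        set_name=set_name,
        means=means[order],
        variances=gm.covariances_.reshape(2)[order],
        mixing_weights=gm.weights_[order],
        cell_ids=list(cell_ids),
        cell_group=group,
        posterior_high=post,
        converged=bool(gm.converged_),
    )


def consensus_labels(assignments) -> pd.Series:
    """Strict-conjunction consensus over per-signature high/low assignments.

    hypoxic iff "high" in every assignment; normoxic iff "low" in every
    assignment; otherwise unclassified. Returns a cell_id-indexed Series.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("need at least one assignment")
    ref = assignments[0].cell_ids
    for a in assignments[1:]:
        if set(a.cell_ids) != set(ref):
            diff = set(a.cell_ids) ^ set(ref)
            raise ValueError(f"assignments cover different cells: {sorted(diff)[:5]}")
    high = np.ones(len(ref), dtype=bool)
    low = np.ones(len(ref), dtype=bool)
    for a in assignments:
        g = pd.Series(a.cell_group, index=a.cell_ids).loc[ref].to_numpy()
        high &= g == "high"
        low &= g == "low"
    labels = np.full(len(ref), UNCLASSIFIED, dtype=object)
    labels[high] = HYPOXIC
    labels[low] = NORMOXIC
    return pd.Series(labels, index=ref, name="status")


class GMMConsensusLabeler(BaseEstimator):
    """Estimator producing high-confidence hypoxic/normoxic/unclassified labels.

    fit(X) takes a cells x signatures score DataFrame, fits one 1-D
    two-component Gaussian mixture per signature and stores the consensus.

    Attributes
    ----------
    assignments_ : list of GmmAssignment
    labels_ : pandas.Series, cell_id -> status
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a cells x signatures score DataFrame")
        self.assignments_ = [
            fit_gmm_1d(X[col].to_numpy(), cell_ids=list(X.index),
                       seed=self.random_state, set_name=str(col))
            for col in X.columns
        ]
        self.labels_ = consensus_labels(self.assignments_)
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        return self.fit(X).labels_
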