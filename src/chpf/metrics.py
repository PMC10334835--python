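"""Self-contained downstream scores.

Per-cell hypoxia score (mean z-scored signature expression), CNA score
(quadratic sum of copy-number region values), prognostic risk score
(coefficient-weighted expression) with median split, the connectivity-map
weighted connectivity score (WTCS), and the Spearman drug-TF association
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix

logger = logging.getLogger(__name__)


def hypoxia_score(m: ExpressionMatrix, genes) -> pd.Series:
    """Per-cell mean of z-scored lognorm expression over signature genes.

    Genes constant across cells contribute zero (degenerate z-score).
    """
    if m.layer != "lognorm":
        raise ValueError("hypoxia_score expects a lognorm matrix")
    present = [g for g in genes if g in set(m.gene_ids)]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if len(present) < len(list(genes)):
        logger.info("%d signature genes absent from matrix",
                    len(list(genes)) - len(present))
    sub = m.subset_genes(present)
    mu = sub.values.mean(axis=1, keepdims=True)
    sd = sub.values.std(axis=1, keepdims=True)
    z = np.divide(sub.values - mu, sd, out=np.zeros_like(sub.values), where=sd > 0)
    return pd.Series(z.mean(axis=0), index=m.cell_ids, name="hypoxia_score")


def cna_score(cnv: pd.DataFrame) -> pd.Series:
    """Per-cell quadratic sum of copy-number region values.

    ``cnv`` is regions x cells; score(cell) = sum over regions of value^2.
    """
    if cnv.shape[0] == 0:
        raise ValueError("empty region set")
    vals = cnv.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("CNV values must be finite")
    return pd.Series((vals**2).sum(axis=0), index=cnv.columns, name="cna_score")


@dataclass
class RiskModel:
    """Gene coefficients from external survival regression."""

    genes: list
    coefficients: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("model genes must be unique")
        if self.coefficients.shape != (len(self.genes),):
            raise ValueError("one coefficient per gene required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


def risk_score(expr: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Per-patient coefficient-weighted expression sum.

    ``expr`` is genes x patients; every model gene must be present.
    """
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise KeyError(f"model genes missing from expression table: {missing}")
    sub = expr.loc[model.genes].to_numpy(dtype=float)
    return pd.Series(model.coefficients @ sub, index=expr.columns, name="risk_score")


def median_split(scores: pd.Series) -> pd.Series:
    """high_risk iff score > median; scores equal to the median go low_risk."""
    if len(scores) < 2:
        raise ValueError("need at least 2 patients")
    med = float(np.median(scores.to_numpy(dtype=float)))
    groups = np.where(scores.to_numpy(dtype=float) > med, "high_risk", "low_risk")
    if (groups == "low_risk").all():
        logger.warning("all scores at or below the median; no high-risk patients")
    return pd.Series(groups, index=scores.index, name="risk_group")


@dataclass
class RankedSignature:
    """Genes ordered by a differential statistic, most up-regulated first."""

    genes: list
    statistic: np.ndarray

    def __post_init__(self):
        self.statistic = np.asarray(self.statistic, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked genes must be unique")
        if self.statistic.shape != (len(self.genes),):
            raise ValueError("one statistic per gene required")
        if np.any(np.diff(self.statistic) > 0):
            raise ValueError("statistic must be non-increasing down the ranking")


def enrichment_score(ranking: RankedSignature, gene_set) -> float:
    """Signed maximum-deviation weighted-KS enrichment of a set in a ranking.

    In-set steps are weighted by \\|statistic\\| (normalized); out-of-set
    steps are uniform. The score is the running-sum value of largest
    absolute deviation.
    """
    genes = list(ranking.genes)
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set has no member in the ranking")
    if len(members) == len(genes):
        raise ValueError("gene set covers the whole ranking")
    ind = np.array([g in members for g in genes])
    w = np.abs(ranking.statistic)
    if w[ind].sum() == 0:
        # all member statistics are zero: fall back to uniform in-set steps
        w = np.ones_like(w)
    p_in = np.cumsum(np.where(ind, w, 0.0)) / w[ind].sum()
    p_out = np.cumsum(~ind) / (len(genes) - len(members))
    dev = p_in - p_out
    return float(dev[np.argmax(np.abs(dev))])


def wtcs(ranking: RankedSignature, up_set, down_set) -> float:
    """Weighted connectivity score of an up/down query against a ranked signature.

    WTCS = (ES_up - ES_down) / 2 when the two enrichment scores have
    opposite signs, else 0; always within [-1, 1].
    """
    up = set(up_set)
    down = set(down_set)
    if up & down:
        raise ValueError(f"up and down sets overlap: {sorted(up & down)[:5]}")
    es_up = enrichment_score(ranking, up)
    es_down = enrichment_score(ranking, down)
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return float((es_up - es_down) / 2.0)


def drug_tf_associations(
    tf_expr: pd.DataFrame,
    drug_auc: pd.DataFrame,
    cor_min: float = 0.3,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Spearman screen of TF expression against drug-sensitivity AUC.

    ``tf_expr`` is TFs x cell lines, ``drug_auc`` drugs x cell lines;
    each pair is tested over its shared cell lines (>= 3 required,
    constant vectors skipped), Benjamini-Hochberg is applied over all
    tested pairs, and pairs with \\|rho\\| > ``cor_min`` (strict) and
    FDR < ``fdr_max`` are retained. Direction follows the AUC
    convention: rho < 0 means higher TF expression tracks lower AUC,
    i.e. drug sensitivity; rho > 0 means resistance.
    """
    shared = [c for c in tf_expr.columns if c in set(drug_auc.columns)]
    rows = []
    for tf in tf_expr.index:
        x_full = tf_expr.loc[tf, shared]
        for drug in drug_auc.index:
            y_full = drug_auc.loc[drug, shared]
            ok = x_full.notna() & y_full.notna()
            if ok.sum() < 3:
                continue
            x, y = x_full[ok].to_numpy(float), y_full[ok].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("constant vector for pair (%s, %s); skipped", tf, drug)
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append(dict(TF=tf, drug=drug, rho=float(rho), p_value=float(p)))
    if not rows:
        return pd.DataFrame(columns=["TF", "drug", "rho", "p_value", "FDR", "direction"])
    tbl = pd.DataFrame(rows)
    tbl["FDR"] = stats.false_discovery_control(tbl["p_value"].to_numpy(), method="bh")
    tbl["direction"] = np.where(tbl["rho"] < 0, "sensitivity", "resistance")
    keep = (tbl["rho"].abs() > cor_min) & (tbl["FDR"] < fdr_max)
    return tbl[keep].reset_index(drop=True)
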