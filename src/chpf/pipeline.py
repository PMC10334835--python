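"""End-to-end pipeline: filter -> normalize -> score -> consensus ->
features -> ensemble -> vote -> stable features -> cell-type signatures.

Every stage output carries the run's config hash in a ``#`` header line so
outputs from different configurations cannot be silently mixed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (HypoxiaEnsembleClassifier, cell_type_signatures,
                         select_deg_features, vote)
from .consensus import UNCLASSIFIED, GMMConsensusLabeler
from .data import filter_genes, normalize_expression
from .io import read_expression, read_gene_sets, read_metadata
from .scoring import ssgsea_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run; hashed into every output."""

    matrix: str
    gmt: str
    outdir: str
    meta: str | None = None
    matrix_format: str | None = None
    min_cell_fraction: float = 0.001
    scale_factor: float = 1e4
    alpha: float = 0.25
    n_features: int = 500
    n_members: int = 100
    k_folds: int = 5
    stable_fraction: float = 0.9
    sig_fdr: float = 0.05
    sig_lfc: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.min_cell_fraction <= 1:
            raise ValueError("min_cell_fraction must be in [0, 1]")
        for name in ("sig_fdr", "stable_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    def config_hash(self) -> str:
        fields = asdict(self)
        fields.pop("outdir")  # where outputs land does not change what they are
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_stage(df: pd.DataFrame, path: Path, config_hash: str,
                 index_label: str = "cell_id") -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def check_config_hash(path, expected: str) -> None:
    """Refuse to consume a stage output written under a different config."""
    with open(path) as fh:
        first = fh.readline().strip()
    found = first.removeprefix("# config_hash=") if first.startswith("# config_hash=") else None
    if found != expected:
        raise ValueError(
            f"{path} was produced under config hash {found!r}, expected {expected!r}"
        )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full framework and write per-stage TSVs plus a manifest.

    Returns the output directory. Final per-cell status keeps the
    consensus label for high-confidence cells and the committee's call for
    the rest; the voting rate is reported for every cell.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()

    counts = read_expression(cfg.matrix, format=cfg.matrix_format)
    counts = filter_genes(counts, cfg.min_cell_fraction)
    lognorm = normalize_expression(counts, cfg.scale_factor)
    gene_sets = read_gene_sets(cfg.gmt)

    scores = ssgsea_scores(lognorm, gene_sets, alpha=cfg.alpha)
    _write_stage(scores.to_frame().T, outdir / "scores.tsv", h)

    labeler = GMMConsensusLabeler(random_state=cfg.seed)
    hc = labeler.fit_predict(scores.to_frame().T)
    _write_stage(hc.to_frame(), outdir / "hc_labels.tsv", h)

    panel = select_deg_features(lognorm, hc, cfg.n_features)
    _write_stage(panel.stats, outdir / "features.tsv", h, index_label="gene")

    hc_cells = hc.index[hc != UNCLASSIFIED]
    X_hc = lognorm.subset_cells(list(hc_cells)).to_cells_by_genes()
    model = HypoxiaEnsembleClassifier(
        n_members=cfg.n_members, k_folds=cfg.k_folds,
        feature_panel=panel, random_state=cfg.seed,
    ).fit(X_hc, hc.loc[hc_cells])
    model.save(outdir / "model")
    _write_stage(
        pd.DataFrame({"weight": model.weights_, "fold": model.fold_map_}),
        outdir / "weights.tsv", h, index_label="member",
    )

    voted = vote(model, lognorm)
    final = hc.copy()
    unclassified = hc.index[hc == UNCLASSIFIED]
    final.loc[unclassified] = voted.loc[unclassified, "status"]
    predictions = pd.DataFrame(
        {
            "voting_rate": voted["voting_rate"],
            "consensus": hc,
            "status": final,
        }
    )
    _write_stage(predictions, outdir / "predictions.tsv", h)

    stable = model.stable_features(cfg.stable_fraction)
    _write_stage(pd.DataFrame({"gene": stable}), outdir / "stable_features.tsv", h,
                 index_label="rank")

    if cfg.meta:
        meta = read_metadata(cfg.meta)
        sig = cell_type_signatures(
            lognorm, final, meta, genes=stable or None,
            fdr=cfg.sig_fdr, lfc=cfg.sig_lfc,
        )
    else:
        sig = pd.DataFrame(
            columns=["cell_type", "gene", "log2FC", "p_value", "FDR", "direction"])
    _write_stage(sig, outdir / "celltype_signatures.tsv", h, index_label="row")

    hashed_fields = asdict(cfg)
    hashed_fields.pop("outdir")
    manifest = {
        "chpf_version": __version__,
        "config": hashed_fields,
        "config_hash": h,
        "n_genes_after_filter": counts.n_genes,
        "n_cells": counts.n_cells,
        "n_high_confidence_hypoxic": int((hc == "hypoxic").sum()),
        "n_high_confidence_normoxic": int((hc == "normoxic").sum()),
        "n_unclassified": int((hc == UNCLASSIFIED).sum()),
        "n_stable_features": len(stable),
        "member_weights_mean": float(np.mean(model.weights_)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", outdir)
    return outdir
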