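"""Core in-memory containers and expression preprocessing.

The framework operates on a genes x cells expression matrix carrying an
explicit layer flag (``raw_counts`` or ``lognorm``) so every downstream
stage can assert the normalization state it requires, plus named gene-set
collections and per-cell metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
LOGNORM = "lognorm"


@dataclass
class ExpressionMatrix:
    """A genes x cells numeric expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers (rows).
    cell_ids : list of str
        Unique cell identifiers (columns).
    values : ndarray of shape (n_genes, n_cells)
        Non-negative counts (``raw_counts``) or finite log-normalized
        values (``lognorm``).
    layer : {"raw_counts", "lognorm"}
    """

    gene_ids: list
    cell_ids: list
    values: np.ndarray
    layer: str = RAW_COUNTS

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if self.layer not in (RAW_COUNTS, LOGNORM):
            raise ValueError(f"unknown layer {self.layer!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.layer == RAW_COUNTS and np.any(self.values < 0):
            raise ValueError("raw counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        """Genes x cells DataFrame view."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def to_cells_by_genes(self) -> pd.DataFrame:
        """Cells x genes DataFrame (the sklearn samples-by-features view)."""
        return self.to_frame().T

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.cell_ids),
                                self.values[rows, :], self.layer)

    def subset_cells(self, cells) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in cells]
        return ExpressionMatrix(list(self.gene_ids), list(cells),
                                self.values[:, cols], self.layer)


@dataclass
class GeneSetCollection:
    """Named gene lists (e.g. hypoxia signatures parsed from GMT)."""

    sets: dict = field(default_factory=dict)  # name -> ordered list of genes
    provenance: dict = field(default_factory=dict)  # name -> free text

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    @property
    def names(self) -> list:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name) -> list:
        return self.sets[name]


@dataclass
class CellMetadata:
    """Per-cell annotations joined onto an ExpressionMatrix by cell_id."""

    table: pd.DataFrame  # index = cell_id; columns include cell_type, optional region/patient

    def __post_init__(self):
        if "cell_type" not in self.table.columns:
            raise ValueError("metadata requires a cell_type column")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate cell_id in metadata")
        self.table.index = self.table.index.astype(str)

    def aligned_to(self, cell_ids) -> pd.DataFrame:
        missing = [c for c in cell_ids if c not in self.table.index]
        if missing:
            raise KeyError(f"cells missing from metadata: {missing[:5]}"
                           + ("..." if len(missing) > 5 else ""))
        return self.table.loc[list(cell_ids)]


def filter_genes(m: ExpressionMatrix, min_cell_fraction: float = 0.001) -> ExpressionMatrix:
    """Remove genes expressed (count > 0) in fewer than ``min_cell_fraction`` of cells.

    A gene is retained iff its expressing-cell fraction is >= the threshold,
    i.e. only strictly sub-threshold genes are dropped. Gene order is
    preserved and the cell set is unchanged.
    """
    if m.layer != RAW_COUNTS:
        raise ValueError("filter_genes expects a raw_counts matrix")
    if not 0.0 <= min_cell_fraction <= 1.0:
        raise ValueError("min_cell_fraction must be in [0, 1]")
    frac = (m.values > 0).sum(axis=1) / m.n_cells
    keep = frac >= min_cell_fraction
    if not keep.any():
        raise ValueError(
            "all genes would be removed; review the min_cell_fraction threshold"
        )
    kept_genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return ExpressionMatrix(kept_genes, list(m.cell_ids), m.values[keep, :], RAW_COUNTS)


def normalize_expression(m: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization to ``scale_factor`` counts per cell, then log1p.

    ``x -> log(1 + scale_factor * x / total(cell))``, the standard
    scRNA-seq log-normalization. Cells with zero total counts are
    rejected (no defined library size).
    """
    if m.layer != RAW_COUNTS:
        raise ValueError("normalize_expression expects a raw_counts matrix")
    totals = m.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [c for c, z in zip(m.cell_ids, zero) if z]
        raise ValueError(f"cells with zero total counts: {bad}")
    out = np.log1p(m.values / totals[None, :] * scale_factor)
    return ExpressionMatrix(list(m.gene_ids), list(m.cell_ids), out, LOGNORM)
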