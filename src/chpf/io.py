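"""Readers and writers for the standard formats the framework touches.

Supported inputs: 10x-style MTX triplet directories (MatrixMarket matrix +
features + barcodes), dense CSV/TSV count tables (gene rows x cell columns),
GMT gene-set files, and TSV label / metadata / edge-list tables.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import CellMetadata, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


def _dedupe(names):
    """Disambiguate duplicates deterministically: second 'ACTB' becomes 'ACTB.1'."""
    seen = {}
    out = []
    for n in names:
        if n not in seen:
            seen[n] = 0
            out.append(n)
        else:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
    return out


def read_expression(path, format: str | None = None) -> ExpressionMatrix:
    """Read a raw-counts expression matrix.

    Parameters
    ----------
    path : str or Path
        MTX triplet directory, or a dense CSV/TSV file with gene rows and
        cell columns (first column = gene ids, header = cell ids).
    format : {"mtx_dir", "csv", "tsv"}, optional
        Inferred from the path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix.lower() == ".csv":
            format = "csv"
        else:
            format = "tsv"
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
            values = df.to_numpy(dtype=float)
        except ValueError as e:
            raise ValueError(f"non-numeric value while parsing {path}: {e}") from e
        genes = _dedupe([str(g) for g in df.index])
        cells = _dedupe([str(c) for c in df.columns])
        return ExpressionMatrix(genes, cells, values, "raw_counts")
    raise ValueError(f"unknown format {format!r}")


def _find_one(dirpath: Path, stems):
    for stem in stems:
        for cand in (dirpath / stem, dirpath / (stem + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {stems} found in {dirpath}")


def _read_mtx_dir(dirpath: Path) -> ExpressionMatrix:
    mtx = _find_one(dirpath, ["matrix.mtx"])
    feat = _find_one(dirpath, ["features.tsv", "genes.tsv"])
    barc = _find_one(dirpath, ["barcodes.tsv"])
    mat = scipy.io.mmread(os.fspath(mtx))
    mat = scipy.sparse.coo_matrix(mat).toarray().astype(float)
    features = pd.read_csv(feat, sep="\t", header=None)
    # 10x features files carry id / symbol / type columns; use symbol when present
    sym_col = 1 if features.shape[1] > 1 else 0
    genes = _dedupe([str(g) for g in features.iloc[:, sym_col]])
    cells = _dedupe([str(b) for b in pd.read_csv(barc, sep="\t", header=None).iloc[:, 0]])
    if mat.shape[0] != len(genes) or mat.shape[1] != len(cells):
        raise ValueError(
            f"MTX triplet dimension mismatch in {dirpath}: matrix is "
            f"{mat.shape[0]} x {mat.shape[1]} but features={len(genes)}, "
            f"barcodes={len(cells)}"
        )
    return ExpressionMatrix(genes, cells, mat, "raw_counts")


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description, genes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sets, prov = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
            prov[name] = desc
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, prov)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_labels(labels: pd.DataFrame, path) -> None:
    """Write a cell_id-indexed label/score table as TSV, preserving input order."""
    if labels.empty:
        logger.warning("writing empty label table to %s", path)
    labels.to_csv(path, sep="\t", index=True, index_label="cell_id")


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_id", comment="#")


def read_metadata(path) -> CellMetadata:
    df = pd.read_csv(path, sep="\t", index_col="cell_id", dtype=str)
    return CellMetadata(df)


def write_metadata(meta: CellMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="cell_id")


def read_edge_list(path) -> pd.DataFrame:
    """Read a directed TF->target edge list (TSV: tf, target[, weight])."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "tf" not in cols or "target" not in cols:
        raise ValueError(f"edge list {path} must have 'tf' and 'target' columns")
    return df
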