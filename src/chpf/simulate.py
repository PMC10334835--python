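"""Deterministic synthetic-data generators.

These produce every input the framework consumes — a negative-binomial
counts matrix with a planted hypoxia gene program expressed in a
designated fraction of cells, overlapping hypoxia gene sets, per-cell
metadata with a core/periphery region structure, directed regulatory
networks with planted hub TFs, and ranked signatures with planted up/down
blocks — so the full pipeline and every oracle run without any download.
All randomness derives from the config seed; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CellMetadata, ExpressionMatrix, GeneSetCollection
from .metrics import RankedSignature
from .network import GeneNetwork


@dataclass
class SyntheticDataset:
    """Generated inputs plus the planted ground truth.

    Unpacks as ``matrix, metadata, true_status, signatures`` for pipeline
    use; ``program_genes`` records which genes carry the planted hypoxia
    program.
    """

    matrix: ExpressionMatrix
    metadata: CellMetadata
    true_status: pd.Series
    signatures: GeneSetCollection
    program_genes: list

    def __iter__(self):
        return iter((self.matrix, self.metadata, self.true_status, self.signatures))


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic counts matrix.

    Defaults plant a 200-gene hypoxia program at log2 fold change 2 in 30%
    of 2,000 cells across four cell types, with seven 50-gene signatures
    drawing 80% of their genes from the program.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    n_celltypes: int = 4
    hypoxic_fraction: float = 0.3
    n_program_genes: int = 200
    program_log2fc: float = 2.0
    nb_dispersion: float = 0.3
    library_size_mean: float = 5000.0
    n_signatures: int = 7
    signature_size: int = 50
    signature_program_overlap: float = 0.8
    n_markers_per_celltype: int = 20
    celltype_marker_fold: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hypoxic_fraction <= 1.0:
            raise ValueError("hypoxic_fraction must be in [0, 1]")
        if not 0.0 <= self.signature_program_overlap <= 1.0:
            raise ValueError("signature_program_overlap must be in [0, 1]")
        for name in ("n_cells", "n_genes", "n_celltypes", "n_program_genes",
                     "n_signatures", "signature_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("nb_dispersion and library_size_mean must be positive")
        if self.n_program_genes > self.n_genes:
            raise ValueError("n_program_genes cannot exceed n_genes")


def generate_dataset(cfg: GeneratorConfig):
    """Synthesize (counts, metadata, true per-cell status, gene sets).

    Counts follow a gamma-Poisson (negative binomial) model: per-gene
    baseline abundances, log-normal per-cell library sizes, and dispersion
    ``nb_dispersion`` (variance = mu + dispersion * mu^2). Hypoxic cells
    (``round(hypoxic_fraction * n_cells)`` of them, all placed in the
    "core" region) express the program genes at ``2**program_log2fc``
    times their baseline mean; each cell type additionally has a small
    marker-gene block so the cell-type signature stage has structure to
    find.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    cells = [f"C{i:05d}" for i in range(cfg.n_cells)]

    base = rng.gamma(shape=2.0, scale=1.0, size=cfg.n_genes)
    base /= base.sum()

    program = np.sort(rng.choice(cfg.n_genes, size=cfg.n_program_genes, replace=False))
    non_program = np.setdiff1d(np.arange(cfg.n_genes), program)

    n_hyp = int(round(cfg.hypoxic_fraction * cfg.n_cells))
    hypoxic = np.zeros(cfg.n_cells, dtype=bool)
    hypoxic[rng.choice(cfg.n_cells, size=n_hyp, replace=False)] = True

    celltype = rng.integers(0, cfg.n_celltypes, size=cfg.n_cells)
    marker_sets = []
    pool = rng.permutation(non_program)
    for ct in range(cfg.n_celltypes):
        take = pool[ct * cfg.n_markers_per_celltype:(ct + 1) * cfg.n_markers_per_celltype]
        marker_sets.append(take)

    fold = np.ones((cfg.n_genes, cfg.n_cells))
    fold[np.ix_(program, np.flatnonzero(hypoxic))] = 2.0**cfg.program_log2fc
    for ct, markers in enumerate(marker_sets):
        if markers.size:
            fold[np.ix_(markers, np.flatnonzero(celltype == ct))] *= cfg.celltype_marker_fold

    sigma = 0.3
    lib = rng.lognormal(
        mean=np.log(cfg.library_size_mean) - sigma**2 / 2, sigma=sigma, size=cfg.n_cells
    )
    mu = base[:, None] * fold * lib[None, :]
    shape = 1.0 / cfg.nb_dispersion
    counts = rng.poisson(rng.gamma(shape, mu / shape)).astype(float)

    matrix = ExpressionMatrix(genes, cells, counts, "raw_counts")

    region = np.where(hypoxic, "core",
                      np.where(rng.random(cfg.n_cells) < 0.5, "core", "periphery"))
    meta = CellMetadata(pd.DataFrame(
        {
            "cell_type": [f"celltype_{t}" for t in celltype],
            "region": region,
            "patient": [f"patient_{p}" for p in rng.integers(0, 4, size=cfg.n_cells)],
        },
        index=pd.Index(cells, name="cell_id"),
    ))
    status = pd.Series(np.where(hypoxic, "hypoxic", "normoxic"), index=cells,
                       name="true_status")

    n_from_program = int(round(cfg.signature_program_overlap * cfg.signature_size))
    n_from_program = min(n_from_program, cfg.n_program_genes)
    n_rest = cfg.signature_size - n_from_program
    sets, prov = {}, {}
    for s in range(cfg.n_signatures):
        picked = list(rng.choice(program, size=n_from_program, replace=False))
        if n_rest:
            picked += list(rng.choice(non_program, size=min(n_rest, non_program.size),
                                      replace=False))
        sets[f"HYPOXIA_SIG_{s}"] = [genes[i] for i in picked]
        prov[f"HYPOXIA_SIG_{s}"] = "synthetic hypoxia signature"
    signatures = GeneSetCollection(sets, prov)
    return SyntheticDataset(matrix, meta, status, signatures,
                            [genes[i] for i in program])


def generate_network(
    n_nodes: int, n_hubs: int, edges_per_node: int = 3, seed: int = 0
):
    """Directed regulatory network with planted hub TFs.

    Every node draws ``edges_per_node`` parents from a TF pool in which
    the ``n_hubs`` designated hubs carry 20x selection weight, giving the
    hubs inflated out-degree (and mutual in-edges), so they dominate the
    centrality ranking. Returns ``(network, hub_ids)``.
    """
    if n_hubs >= n_nodes:
        raise ValueError("n_hubs must be smaller than n_nodes")
    rng = np.random.default_rng(seed)
    names = [f"N{i:05d}" for i in range(n_nodes)]
    hubs = list(range(n_hubs))
    n_other_tfs = max(1, int(0.1 * (n_nodes - n_hubs)))
    other_tfs = list(range(n_hubs, n_hubs + n_other_tfs))
    tf_pool = np.array(hubs + other_tfs)
    weights = np.where(tf_pool < n_hubs, 20.0, 1.0)

    edges = set()
    for node in range(n_nodes):
        ok = tf_pool != node
        p = weights[ok] / weights[ok].sum()
        parents = rng.choice(tf_pool[ok], size=min(edges_per_node, ok.sum()),
                             replace=False, p=p)
        for par in parents:
            edges.add((int(par), node))
    df = pd.DataFrame(sorted(edges), columns=["tf", "target"])
    df["tf"] = [names[i] for i in df["tf"]]
    df["target"] = [names[i] for i in df["target"]]
    net = GeneNetwork(df, tf_nodes={names[i] for i in tf_pool}, isolates=[])
    return net, [names[i] for i in hubs]


def generate_ranked_signature(
    n_genes: int, up_block: int, down_block: int, seed: int = 0
):
    """Ranked signature with planted up/down blocks at the extremes.

    Returns ``(ranking, up_set, down_set)`` where the up set occupies the
    top of the ranking and the down set the bottom — the extremal
    configuration for connectivity scoring.
    """
    if up_block + down_block > n_genes:
        raise ValueError("up and down blocks overlap")
    rng = np.random.default_rng(seed)
    genes = [f"R{i:05d}" for i in range(n_genes)]
    stat = np.sort(rng.normal(size=n_genes))[::-1]
    ranking = RankedSignature(genes, stat)
    return ranking, genes[:up_block], genes[n_genes - down_block:]
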