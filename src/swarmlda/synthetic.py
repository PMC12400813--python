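"""Synthetic scRNA-seq-like count data with known cell-type structure.

The generator emulates the regime the annotator is built for: sparse
nonnegative integer counts over many genes, a handful of imbalanced cell
types, each marked by a block of genes whose mean is shifted up by a known
log fold change, with extra zeros from dropout.  Counts are negative
binomial (mean/dispersion parameterization) with independent Bernoulli
dropout.  A second, Gaussian generator produces data that satisfy LDA's
shared-covariance assumptions exactly, for oracle-equivalence tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import mmwrite
from scipy.sparse import csc_matrix

from .preprocess import CellTypeLabels, ExpressionMatrix

__all__ = ["SimConfig", "simulate_counts", "simulate_gaussian", "write_10x_dir"]


@dataclass
class SimConfig:
    """Parameters of the count simulator.

    Defaults describe a well-separated 4-type population of 800 cells x 1000
    genes: 30 markers per type at a natural-log fold change of 2, baseline
    negative-binomial mean 1.0 with dispersion (size) 2.0, 20% dropout, and
    imbalanced type proportions.
    """

    n_cells: int = 800
    n_genes: int = 1000
    n_types: int = 4
    class_props: tuple = (0.4, 0.3, 0.2, 0.1)
    n_marker_genes_per_class: int = 30
    log_fold_change: float = 2.0
    base_mean: float = 1.0
    dispersion: float = 2.0
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_props, dtype=np.float64)
        if props.shape != (self.n_types,) or np.any(props <= 0):
            raise ValueError("class_props must be positive and length n_types")
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("class_props must sum to 1")
        if self.n_marker_genes_per_class * self.n_types > self.n_genes:
            raise ValueError("too many marker genes for n_genes")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.log_fold_change, 0.0) < 0 or self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("log_fold_change >= 0, base_mean > 0, dispersion > 0 required")


def _class_sizes(props: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n cells across classes."""
    quota = props * n
    sizes = np.floor(quota).astype(int)
    rem = quota - sizes
    for k in np.argsort(-rem)[: n - sizes.sum()]:
        sizes[k] += 1
    return sizes


def simulate_counts(cfg: SimConfig):
    """Draw a labeled count matrix; returns (matrix, labels, marker_map).

    Gene g is a marker of type k iff it lies in the k-th consecutive block of
    ``n_marker_genes_per_class`` genes; markers have NB mean
    ``base_mean * exp(log_fold_change)`` in their own type and ``base_mean``
    elsewhere.  ``marker_map`` maps each type name to its true marker genes.
    Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    props = np.asarray(cfg.class_props, dtype=np.float64)
    sizes = _class_sizes(props, cfg.n_cells)
    codes = rng.permutation(np.repeat(np.arange(cfg.n_types), sizes))

    nm = cfg.n_marker_genes_per_class
    mu = np.full((cfg.n_types, cfg.n_genes), cfg.base_mean)
    for k in range(cfg.n_types):
        mu[k, k * nm : (k + 1) * nm] *= np.exp(cfg.log_fold_change)

    theta = cfg.dispersion
    cell_mu = mu[codes]  # n_cells x n_genes
    counts = rng.negative_binomial(theta, theta / (theta + cell_mu)).astype(np.float64)
    if cfg.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= cfg.dropout_rate

    gene_names = [f"gene_{j:05d}" for j in range(cfg.n_genes)]
    cell_ids = [f"cell_{i:05d}" for i in range(cfg.n_cells)]
    type_names = [f"type_{k}" for k in range(cfg.n_types)]
    matrix = ExpressionMatrix(counts, gene_names, cell_ids, layer_tag="raw")
    labels = CellTypeLabels(
        np.array([type_names[c] for c in codes], dtype=object), type_names
    )
    marker_map = {
        type_names[k]: gene_names[k * nm : (k + 1) * nm] for k in range(cfg.n_types)
    }
    return matrix, labels, marker_map


def simulate_gaussian(
    n: int,
    p: int,
    n_types: int,
    shift: float = 4.0,
    noise_sd: float = 1.0,
    props=None,
    seed: int = 0,
):
    """Shared-covariance Gaussian classes for LDA oracle tests.

    Class k's mean is ``shift`` on its own coordinate block (p // n_types
    features) and 0 elsewhere; noise is isotropic with sd ``noise_sd``.
    Returns (X, codes, means) with X an n x p float array.
    """
    rng = np.random.default_rng(seed)
    props = (
        np.full(n_types, 1.0 / n_types) if props is None else np.asarray(props, float)
    )
    sizes = _class_sizes(props / props.sum(), n)
    codes = rng.permutation(np.repeat(np.arange(n_types), sizes))
    block = max(p // n_types, 1)
    means = np.zeros((n_types, p))
    for k in range(n_types):
        means[k, k * block : min((k + 1) * block, p)] = shift
    X = means[codes] + rng.normal(0.0, noise_sd, size=(n, p))
    return X, codes, means


def write_10x_dir(
    m: ExpressionMatrix, labels: CellTypeLabels | None, out_dir: str | os.PathLike
) -> None:
    """Write a 10x-style MTX directory (genes x cells on disk) plus labels.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", csc_matrix(m.values.T))
    with open(out / "features.tsv", "w") as fh:
        for g in m.gene_names:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(out / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(m.cell_ids) + "\n")
    if labels is not None:
        with open(out / "labels.tsv", "w") as fh:
            fh.write("cell_id\tcell_type\n")
            for cid, lab in zip(m.cell_ids, labels.labels):
                fh.write(f"{cid}\t{lab}\n")
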