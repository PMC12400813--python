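"""Reading expression data and the standard preprocessing pipeline.

The pipeline mirrors what most supervised annotation tools do before model
fitting: quality-control filtering of cells and genes, removal of
zero-variance genes, per-cell log-normalization (counts-per-10k, log1p), and
one-vs-rest Wilcoxon rank-sum screening that keeps the top ``top_n`` genes
per cell type as candidate markers.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread
from scipy.stats import mannwhitneyu

__all__ = [
    "ExpressionMatrix",
    "CellTypeLabels",
    "GeneScreenResult",
    "read_matrix",
    "read_labels",
    "write_matrix_csv",
    "qc_filter",
    "log_normalize",
    "wilcoxon_rank_sum",
    "screen_marker_genes",
    "write_screen_tsv",
]

RAW = "raw"
LOGNORM = "lognorm"


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with row/column identifiers.

    ``values`` holds nonnegative counts (``layer_tag == "raw"``) or
    log-normalized expression (``layer_tag == "lognorm"``).
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    layer_tag: str = RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D cells x genes matrix")
        n, p = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell id count ({len(self.cell_ids)}) does not match matrix rows ({n})"
            )
        if len(self.gene_names) != p:
            raise ValueError(
                f"gene name count ({len(self.gene_names)}) does not match matrix columns ({p})"
            )
        if len(set(self.gene_names)) != p:
            raise ValueError("gene names must be unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain NaN or Inf")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if self.layer_tag not in (RAW, LOGNORM):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, cell_idx=None, gene_idx=None) -> "ExpressionMatrix":
        """Return a copy restricted to the given row/column indices."""
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        return ExpressionMatrix(
            values=self.values[np.ix_(ci, gi)],
            gene_names=[self.gene_names[j] for j in gi],
            cell_ids=[self.cell_ids[i] for i in ci],
            layer_tag=self.layer_tag,
        )


@dataclass
class CellTypeLabels:
    """Per-cell categorical labels over a fixed ordered set of K cell types."""

    labels: np.ndarray  # array of str, length n
    label_order: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.label_order = [str(t) for t in self.label_order]
        if len(self.label_order) < 2:
            raise ValueError("need at least 2 cell types (K >= 2)")
        if len(set(self.label_order)) != len(self.label_order):
            raise ValueError("label_order contains duplicates")
        known = set(self.label_order)
        bad = sorted({str(v) for v in self.labels} - known)
        if bad:
            raise ValueError(f"labels not present in label_order: {bad}")

    @property
    def n_types(self) -> int:
        return len(self.label_order)

    @property
    def codes(self) -> np.ndarray:
        """Integer codes 0..K-1 following ``label_order``."""
        lut = {t: k for k, t in enumerate(self.label_order)}
        return np.array([lut[str(v)] for v in self.labels], dtype=np.intp)

    def subset(self, cell_idx) -> "CellTypeLabels":
        return CellTypeLabels(self.labels[np.asarray(cell_idx)], list(self.label_order))

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.n_types)


@dataclass
class GeneScreenResult:
    """Per-class Wilcoxon p-values and the union of selected marker genes."""

    pvalues: np.ndarray  # K x p
    statistics: np.ndarray  # K x p Mann-Whitney U of the class sample
    selected_genes: list[str]  # union, original gene order
    per_class_top: list[list[str]]  # K lists, ranked by ascending p-value
    gene_names: list[str]
    label_order: list[str]


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rb")
    return open(path, "rb")


def _find_10x_file(d: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        cand = d / name
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing {stem}(.gz) in 10x directory {d}")


def read_matrix(path: str | os.PathLike, fmt: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from a 10x MTX directory or a dense CSV/TSV.

    The 10x convention stores the matrix genes x cells on disk; it is
    transposed to cells x genes here.  Dense CSV/TSV are cells x genes with a
    header row of gene names and the first column holding cell ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if fmt is None:
        if path.is_dir():
            fmt = "mtx_dir"
        elif path.suffix == ".csv":
            fmt = "csv"
        else:
            fmt = "tsv"

    if fmt == "mtx_dir":
        mtx_path = _find_10x_file(path, "matrix.mtx")
        feat_path = _find_10x_file(path, "features.tsv")
        bc_path = _find_10x_file(path, "barcodes.tsv")
        with _open_maybe_gz(mtx_path) as fh:
            mat = mmread(fh)
        mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=np.float64)
        feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
        bcs = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)
        genes = feats.iloc[:, 0].tolist()
        cells = bcs.iloc[:, 0].tolist()
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"{feat_path.name} lists {len(genes)} genes but matrix has {mat.shape[0]} rows"
            )
        if mat.shape[1] != len(cells):
            raise ValueError(
                f"{bc_path.name} lists {len(cells)} barcodes but matrix has {mat.shape[1]} columns"
            )
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate gene ids in {feat_path.name}")
        if len(set(cells)) != len(cells):
            raise ValueError(f"duplicate barcodes in {bc_path.name}")
        return ExpressionMatrix(mat.T, genes, cells, layer_tag=RAW)

    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64),
        [str(g) for g in df.columns],
        [str(c) for c in df.index],
        layer_tag=RAW,
    )


def write_matrix_csv(m: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write cells x genes values as CSV (header = gene names, col 1 = cell id)."""
    pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_names).to_csv(path)


_HEADER_TOKENS = {"cell_id", "cellid", "cell", "barcode", "barcodes"}


def read_labels(path: str | os.PathLike, cell_ids: Sequence[str]) -> CellTypeLabels:
    """Read a two-column (cell_id, cell_type) TSV, aligned to ``cell_ids``.

    A header row is optional and detected from the first field.  Every cell
    in ``cell_ids`` must be labeled; missing cells are a fatal error naming
    the first offender.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} must have two tab-separated columns")
    if str(df.iloc[0, 0]).strip().lower() in _HEADER_TOKENS:
        df = df.iloc[1:]
    lut = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    labels = []
    for cid in cell_ids:
        if str(cid) not in lut:
            raise ValueError(f"cell {cid!r} has no label in {path}")
        labels.append(lut[str(cid)])
    # label_order: first-appearance order in the label file, restricted to used types
    seen: list[str] = []
    for t in df.iloc[:, 1].astype(str):
        if t not in seen:
            seen.append(t)
    used = set(labels)
    order = [t for t in seen if t in used]
    return CellTypeLabels(np.array(labels, dtype=object), order)


def qc_filter(
    m: ExpressionMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
) -> ExpressionMatrix:
    """Remove low-quality cells and uninformative genes from raw counts.

    Cells with fewer than ``min_genes_per_cell`` detected (nonzero) genes and
    genes detected in fewer than ``min_cells_per_gene`` cells are dropped, as
    are zero-variance genes.  Filtering is iterated to a fixed point so the
    output is stable under re-filtering; survivor order is preserved.
    """
    if m.layer_tag != RAW:
        raise ValueError("qc_filter expects raw counts")
    keep_cells = np.arange(m.n_cells)
    keep_genes = np.arange(m.n_genes)
    X = m.values
    while True:
        sub = X[np.ix_(keep_cells, keep_genes)]
        cell_ok = (sub > 0).sum(axis=1) >= min_genes_per_cell
        if not cell_ok.any():
            raise ValueError("qc_filter removed all cells; lower min_genes_per_cell")
        sub = sub[cell_ok]
        detected = (sub > 0).sum(axis=0)
        gene_ok = (detected >= min_cells_per_gene) & (sub.var(axis=0) > 0)
        if not gene_ok.any():
            raise ValueError("qc_filter removed all genes; lower min_cells_per_gene")
        changed = (not cell_ok.all()) or (not gene_ok.all())
        keep_cells = keep_cells[cell_ok]
        keep_genes = keep_genes[gene_ok]
        if not changed:
            break
    return m.subset(keep_cells, keep_genes)


def log_normalize(m: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Per-cell log-normalization: ln(1 + count / cell_total * scale_factor)."""
    if m.layer_tag != RAW:
        raise ValueError("log_normalize expects raw counts")
    totals = m.values.sum(axis=1)
    if np.any(totals <= 0):
        bad = m.cell_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"cell {bad!r} has zero total count; run qc_filter first")
    vals = np.log1p(m.values / totals[:, None] * scale_factor)
    return replace(m, values=vals, layer_tag=LOGNORM)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses midranks with tie-corrected variance under the normal approximation;
    small tie-free samples are tested exactly.  Returns ``(U, p)`` where U is
    the Mann-Whitney statistic of ``x``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = mannwhitneyu(x, y, alternative="two-sided", use_continuity=False, method="auto")
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance combined sample
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def screen_marker_genes(
    m: ExpressionMatrix, lab: CellTypeLabels, top_n: int = 400
) -> GeneScreenResult:
    """One-vs-rest Wilcoxon screening of marker genes per cell type.

    For each cell type the genes with the ``top_n`` smallest p-values are kept
    (ties broken by larger deviation of U from its null mean, then by gene
    index); the returned ``selected_genes`` is their union in original gene
    order.  P-values are kept for downstream weighted subset sampling.
    """
    if m.layer_tag != LOGNORM:
        raise ValueError("screen_marker_genes expects log-normalized data")
    if m.n_cells != len(lab.labels):
        raise ValueError("matrix and labels have different numbers of cells")
    codes = lab.codes
    K, p = lab.n_types, m.n_genes
    counts = lab.class_counts()
    small = [lab.label_order[k] for k in range(K) if counts[k] < 2]
    if small:
        raise ValueError(
            f"cell types with fewer than 2 cells: {small}; reliable screening "
            "needs more cells per type (at least 20-30 recommended)"
        )
    pvals = np.empty((K, p))
    stats = np.empty((K, p))
    take = min(top_n, p)
    per_class_top: list[list[str]] = []
    sel_mask = np.zeros(p, dtype=bool)
    for k in range(K):
        in_k = codes == k
        res = mannwhitneyu(
            m.values[in_k],
            m.values[~in_k],
            alternative="two-sided",
            use_continuity=False,
            method="asymptotic",
            axis=0,
        )
        pk = np.nan_to_num(np.asarray(res.pvalue, dtype=np.float64), nan=1.0)
        uk = np.asarray(res.statistic, dtype=np.float64)
        pvals[k] = np.minimum(pk, 1.0)
        stats[k] = uk
        dev = np.abs(uk - in_k.sum() * (~in_k).sum() / 2.0)
        order = np.lexsort((np.arange(p), -dev, pvals[k]))
        top = order[:take]
        per_class_top.append([m.gene_names[j] for j in top])
        sel_mask[top] = True
    selected = [g for j, g in enumerate(m.gene_names) if sel_mask[j]]
    return GeneScreenResult(
        pvalues=pvals,
        statistics=stats,
        selected_genes=selected,
        per_class_top=per_class_top,
        gene_names=list(m.gene_names),
        label_order=list(lab.label_order),
    )


def write_screen_tsv(res: GeneScreenResult, path: str | os.PathLike) -> None:
    """Serialize screening results as TSV: gene, class, p_value, selected."""
    sel = set()
    for top in res.per_class_top:
        sel.update(top)
    rows = []
    for k, cls in enumerate(res.label_order):
        in_top = set(res.per_class_top[k])
        for j, g in enumerate(res.gene_names):
            rows.append((g, cls, res.pvalues[k, j], int(g in in_top)))
    pd.DataFrame(rows, columns=["gene", "class", "p_value", "selected"]).to_csv(
        path, sep="\t", index=False
    )
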