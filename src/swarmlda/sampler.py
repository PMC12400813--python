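"""Random-subspace subset generation for the model swarm.

Each of the M ensemble members is fit on its own random subset of the
reference: a fixed fraction of the cells (default 80%) and floor(sqrt(p))+70
of the p screened genes.  Uniform sampling keeps inclusion probabilities
flat; a weighted mode accepts arbitrary nonnegative per-gene weights (e.g.
derived from screening p-values).  Optional stratified cell sampling keeps
every cell type represented in every subset.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import CellTypeLabels

__all__ = [
    "SubsetSpec",
    "SwarmPlan",
    "gene_subset_size",
    "draw_swarm",
    "mean_pairwise_overlap",
]


@dataclass
class SubsetSpec:
    """One swarm member's sampled cell and gene indices plus its RNG seed."""

    cell_idx: np.ndarray
    gene_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.cell_idx = np.asarray(self.cell_idx, dtype=np.intp)
        self.gene_idx = np.asarray(self.gene_idx, dtype=np.intp)


@dataclass
class SwarmPlan:
    """The full set of M subsets, reproducible from ``master_seed``."""

    subsets: list[SubsetSpec]
    cell_frac: float
    M: int
    sampling_mode: str
    master_seed: int
    stratify: bool = False
    gene_weights: np.ndarray | None = None

    def to_json(self, path: str | os.PathLike) -> None:
        doc = {
            "cell_frac": self.cell_frac,
            "M": self.M,
            "sampling_mode": self.sampling_mode,
            "master_seed": self.master_seed,
            "stratify": self.stratify,
            "subsets": [
                {
                    "cell_idx": s.cell_idx.tolist(),
                    "gene_idx": s.gene_idx.tolist(),
                    "seed": int(s.seed),
                }
                for s in self.subsets
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SwarmPlan":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            subsets=[
                SubsetSpec(np.array(s["cell_idx"]), np.array(s["gene_idx"]), s["seed"])
                for s in doc["subsets"]
            ],
            cell_frac=doc["cell_frac"],
            M=doc["M"],
            sampling_mode=doc["sampling_mode"],
            master_seed=doc["master_seed"],
            stratify=doc.get("stratify", False),
        )


def gene_subset_size(p: int) -> int:
    """Number of genes per subset: min(floor(sqrt(p)) + 70, p)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return min(int(np.floor(np.sqrt(p))) + 70, p)


def _subset_seed(master_seed: int, i: int) -> int:
    return int(np.random.SeedSequence(master_seed, spawn_key=(i,)).generate_state(1)[0])


def _stratified_counts(class_counts: np.ndarray, n_keep: int) -> np.ndarray:
    """Largest-remainder apportionment of n_keep cells across classes, >=1 each."""
    K = len(class_counts)
    if n_keep < K:
        raise ValueError(f"cannot keep {n_keep} cells while representing {K} classes")
    n = class_counts.sum()
    quota = class_counts * n_keep / n
    take = np.maximum(np.floor(quota).astype(int), 1)
    take = np.minimum(take, class_counts)
    # adjust to hit n_keep exactly, respecting per-class availability and the >=1 floor
    while take.sum() < n_keep:
        room = class_counts - take
        frac = np.where(room > 0, quota - take, -np.inf)
        take[int(np.argmax(frac))] += 1
    while take.sum() > n_keep:
        slack = np.where(take > 1, take - quota, -np.inf)
        take[int(np.argmax(slack))] -= 1
    return take


def draw_swarm(
    n: int,
    p: int,
    M: int = 300,
    cell_frac: float = 0.8,
    mode: str = "uniform",
    gene_weights: Sequence[float] | None = None,
    labels: CellTypeLabels | None = None,
    stratify: bool = False,
    master_seed: int = 0,
) -> SwarmPlan:
    """Draw M reproducible cell/gene subsets without replacement."""
    if not (0.0 < cell_frac <= 1.0):
        raise ValueError("cell_frac must be in (0, 1]")
    if M < 1:
        raise ValueError("M must be >= 1")
    if mode not in ("uniform", "weighted"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    gw = None
    if mode == "weighted":
        if gene_weights is None:
            raise ValueError("weighted mode requires gene_weights")
        gw = np.asarray(gene_weights, dtype=np.float64)
        if gw.shape != (p,) or np.any(gw < 0) or gw.sum() <= 0:
            raise ValueError("gene_weights must be length p, nonnegative, not all zero")
        gw = gw / gw.sum()
    if stratify and labels is None:
        raise ValueError("stratified cell sampling requires labels")

    n_keep = int(round(cell_frac * n))
    g_keep = gene_subset_size(p)
    codes = labels.codes if labels is not None else None

    subsets = []
    for i in range(M):
        seed = _subset_seed(master_seed, i)
        rng = np.random.default_rng(seed)
        if stratify:
            counts = np.bincount(codes, minlength=labels.n_types)
            if np.any(counts == 0):
                raise ValueError("stratified sampling with an empty class in labels")
            take = _stratified_counts(counts, n_keep)
            parts = []
            for k, t in enumerate(take):
                members = np.flatnonzero(codes == k)
                parts.append(rng.choice(members, size=int(t), replace=False))
            cell_idx = np.sort(np.concatenate(parts))
        else:
            cell_idx = np.sort(rng.choice(n, size=n_keep, replace=False))
        if gw is not None:
            if np.count_nonzero(gw) < g_keep:
                raise ValueError("gene_weights support smaller than the gene subset size")
            gene_idx = np.sort(rng.choice(p, size=g_keep, replace=False, p=gw))
        else:
            gene_idx = np.sort(rng.choice(p, size=g_keep, replace=False))
        subsets.append(SubsetSpec(cell_idx, gene_idx, seed))
    return SwarmPlan(
        subsets=subsets,
        cell_frac=cell_frac,
        M=M,
        sampling_mode=mode,
        master_seed=master_seed,
        stratify=stratify,
        gene_weights=gw,
    )


def mean_pairwise_overlap(index_sets: Sequence[Sequence[int]]) -> float:
    """Mean Jaccard ratio |A∩B| / |A∪B| over all unordered pairs of sets.

    For subsets drawn uniformly at a fraction f of a large universe the
    expectation approaches f / (2 - f) — e.g. 2/3 at f = 0.8.
    """
    if len(index_sets) < 2:
        raise ValueError("need at least 2 index sets")
    arrays = [np.unique(np.asarray(list(s))) for s in index_sets]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty index set")
    universe = np.unique(np.concatenate(arrays))
    B = np.zeros((len(arrays), universe.size), dtype=np.float64)
    for i, a in enumerate(arrays):
        B[i, np.searchsorted(universe, a)] = 1.0
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    iu = np.triu_indices(len(arrays), k=1)
    return float(np.mean(inter[iu] / union[iu]))
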