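"""End-to-end orchestration: train, persist, predict, evaluate.

``train_pipeline`` chains preprocessing (QC -> log-normalization -> Wilcoxon
screening), swarm subset drawing, closed-form pLDA fitting, and joint
training of the aggregation layer.  A trained model is persisted as a bundle
directory (JSON manifest + subset plan + one .npz of arrays) with a
bit-exact reload contract.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml
from sklearn.metrics import confusion_matrix, f1_score

from . import __version__
from .ensemble import (
    EnsembleModel,
    PredictionResult,
    PrelimNet,
    TrainingConfig,
    VotingWeights,
    predict,
    train_ensemble,
)
from .plda import PLDAModel
from .preprocess import (
    CellTypeLabels,
    ExpressionMatrix,
    GeneScreenResult,
    log_normalize,
    qc_filter,
    screen_marker_genes,
)
from .sampler import SwarmPlan, draw_swarm

__all__ = [
    "RunConfig",
    "EvalReport",
    "train_pipeline",
    "prepare_query",
    "evaluate",
    "save_bundle",
    "load_bundle",
]


@dataclass
class RunConfig:
    """Every tunable of a training run, validated before any computation."""

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    scale_factor: float = 10_000.0
    top_n: int = 400
    n_models: int = 300
    cell_frac: float = 0.8
    sampling_mode: str = "uniform"
    stratify: bool = False
    beta: float = 1e-6
    penalty_kind: str = "trace_shrinkage"
    priors: str = "reference"
    missing_class_policy: str = "error"
    alpha: float = 0.5
    hidden: int | None = None
    shared_voter: bool = False
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 256
    max_epochs: int = 200
    val_frac: float = 0.1
    patience: int = 10
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.min_genes_per_cell >= 0, "min_genes_per_cell must be >= 0"),
            (self.min_cells_per_gene >= 0, "min_cells_per_gene must be >= 0"),
            (self.scale_factor > 0, "scale_factor must be positive"),
            (self.top_n >= 1, "top_n must be >= 1"),
            (self.n_models >= 1, "n_models must be >= 1"),
            (0 < self.cell_frac <= 1, "cell_frac must be in (0, 1]"),
            (self.sampling_mode in ("uniform", "weighted"), "bad sampling_mode"),
            (self.penalty_kind in ("trace_shrinkage", "tikhonov"), "bad penalty_kind"),
            (
                self.penalty_kind == "tikhonov" or 0 <= self.beta <= 1,
                "shrinkage beta must be in [0, 1]",
            ),
            (self.beta >= 0, "beta must be >= 0"),
            (self.priors in ("reference", "subset", "uniform"), "bad priors"),
            (0 <= self.alpha <= 1, "alpha must be in [0, 1]"),
            (self.lr > 0, "lr must be positive"),
            (0 <= self.momentum < 1, "momentum must be in [0, 1)"),
            (self.batch_size >= 1, "batch_size must be >= 1"),
            (self.max_epochs >= 1, "max_epochs must be >= 1"),
            (0 <= self.val_frac < 1, "val_frac must be in [0, 1)"),
            (self.patience >= 1, "patience must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            beta=self.beta,
            penalty_kind=self.penalty_kind,
            priors=self.priors,
            missing_class_policy=self.missing_class_policy,
            alpha=self.alpha,
            hidden=self.hidden,
            shared_voter=self.shared_voter,
            lr=self.lr,
            momentum=self.momentum,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            val_frac=self.val_frac,
            patience=self.patience,
            seed=self.seed,
        )


@dataclass
class EvalReport:
    """Annotation quality metrics against ground-truth labels."""

    overall_accuracy: float
    macro_f1: float
    per_class_f1: dict
    confusion: np.ndarray  # rows = truth, cols = predicted, over `classes`
    classes: list[str]
    degenerate_classes: list[str]  # no true and no predicted positives (F1 := 0)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "macro_f1": self.macro_f1,
            "per_class_f1": self.per_class_f1,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "degenerate_classes": self.degenerate_classes,
        }


def _screen_gene_weights(screen: GeneScreenResult) -> np.ndarray:
    """Default importance weights for weighted gene sampling.

    A generic hook: weight each gene by -ln of its best (smallest) one-vs-rest
    p-value across classes, so strongly differential genes are favored.
    """
    best = np.min(screen.pvalues, axis=0)
    return -np.log(np.maximum(best, 1e-300)) + 1e-12


def train_pipeline(
    ref: ExpressionMatrix,
    labels: CellTypeLabels,
    config: RunConfig | None = None,
    log=None,
):
    """Run QC -> normalize -> screen -> swarm -> pLDA -> ensemble training.

    Returns ``(model, plan, screen, qc_matrix, qc_labels)``.  ``log`` is an
    optional callable receiving per-stage progress strings.
    """
    config = config or RunConfig()
    config.validate()
    say = log or (lambda msg: None)
    t0 = time.perf_counter()

    id_to_row = {c: i for i, c in enumerate(ref.cell_ids)}
    qc = qc_filter(ref, config.min_genes_per_cell, config.min_cells_per_gene)
    lab = labels.subset([id_to_row[c] for c in qc.cell_ids])
    say(
        f"[qc] kept {qc.n_cells}/{ref.n_cells} cells, {qc.n_genes}/{ref.n_genes} genes "
        f"({time.perf_counter() - t0:.1f}s)"
    )

    t = time.perf_counter()
    norm = log_normalize(qc, config.scale_factor)
    screen = screen_marker_genes(norm, lab, top_n=config.top_n)
    sel_idx = [norm.gene_names.index(g) for g in screen.selected_genes]
    screened = norm.subset(gene_idx=sel_idx)
    say(
        f"[screen] selected {len(screen.selected_genes)} genes "
        f"({time.perf_counter() - t:.1f}s)"
    )

    t = time.perf_counter()
    gene_weights = None
    if config.sampling_mode == "weighted":
        best = np.min(screen.pvalues[:, sel_idx], axis=0)
        gene_weights = -np.log(np.maximum(best, 1e-300)) + 1e-12
    plan = draw_swarm(
        n=screened.n_cells,
        p=screened.n_genes,
        M=config.n_models,
        cell_frac=config.cell_frac,
        mode=config.sampling_mode,
        gene_weights=gene_weights,
        labels=lab,
        stratify=config.stratify,
        master_seed=config.seed,
    )
    say(f"[swarm] drew {plan.M} subsets ({time.perf_counter() - t:.1f}s)")

    t = time.perf_counter()
    model = train_ensemble(screened, lab, plan, config.training_config())
    say(
        f"[ensemble] trained {model.n_models} members, "
        f"{model.fit_report.get('epochs_run')} epochs, "
        f"train acc {model.fit_report.get('train_accuracy'):.3f} "
        f"({time.perf_counter() - t:.1f}s)"
    )
    return model, plan, screen, qc, lab


def prepare_query(query_raw: ExpressionMatrix, scale_factor: float) -> ExpressionMatrix:
    """Apply the bundle's stored normalization to raw query counts."""
    if query_raw.n_cells == 0:
        return ExpressionMatrix(
            query_raw.values, query_raw.gene_names, [], layer_tag="lognorm"
        )
    return log_normalize(query_raw, scale_factor)


def evaluate(pred, truth: CellTypeLabels) -> EvalReport:
    """Score predictions against ground truth.

    ``pred`` is a PredictionResult or an array of predicted label strings.
    Truth labels outside the prediction's label set count as errors.  F1 of a
    class with no true and no predicted members is defined as 0 and flagged.
    """
    y_pred = pred.labels if isinstance(pred, PredictionResult) else np.asarray(pred, dtype=object)
    y_true = truth.labels
    if len(y_pred) != len(y_true):
        raise ValueError(
            f"prediction has {len(y_pred)} cells but truth has {len(y_true)}"
        )
    classes = list(truth.label_order)
    for v in y_pred:
        if v not in classes:
            classes.append(str(v))
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    acc = float(np.mean(y_true == y_pred))
    f1 = f1_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    present = set(str(v) for v in y_true)
    macro = float(np.mean([f1[i] for i, c in enumerate(classes) if c in present]))
    degenerate = [
        c
        for i, c in enumerate(classes)
        if conf[i].sum() == 0 and conf[:, i].sum() == 0
    ]
    return EvalReport(
        overall_accuracy=acc,
        macro_f1=macro,
        per_class_f1={c: float(f1[i]) for i, c in enumerate(classes)},
        confusion=conf,
        classes=classes,
        degenerate_classes=degenerate,
    )


# ---------------------------------------------------------------------------
# bundle persistence


def save_bundle(
    model: EnsembleModel,
    plan: SwarmPlan,
    run_config: RunConfig | None,
    out_dir: str | os.PathLike,
) -> None:
    """Persist a trained model as manifest.json + plan.json + arrays.npz."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "label_order": model.label_order,
        "gene_names": model.gene_names,
        "training_config": asdict(model.training_config),
        "run_config": None if run_config is None else asdict(run_config),
        "fit_report": model.fit_report,
        "n_models": model.n_models,
        "shared_voter": model.voting.shared,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    plan.to_json(out / "plan.json")
    mods = model.plda_models
    arrays = {
        "means": np.stack([m.means for m in mods]),
        "chol": np.stack([m.sigma_chol for m in mods]),
        "chol_lower": np.array([m.chol_lower for m in mods]),
        "log_priors": np.stack([m.log_priors for m in mods]),
        "present": np.stack([m.present for m in mods]),
        "gene_idx": np.stack([m.gene_idx for m in mods]),
        "coef": np.stack([m.coef_ for m in mods]),
        "intercept": np.stack([m.intercept_ for m in mods]),
        "W1": np.stack([n.W1 for n in model.prelim_nets]),
        "b1": np.stack([n.b1 for n in model.prelim_nets]),
        "W2": np.stack([n.W2 for n in model.prelim_nets]),
        "b2": np.stack([n.b2 for n in model.prelim_nets]),
        "in_mean": np.stack([n.in_mean for n in model.prelim_nets]),
        "in_sd": np.stack([n.in_sd for n in model.prelim_nets]),
        "logits": model.voting.logits,
    }
    np.savez(out / "arrays.npz", **arrays)


def load_bundle(bundle_dir: str | os.PathLike):
    """Load a persisted bundle; returns (EnsembleModel, SwarmPlan, manifest)."""
    d = Path(bundle_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    plan = SwarmPlan.from_json(d / "plan.json")
    arr = np.load(d / "arrays.npz")
    tc = TrainingConfig(**manifest["training_config"])
    M = manifest["n_models"]
    mods = [
        PLDAModel(
            means=arr["means"][m],
            sigma_chol=arr["chol"][m],
            chol_lower=bool(arr["chol_lower"][m]),
            log_priors=arr["log_priors"][m],
            beta=tc.beta,
            penalty_kind=tc.penalty_kind,
            gene_idx=arr["gene_idx"][m],
            present=arr["present"][m],
            coef_=arr["coef"][m],
            intercept_=arr["intercept"][m],
        )
        for m in range(M)
    ]
    nets = [
        PrelimNet(
            W1=arr["W1"][m],
            b1=arr["b1"][m],
            W2=arr["W2"][m],
            b2=arr["b2"][m],
            in_mean=arr["in_mean"][m],
            in_sd=arr["in_sd"][m],
        )
        for m in range(M)
    ]
    voting = VotingWeights(
        arr["logits"],
        shared=manifest["shared_voter"],
        n_classes=len(manifest["label_order"]),
    )
    model = EnsembleModel(
        plda_models=mods,
        prelim_nets=nets,
        voting=voting,
        label_order=manifest["label_order"],
        gene_names=manifest["gene_names"],
        training_config=tc,
        fit_report=manifest.get("fit_report", {}),
    )
    return model, plan, manifest
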