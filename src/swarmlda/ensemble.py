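"""Learned aggregation of the swarm's discriminant scores.

Each of the M penalized-LDA members produces K discriminant scores per cell.
A small per-model prediction network g^(m) maps those K scores to preliminary
class probabilities; a voting layer then averages the M preliminary
predictions with per-(model, class) weights w_mk, softmax-normalized over
models within each class.  Nets and voting logits are trained jointly by
minibatch SGD on the combined loss

    L = alpha * CE(final, y) + (1 - alpha) * sum_m CE(prelim_m, y)

whose second term acts as a skip connection from each member's output to the
objective.  Everything is plain NumPy with hand-derived gradients: the nets
are tiny (K inputs, one hidden layer), so CPU training is fast and exactly
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import train_test_split

from .plda import PLDAModel, discriminant_scores, fit_plda
from .preprocess import CellTypeLabels, ExpressionMatrix
from .sampler import SwarmPlan

__all__ = [
    "PrelimNet",
    "VotingWeights",
    "TrainingConfig",
    "EnsembleModel",
    "PredictionResult",
    "proportional_probs",
    "prelim_forward",
    "aggregate_vote",
    "ensemble_loss",
    "train_ensemble",
    "predict",
]

# standardized value substituted for scores of classes absent from a member's
# fitting subset: strongly disfavored but finite
_ABSENT_FILL = -10.0


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class PrelimNet:
    """One member's prediction network g^(m): R^K -> simplex^K.

    A single-hidden-layer ReLU MLP over per-class standardized discriminant
    scores, with a softmax output.
    """

    W1: np.ndarray  # K x H
    b1: np.ndarray  # H
    W2: np.ndarray  # H x K
    b2: np.ndarray  # K
    in_mean: np.ndarray  # K, per-class score standardization
    in_sd: np.ndarray  # K

    def forward(self, scores: np.ndarray) -> np.ndarray:
        z = (np.asarray(scores, dtype=np.float64) - self.in_mean) / self.in_sd
        z = np.where(np.isfinite(z), z, _ABSENT_FILL)
        h = np.maximum(z @ self.W1 + self.b1, 0.0)
        return _softmax(h @ self.W2 + self.b2, axis=-1)


@dataclass
class VotingWeights:
    """Per-(model, class) voting logits; weights are softmax over models."""

    logits: np.ndarray  # M x K, or M x 1 in shared mode
    shared: bool = False
    n_classes: int | None = None

    @property
    def weights(self) -> np.ndarray:
        w = _softmax(self.logits, axis=0)
        if self.shared:
            K = self.n_classes or 1
            w = np.repeat(w, K, axis=1) if w.shape[1] == 1 else w
        return w


@dataclass
class TrainingConfig:
    """All tunables of ensemble fitting and training."""

    beta: float = 1e-6
    penalty_kind: str = "trace_shrinkage"
    priors: str = "reference"  # reference | subset | uniform
    missing_class_policy: str = "error"
    alpha: float = 0.5
    hidden: int | None = None  # default max(16, 4K)
    shared_voter: bool = False
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 256
    max_epochs: int = 200
    val_frac: float = 0.1
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class EnsembleModel:
    """The trained swarm: M pLDA members, M prelim nets, and voting weights."""

    plda_models: list[PLDAModel]
    prelim_nets: list[PrelimNet]
    voting: VotingWeights
    label_order: list[str]
    gene_names: list[str]  # the screened gene panel, by name
    training_config: TrainingConfig
    fit_report: dict = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return len(self.plda_models)

    @property
    def n_classes(self) -> int:
        return len(self.label_order)


@dataclass
class PredictionResult:
    probs: np.ndarray  # cells x K
    labels: np.ndarray  # array of str
    per_model_probs: np.ndarray | None = None  # M x cells x K


def proportional_probs(scores: np.ndarray) -> np.ndarray:
    """Baseline non-learned preliminary prediction from discriminant scores.

    Implemented as softmax(delta): a direct ratio delta_k / sum(delta) is
    ill-defined when scores are negative or sum to zero, while softmax is the
    standard shift-invariant map onto the simplex.  Diagnostic only.
    """
    return _softmax(np.asarray(scores, dtype=np.float64), axis=-1)


def prelim_forward(net: PrelimNet, scores: np.ndarray) -> np.ndarray:
    """Apply one prediction network to a cells x K score matrix."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite discriminant scores passed to prelim_forward")
    return net.forward(scores)


def aggregate_vote(prelim: np.ndarray, voting: VotingWeights) -> np.ndarray:
    """Softmax-weighted per-class vote over models, renormalized per cell.

    P[i,k] = sum_m w_mk * p^(m)[i,k] / sum_m w_mk, then rows rescaled to sum
    to one (the explicit denominator guards masked/shared-weight variants).
    """
    prelim = np.asarray(prelim, dtype=np.float64)
    w = voting.weights
    if prelim.ndim != 3 or prelim.shape[0] != w.shape[0] or prelim.shape[2] != w.shape[1]:
        raise ValueError(
            f"prelim shape {prelim.shape} incompatible with voting weights {w.shape}"
        )
    Q = np.einsum("mik,mk->ik", prelim, w) / w.sum(axis=0)[None, :]
    return Q / Q.sum(axis=1, keepdims=True)


def ensemble_loss(
    final: np.ndarray, prelim: np.ndarray, y: np.ndarray, alpha: float
) -> float:
    """Combined loss: alpha*CE(final) + (1-alpha)*sum over models of CE(prelim)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    final = np.asarray(final, dtype=np.float64)
    prelim = np.asarray(prelim, dtype=np.float64)
    y = np.asarray(y, dtype=np.intp)
    n = final.shape[0]
    rows = np.arange(n)
    ce_final = -np.mean(np.log(np.maximum(final[rows, y], 1e-300)))
    ce_models = -np.log(np.maximum(prelim[:, rows, y], 1e-300)).mean(axis=1).sum()
    return float(alpha * ce_final + (1.0 - alpha) * ce_models)


class _NetBank:
    """Stacked parameters of all M prelim nets plus voting logits."""

    def __init__(self, M: int, K: int, H: int, shared_voter: bool, rng: np.random.Generator):
        self.M, self.K, self.H, self.shared = M, K, H, shared_voter
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / K), size=(M, K, H))
        self.b1 = np.zeros((M, H))
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / H), size=(M, H, K))
        self.b2 = np.zeros((M, K))
        self.logits = np.zeros((M, 1) if shared_voter else (M, K))
        self._params = ("W1", "b1", "W2", "b2", "logits")
        self._vel = {p: np.zeros_like(getattr(self, p)) for p in self._params}

    def weights(self) -> np.ndarray:
        w = _softmax(self.logits, axis=0)
        return np.repeat(w, self.K, axis=1) if self.shared else w

    def forward(self, Zb: np.ndarray):
        A1 = np.matmul(Zb, self.W1) + self.b1[:, None, :]
        H1 = np.maximum(A1, 0.0)
        A2 = np.matmul(H1, self.W2) + self.b2[:, None, :]
        logP = A2 - logsumexp(A2, axis=-1, keepdims=True)
        P = np.exp(logP)
        w = self.weights()
        Q = np.einsum("mbk,mk->bk", P, w)
        R = Q.sum(axis=1)
        return A1, H1, P, logP, w, Q, R

    def loss_from_forward(self, logP, Q, R, y, alpha) -> float:
        B = len(y)
        rows = np.arange(B)
        ce_final = -np.mean(np.log(np.maximum(Q[rows, y], 1e-300)) - np.log(R))
        ce_models = -logP[:, rows, y].mean(axis=1).sum()
        return float(alpha * ce_final + (1.0 - alpha) * ce_models)

    def backward(self, Zb, A1, H1, P, w, Q, R, y, alpha):
        M, B, K = P.shape
        Y = np.zeros((B, K))
        Y[np.arange(B), y] = 1.0
        dQ = (alpha / B) * (1.0 / R[:, None] - Y / np.maximum(Q, 1e-300))
        dP = dQ[None, :, :] * w[:, None, :]
        dP = dP - ((1.0 - alpha) / B) * Y[None, :, :] / np.maximum(P, 1e-300)
        dA2 = P * (dP - np.sum(dP * P, axis=-1, keepdims=True))
        grads = {
            "W2": np.matmul(H1.transpose(0, 2, 1), dA2),
            "b2": dA2.sum(axis=1),
        }
        dH1 = np.matmul(dA2, self.W2.transpose(0, 2, 1))
        dA1 = dH1 * (A1 > 0)
        grads["W1"] = np.matmul(Zb.transpose(0, 2, 1), dA1)
        grads["b1"] = dA1.sum(axis=1)
        dw = np.einsum("bk,mbk->mk", dQ, P)
        dlog = w * (dw - np.sum(w * dw, axis=0, keepdims=True))
        grads["logits"] = dlog.sum(axis=1, keepdims=True) if self.shared else dlog
        return grads

    def sgd_step(self, grads, lr: float, momentum: float) -> None:
        for p in self._params:
            v = self._vel[p]
            v *= momentum
            v -= lr * grads[p]
            getattr(self, p).__iadd__(v)

    def snapshot(self) -> dict:
        return {p: getattr(self, p).copy() for p in self._params}

    def restore(self, snap: dict) -> None:
        for p in self._params:
            np.copyto(getattr(self, p), snap[p])


def _standardize_scores(Z: np.ndarray):
    """Per-model, per-class z-scoring of raw discriminant scores.

    Raw delta values can span many orders of magnitude (they scale with the
    inverse covariance); standardization keeps the net inputs in a range
    where a single learning rate works across datasets.
    """
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(Z, axis=1)
        sd = np.nanstd(Z, axis=1)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    sd = np.where(np.isfinite(sd) & (sd > 1e-8), sd, 1.0)
    Zs = (Z - mu[:, None, :]) / sd[:, None, :]
    return np.where(np.isfinite(Zs), Zs, _ABSENT_FILL), mu, sd


def train_ensemble(
    ref: ExpressionMatrix,
    lab: CellTypeLabels,
    plan: SwarmPlan,
    config: TrainingConfig | None = None,
) -> EnsembleModel:
    """Fit the swarm and jointly train prediction nets and voting weights.

    ``ref`` must be log-normalized and restricted to the screened gene panel;
    ``plan`` indexes into its columns.  pLDA members are fit in closed form
    (no gradients); the nets and voting logits are then trained by SGD with
    momentum on the combined loss, with a stratified held-out split for early
    stopping.  Fully reproducible from ``config.seed``.
    """
    if config is None:
        config = TrainingConfig()
    if ref.layer_tag != "lognorm":
        raise ValueError("train_ensemble expects log-normalized reference data")
    y = lab.codes
    K = lab.n_types
    n = ref.n_cells
    if np.any(lab.class_counts() < 2):
        raise ValueError("every cell type needs at least 2 reference cells")

    priors = {
        "reference": lab.class_counts() / n,
        "subset": "empirical",
        "uniform": "uniform",
    }[config.priors]

    models = []
    for spec in plan.subsets:
        Xs = ref.values[np.ix_(spec.cell_idx, spec.gene_idx)]
        models.append(
            fit_plda(
                Xs,
                y[spec.cell_idx],
                beta=config.beta,
                penalty_kind=config.penalty_kind,
                priors=priors,
                n_classes=K,
                gene_idx=spec.gene_idx,
                missing_class_policy=config.missing_class_policy,
            )
        )

    Z = np.stack(
        [discriminant_scores(mod, ref.values[:, mod.gene_idx]) for mod in models]
    )  # M x n x K
    Zs, in_mean, in_sd = _standardize_scores(Z)

    M = len(models)
    H = config.hidden or max(16, 4 * K)
    rng = np.random.default_rng(config.seed)
    bank = _NetBank(M, K, H, config.shared_voter, rng)

    idx_all = np.arange(n)
    counts = lab.class_counts()
    use_val = config.val_frac > 0 and counts.min() >= 2 and n * config.val_frac >= K
    if use_val:
        train_idx, val_idx = train_test_split(
            idx_all,
            test_size=config.val_frac,
            stratify=y,
            random_state=int(rng.integers(2**31 - 1)),
        )
    else:
        train_idx, val_idx = idx_all, None

    def epoch_loss(idx) -> float:
        _, _, _, logP, _, Q, R = bank.forward(Zs[:, idx, :])
        return bank.loss_from_forward(logP, Q, R, y[idx], config.alpha)

    best = bank.snapshot()
    best_loss = np.inf
    stale = 0
    epochs_run = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), config.batch_size):
            b = order[start : start + config.batch_size]
            Zb = Zs[:, b, :]
            A1, H1, P, logP, w, Q, R = bank.forward(Zb)
            loss = bank.loss_from_forward(logP, Q, R, y[b], config.alpha)
            if not np.isfinite(loss):
                raise ValueError(
                    "training loss diverged (NaN/Inf); reduce the learning rate"
                )
            grads = bank.backward(Zb, A1, H1, P, w, Q, R, y[b], config.alpha)
            bank.sgd_step(grads, config.lr, config.momentum)
        epochs_run = epoch + 1
        monitor = epoch_loss(val_idx if use_val else train_idx)
        if monitor < best_loss - 1e-9:
            best_loss = monitor
            best = bank.snapshot()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    bank.restore(best)

    nets = [
        PrelimNet(
            W1=bank.W1[m].copy(),
            b1=bank.b1[m].copy(),
            W2=bank.W2[m].copy(),
            b2=bank.b2[m].copy(),
            in_mean=in_mean[m].copy(),
            in_sd=in_sd[m].copy(),
        )
        for m in range(M)
    ]
    voting = VotingWeights(bank.logits.copy(), shared=config.shared_voter, n_classes=K)

    # training-time diagnostics on the reference itself
    prelim_all = np.stack([nets[m].forward(Z[m]) for m in range(M)])
    final_all = aggregate_vote(prelim_all, voting)
    pred_all = np.argmax(final_all, axis=1)
    report = {
        "train_accuracy": float(np.mean(pred_all[train_idx] == y[train_idx])),
        "epochs_run": epochs_run,
        "best_monitor_loss": float(best_loss),
    }
    if use_val:
        report["val_accuracy"] = float(np.mean(pred_all[val_idx] == y[val_idx]))

    return EnsembleModel(
        plda_models=models,
        prelim_nets=nets,
        voting=voting,
        label_order=list(lab.label_order),
        gene_names=list(ref.gene_names),
        training_config=config,
        fit_report=report,
    )


def predict(
    model: EnsembleModel, query: ExpressionMatrix, return_per_model: bool = False
) -> PredictionResult:
    """Annotate query cells with the trained ensemble.

    Query genes are matched to the model's panel by name (column order is
    irrelevant); panel genes absent from the query are imputed as 0 on the
    log scale.  Fails if fewer than half of the panel genes are present.
    """
    if query.layer_tag != "lognorm":
        raise ValueError("query must be log-normalized like the reference")
    pos = {g: j for j, g in enumerate(query.gene_names)}
    panel = model.gene_names
    hits = [pos.get(g) for g in panel]
    n_present = sum(h is not None for h in hits)
    if n_present < 0.5 * len(panel):
        raise ValueError(
            f"only {n_present}/{len(panel)} of the model's genes are present in the "
            "query; reference and query appear incompatible"
        )
    Xq = np.zeros((query.n_cells, len(panel)))
    for j, h in enumerate(hits):
        if h is not None:
            Xq[:, j] = query.values[:, h]

    prelim = np.stack(
        [
            net.forward(discriminant_scores(mod, Xq[:, mod.gene_idx]))
            for mod, net in zip(model.plda_models, model.prelim_nets)
        ]
    )
    probs = aggregate_vote(prelim, model.voting)
    labels = np.array(
        [model.label_order[k] for k in np.argmax(probs, axis=1)], dtype=object
    )
    return PredictionResult(
        probs=probs,
        labels=labels,
        per_model_probs=prelim if return_per_model else None,
    )
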