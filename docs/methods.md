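# Methods

## Overview

`swarmlda` annotates query cells by label transfer from a labeled reference.
The estimator has three stages: (1) preprocessing and marker screening,
(2) a swarm of closed-form penalized LDA (pLDA) classifiers fit on random
cell/gene subsets, and (3) a learned aggregation layer that maps each
member's discriminant scores to preliminary probabilities and combines them
by weighted soft voting. Stages 1–2 are deterministic linear algebra; only
stage 3 is trained by gradient descent.

## Preprocessing

Raw counts pass through QC (cells with fewer than `min_genes_per_cell`
detected genes removed, genes detected in fewer than `min_cells_per_gene`
cells removed, zero-variance genes removed). The thresholds default to the
community-standard 200 and 3; they are data-set dependent knobs, not model
parameters. Filtering is iterated to a fixed point so that re-filtering the
output removes nothing — a single pass cannot guarantee this because
removing genes lowers per-cell detected-gene counts.

Normalization is counts-per-10,000 followed by `log1p` (natural log). The
scale factor (default 10,000) only shifts log-values by a constant per cell;
classification is insensitive to it as long as reference and query use the
same value, which the model bundle enforces.

Marker screening performs a two-sided one-vs-rest Wilcoxon rank-sum test per
gene and cell type on the log-normalized values, and keeps the `top_n = 400`
genes with the smallest p-values per type (union across types is the working
gene panel). One-vs-rest is the natural contrast when a per-type top list is
wanted. P-values are ranked raw (no multiplicity adjustment): only the rank
order matters, and a monotone correction would not change it. Ties are
broken by the larger deviation of the U statistic from its null mean, then
by gene index, making selection deterministic. The asymptotic test uses
midranks with tie-corrected variance and no continuity correction, so two
identical samples score p = 1 exactly; tie-free samples of eight or fewer
observations are tested exactly. The per-gene p-values are retained and
exposed to the sampler as an optional importance weight (weighted mode uses
−ln of the best per-class p-value).

Screening requires at least 2 cells per type and warns toward the practical
recommendation of 20–30; rank tests on fewer cells are not stable.

## Subset sampling

Each of the `M` members receives `round(0.8 n)` cells and
`min(floor(sqrt(p)) + 70, p)` genes, drawn uniformly without replacement
(duplicates would be meaningless in LDA fitting). `M` defaults to 300 for
production use; tests and the acceptance script use `M = 20`, which is
already enough to show the ensemble effect on the synthetic fixture while
keeping runtimes in seconds. The subset sizes trade diversity against
per-member information: at 80% cell sampling the expected pairwise Jaccard
overlap between cell subsets is f/(2−f) = 2/3, while the gene subsets
(~100–170 of thousands of genes) are nearly disjoint, so members see very
different gene panels but consistent populations. Per-subset seeds are
spawned from the master seed via `numpy` `SeedSequence`, so plans are
reproducible and safely parallelizable.

Uniform sampling is the default. Two variants exist: a weighted gene-sampling
hook (arbitrary nonnegative weights) and stratified cell sampling, which
apportions the cell budget across types by largest remainder with a floor of
one cell per type — useful when rare types would otherwise vanish from some
subsets. Stratification is off by default; with it off, a type absent from a
subset is a fatal error unless the drop-and-renormalize policy is enabled,
in which case the member abstains on that type (its score column is treated
as strongly disfavored downstream).

## Penalized LDA

Per subset, class means and the pooled covariance are the maximum-likelihood
estimates; the pooled covariance uses denominator n (not n−K), matching the
likelihood being maximized — at the default shrinkage the difference is
negligible anyway. Regularization is the trace-conserving shrinkage
Σ̂(β) = (1−β)Σ̂ + β·Tr(Σ̂)·I/p, positive definite for any β > 0 on
non-degenerate data; β defaults to 1e−6 — enough to lift near-zero
eigenvalues without distorting the estimate. A Tikhonov option Σ̂ + β·I is
provided for comparison. Class priors default to the proportions in the
*full* reference rather than the subset: subset proportions are a noisy
estimate of the same quantity (with stratification off), and the prior is a
property of the reference population, not of a subsample.

Scoring solves with a Cholesky factorization of Σ̂(β) instead of forming the
inverse; the two agree to better than 1e−8 relative error (checked in the
tests against the explicit inverse). Two limits anchor correctness: β = 0
reproduces vanilla LDA decisions exactly, and β = 1 with uniform priors is
exactly the nearest-centroid rule.

## Aggregation layer

Each member's K scores are standardized per class (training mean/sd, stored
with the model) — raw discriminant values scale with the inverse covariance
and can span orders of magnitude, and standardization lets one learning rate
work across datasets. The member network g^(m) is a one-hidden-layer ReLU
MLP (width `max(16, 4K)`, softmax output): the input is only a K-vector, so
small independent nets per member are sufficient and cheap. Voting weights
w_mk are softmax over members within each class; the shared-voter flag ties
all K columns to one weight vector (typically worse — class-specific voters
can specialize). The explicit division by Σ_m w_mk is kept although softmax
makes it 1, guarding masked/shared variants, and final rows are renormalized
to sum to one.

Training minimizes α·CE(final) + (1−α)·Σ_m CE(member m) jointly over all
net parameters and voting logits. α defaults to 0.5 (equal weight to the
ensemble output and the per-member skip term); α = 1 is the standard loss
ablation. The optimizer is minibatch SGD with momentum 0.9, learning rate
0.01, batch 256, at most 200 epochs, with a 10% stratified validation split
and patience-10 early stopping (best parameters restored). Gradients are
derived by hand and verified against central finite differences in the test
suite. All randomness — initialization, batching, the split — flows from one
seed, so training is bit-reproducible.

Inference aligns query genes to the model's panel *by name*; panel genes
missing from the query are imputed as 0, the modal value of log-normalized
scRNA-seq, which keeps the closed-form scores defined. If fewer than half
the panel genes are present the query is rejected as incompatible. Ties at
the argmax resolve to the earlier type in the label order.

## Synthetic data

The generator emulates the data regime the tool targets: sparse nonnegative
integer counts, imbalanced types, marker structure, dropout. Counts are
negative binomial with dispersion (size) θ: gene g in type k has mean
`base_mean·exp(lfc)` if g is one of k's markers, `base_mean` otherwise;
independent Bernoulli dropout zeroes each entry. The standard fixture is 800
cells × 1000 genes, 4 types at proportions (0.4, 0.3, 0.2, 0.1), 30 markers
per type, lfc = 2, base mean 1.0, θ = 2.0, dropout 0.2 — with these choices
roughly half the entries are zero and marker genes are clearly but not
trivially enriched, a regime where screening and classification should both
succeed and the ensemble's advantage over single members is visible.

What the generator does *not* emulate: library-size variation, batch
effects, gene–gene correlation within a type, and compositional coupling
between types. Counts are also not Gaussian after normalization, so passing
tests demonstrate robustness to LDA's assumption being only approximate —
but success on this fixture does not bound performance on real data with
batch structure or highly similar types. A second, Gaussian generator
(shared isotropic covariance, shifted class means) produces data matching
LDA's assumptions exactly; it backs the oracle-equivalence tests.

## Numerical and design notes

- Degenerate inputs: zero-total cells are fatal at normalization (QC
  prevents them); Tr(S) = 0 is fatal for shrinkage with β > 0; a singular
  regularized covariance raises with the suggestion to increase β.
- The naive "probability proportional to the discriminant score" baseline is
  implemented as softmax(δ): a direct ratio δ_k/Σδ is undefined for negative
  or zero-sum scores. It is a diagnostic, not part of the trained model.
- F1 of a class with no true and no predicted positives is defined as 0 and
  flagged; macro-F1 averages only over classes present in the truth. Truth
  labels unknown to the model count as errors (there is no open-set
  "unknown" class).
- The closed-form stages (pLDA fitting, scoring, voting algebra) are exactly
  permutation-equivariant in the class labels; the full trained model is
  reproducible but not symmetric under relabeling, because net
  initialization does not commute with class permutations (true of any
  randomly initialized network).
- Model bundles store the Cholesky factor, solve coefficients, net
  parameters, and voting logits as float arrays; reloading a bundle yields
  bit-identical predictions.
- Problem sizes in the tests and acceptance script (M = 20 members, 800-cell
  fixtures, 5 seeds) were chosen as the smallest configurations that exhibit
  every claimed effect with margin.

## Known limitations

- Small references (tens of cells per type) give unstable screening and
  noisy members; the 20–30 cells/type floor is a practical minimum.
- No open-set detection: every query cell receives one of the reference
  types.
- No batch/platform correction; cross-platform use relies on the shared
  log-normalization and the robustness of rank-based screening.
- With stratification off and very rare types, subsets may miss a type
  entirely (fatal by default; see the drop policy above).
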