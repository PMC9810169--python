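# Methods

## Model

`scsem` clusters cells by learning, jointly, (a) a denoised low-dimensional
embedding of each cell under an explicit count-noise model and (b) a
self-expressive representation of the cell population in that embedding.

**Count noise model.** A raw count X_ij (cell i, gene j) is modelled as
zero-inflated negative binomial:

    NB(x; μ, θ)   = Γ(x+θ) / (x! Γ(θ)) · (θ/(θ+μ))^θ · (μ/(θ+μ))^x
    ZINB(x; π, μ, θ) = π δ₀(x) + (1−π) NB(x; μ, θ)

The NB captures biological overdispersion; the zero-inflation component π
captures dropout — transcripts present in the cell but absent from its
profile.  All three parameters are per-entry maps produced by linear heads
on the decoder's last hidden layer: an exponential head for the mean
(rescaled by the precomputed cell size factor s_i, so the network models
relative expression and the size factor carries depth), an exponential
head for dispersion, and a sigmoid head for dropout probability.

**Self-expressiveness.** If cells of one type span a low-dimensional
subspace, each embedded cell y_i is a linear combination of other cells in
its own subspace: Y = CY with diag(C) = 0.  C is an N×N trainable matrix;
under an ℓ2 penalty its large entries concentrate on same-subspace pairs,
so |C| symmetrized is a cluster affinity.  The trainable matrix is
initialized to the identity and a zero-diagonal mask is applied at every
use, which both honors the identity initialization and enforces the hard
constraint (the effective initial C is the zero matrix, so nothing decodes
through C before fine-tuning shapes it).

**Objective.**

    L = (λ₁ · ½‖X − X̂‖²_F + λ₂ · ½‖Y − CY‖²_F + λ₃ · ‖C‖²_F) · g + L_ZINB

with λ₁ = 0.2, λ₂ = 1.0, λ₃ = 0.5 and global scale g = 0.1.  The
reconstruction target X is the standardized encoder input (X̂ lives in
z-score space), while L_ZINB targets the raw retained counts — the two
outputs play different roles (geometry vs. likelihood).  The C-penalty is
squared Frobenius by default; an ℓ1 option (`reg_norm="l1"`) exposes the
sparse variant.  Loss toggles (`use_rec`, `use_zinb`) support ablation
runs with either term disabled.

## Architecture and training

Encoder widths 256–32–10 (fully connected, ReLU on hidden layers, linear
10-d embedding); mirrored decoder 10–32–256; four parallel heads on the
256-d decoder output.  Fully connected layers are the right inductive bias
because gene order is arbitrary — there is no spatial structure for
convolutions to exploit.  The decoder consumes Y (not CY): the
self-expressive layer is a parallel branch that only feeds the
‖Y − CY‖² term, which keeps the reconstruction path well-defined at
initialization when the effective C is zero.

Training is full batch — the self-expression term couples all cells, so
minibatching would break the N×N coefficient structure — in two phases:

1. **Pre-training** (default 100 epochs, Adam, lr 0.002): encoder, decoder
   and heads only, C frozen, loss = λ₁·rec·g + L_ZINB.  Which loss terms
   are active during pre-training is a genuinely open design point; we
   train the autoencoder alone first so that fine-tuning starts from an
   informative embedding rather than fitting C to noise.
2. **Fine-tuning** (default 40 epochs, Adam, lr 0.001): all parameters
   including C under the full objective.

Gradients come from a small reverse-mode autodiff engine in
`scsem.autodiff` (matmul, broadcast arithmetic, relu/exp/log/sigmoid/
lgamma/clip/log-sum-exp, fused ZINB NLL with analytic derivatives).  Every
primitive's gradient is tested against central finite differences.
Numerical safeguards: ZINB parameters are clamped (θ ∈ [1e-4, 1e4],
μ ∈ [1e-5, 1e6], π ∈ [1e-6, 1−1e-6]) because exponential heads can
overflow; the x = 0 likelihood branch is a log-sum-exp of
{log π, log(1−π) + θ(log θ − log(θ+μ))}, which stays finite as π → 0;
gradients are clipped at global norm 5; training aborts with a diagnostic
error on any non-finite loss.  Weights use Glorot-uniform initialization
from a single seeded generator; parameters and activations are float32 by
default (float64 via `ModelConfig(dtype="float64")` when exactness
matters, e.g. in the loss-accounting tests).

The epoch defaults (100 + 40) are the package's own choice: on the
documented fixture scales (≈500–1000 cells, 2000 genes) the loss curve and
the resulting clustering are stable well before these budgets, and
training stays a few minutes per run on one CPU core.  Larger or harder
datasets may need more epochs; both are plain config fields.  A guard
refuses N > `max_cells` (default 15000) because the dense N×N coefficient
matrix dominates memory — the same practical ceiling any full
self-expressive formulation has.

## Preprocessing

1. Drop genes expressed in no cell.
2. Size factors: per-gene geometric means over cells; genes with any zero
   count have geometric mean 0 and are excluded; s_i is the median of
   counts[i,j]/geomean_j over eligible genes.  If a cell's median is 0 or
   no eligible gene exists, that cell falls back to library size / mean
   library size — guaranteeing s_i > 0 on sparse data.
3. Normalize counts by s_i, transform log2(x+1), then z-score each gene
   over cells.  Zero-variance genes become exactly 0 (the encoder input
   must be finite).  This is the standard order of operations; applying
   the z-score before the log is undefined for values below −1, so the
   package uses normalize → log → scale.
4. Highly variable genes: dispersion = variance/mean of the log-normalized
   values, 20 equal-width bins of mean expression, z-scored within bin,
   top 2000 kept (ties by gene index).  Bins with fewer than two genes or
   zero spread score 0 — a gene whose mean expression is unlike every
   other gene's cannot be calibrated against peers.  Size factors are
   computed on all filtered genes, before HVG selection.
5. The ZINB likelihood is evaluated on the retained genes only (the model
   never sees the others).

## From SEM to labels

Base affinity A = (|C| + |Cᵀ|)/2 with zero diagonal.  By default a
rank-limited smoothing runs first: SVD of the symmetrized C truncated at
rank K·d + 1 (K clusters of intrinsic dimension d, plus one for the affine
offset), U√S row-normalized, Z = UUᵀ, affinity |Z| scaled to max 1.  This
is the established post-processing step for deep subspace clustering and
is the only place the subspace dimension d enters; `enhance=False`
disables it.  Spectral clustering uses the normalized-Laplacian embedding
into K components followed by K-means with 20 seeded restarts;
eigenvectors are sign-fixed (largest-magnitude entry positive) and
zero-degree cells get a 1e-8 self-loop so Laplacian normalization is
defined.  K is always user-supplied — estimating the number of cell types
is out of scope.

## Evaluation metrics

ACC is optimal-assignment accuracy: the contingency table between
predicted and true labels is solved as a rectangular maximum-weight
one-to-one assignment (unmatched clusters score 0).  NMI normalizes
mutual information by the arithmetic mean of the two entropies (geometric
available via `average_method`).  ARI is the pair-counting adjusted Rand
index.  All three are invariant to bijective relabeling; the tests verify
each against brute-force oracles (exhaustive assignment enumeration,
direct entropy computation, pair enumeration).

## Synthetic data

The simulator emulates the standard hierarchical gamma-Poisson recipe for
scRNA-seq counts: per-gene base means ~ Gamma(0.6, scale 3); per-group
differential expression — a `de_prob` (default 0.3) fraction of genes per
group gets a log-normal factor (location `de_logfc_loc`, sd
`de_logfc_sd`), inverted with probability ½; per-batch log-normal factors
(sd 0.15) on all genes; per-cell library sizes ~ log-normal
(location log 20000, sd 0.25) with each cell's gene means renormalized to
its library; Poisson counts; and zero inflation via a logistic function of
the log underlying mean — higher-expressed entries drop out less, matching
the structure the ZINB model assumes.  The logistic midpoint is calibrated
by bisection so the expected fraction of added zeros (masked entries whose
Poisson draw was positive) hits the requested `dropout_rate` within 0.01.
Group and batch memberships use exact largest-remainder quotas, so
balanced designs produce exactly equal groups.  All draws come from one
seeded generator in a fixed order, making fixtures bit-stable.

Two canonical fixtures define the benchmark regimes:

- **easy** — 1000 cells, 2000 genes, 5 balanced groups, 2 batches, strong
  DE (location 1.2), dropout 0.05;
- **hard** — 500 cells, 5 groups with proportions [0.4, 0.3, 0.15, 0.1,
  0.05], 2 batches, same DE, dropout 0.25 (the smallest group has 25
  cells, deliberately few for subspace learning).

What the simulator does *not* reproduce: mean-variance (BCV) trends of
real data, UMI vs. read chemistry, ambient RNA, doublets, or gene-gene
correlation beyond group/batch structure.  Perfect recovery on the easy
fixture therefore demonstrates that the pipeline solves the idealized
separation problem it was designed for, not that real tissues cluster
perfectly.

## Numerical and design notes

- All randomness (weights, simulator, K-means restarts) flows from
  explicit integer seeds; identical seeds give identical outputs on the
  same platform, and every run writes a manifest with the resolved
  configuration.
- HVG ties break by gene index; K-means uses 20 restarts; SVD-based
  smoothing uses the dense LAPACK SVD (N ≤ a few thousand).
- Degenerate inputs fail loudly: all-zero matrices, cells with zero
  library size, infeasible dropout calibration targets, K·d+1 exceeding N.
- Known limitations: O(N²) memory and O(N²·d) time in the self-expressive
  layer; no minibatched approximation for N ≫ 10⁴; dispersion is
  per-entry (not shared per-gene); no batch-effect correction step — the
  self-expression term itself provides robustness when batch effects are
  smaller than type differences.
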