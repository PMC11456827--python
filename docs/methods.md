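# Methods

## Model

`scdfn` clusters N cells from a raw counts matrix in four coupled pieces.

**Preprocessing.** The M = 2000 most variable genes are kept (mean-binned
normalized dispersion: per-gene variance/mean, z-scored within 20
equal-population bins of mean rank; constant or silent genes are never
selected; ties break lexicographically by gene id so selection is
deterministic). Counts are then size-factor normalized (per-cell total over
the median total), log1p-transformed and per-gene z-scored. The raw counts
of the selected genes and the size factors are retained: they are the
target and the exposure of the ZINB likelihood. Each step is toggleable via
`PreprocessConfig`. The exact normalization recipe is a documented package
choice — the architecture only requires real-valued inputs plus raw counts
on the side.

**Cell graph.** An exact KNN graph (default k = 15, euclidean, on the
processed matrix) is union-symmetrized (`a_ij = 1` iff i ∈ knn(j) or
j ∈ knn(i)), with distance ties broken by ascending cell index. The
propagation operator is the renormalized adjacency
`Ā = D̃^{−1/2}(A + I)D̃^{−1/2}` with D̃ the degree matrix of A + I; using
degrees of A + I (rather than of A) guarantees positive degrees for
isolated cells and keeps the spectrum of Ā inside [−1, 1], so repeated
propagation cannot blow up. The literal variant (degrees of A) is available
behind `renormalize=False` and raises on isolated cells.

**Networks.** The AE is a fully connected autoencoder
(d′ → 256 → 64 → 20, mirrored decoder); the IGAE is a symmetric graph
autoencoder (d′ → 256 → 20) whose every layer computes `σ(Ā Z W)`. Hidden
layers use a leaky rectifier (slope 0.2) — a literal linear activation
would collapse depth, so "linear" is exposed as a config option rather than
the default. Latent and output layers are linear. The adjacency
reconstruction Â is the sigmoid inner product of the sum of per-layer
encoder outputs projected to the latent width ("multilevel", default) or of
the final latent alone ("latent"). Widths are config-exposed; nothing in
the method fixes them.

**Fusion.** `Z_I = αZ_AE + (1−α)Z_IGAE` with α stored unconstrained and
squashed through a sigmoid so the convex reading always holds (raw 0 ↦ 0.5,
the initial value); `Z_L = ĀZ_I`; `S = row-softmax(Z_L Z_Lᵀ)` with row-max
subtraction for overflow safety (mathematically a no-op); and
`Z̃ = β(SZ_L) + Z_L` with β initialized at 0, so training starts from the
pure locally propagated embedding. The Gram matrix uses unnormalized dot
products. S is recomputed on every forward pass. S is dense N × N, which
bounds the practical problem size to a few thousand cells (8 GiB holds
N ≈ 30 000 doubles, but the softmax and matmuls become the wall first).

**Self-supervision.** Soft assignments use the Student-t kernel with one
degree of freedom (v = 1) and squared euclidean distances — the canonical
kernel of the self-optimizing clustering family; the unsquared variant is
available behind a flag. One shared center set μ (K × 20) parameterizes the
fused assignment Q and the two branch assignments Q′ (IGAE) and Q″ (AE),
which makes aligning their mixture with the target meaningful. The target
`p_ij ∝ q_ij²/f_j` is computed from the fused Q only. KL terms clamp logs
at 1e−12; a cluster whose soft frequency hits zero is dropped from the
target normalization with a warning.

**ZINB head.** A dedicated shallow decoder (20 → 128) maps the fused
embedding to a hidden representation from which three parallel affine heads
produce Π (sigmoid), M (exp, multiplied by the per-cell size factor) and Θ
(exp, clamped to [1e−4, 1e4]); exponent inputs are clamped to ±12 so
extreme activations cannot overflow. The likelihood targets the raw counts
of the HVG subset; the x = 0 branch uses log-sum-exp. The loss is the mean
over matrix entries, so γ₄ does not depend on matrix size. Attaching the
heads to a decoder from the fused embedding (rather than to the raw input)
ties the count model to the representation being clustered, which is the
point of using it as a reconstruction loss.

## Training

All parameters live in nested numpy arrays and every objective is
differentiated by reverse-mode automatic differentiation (autograd);
optimization is full-batch Adam — the model is transductive (the graph
fixes the cell set), so there is no minibatching.

Phases: (1) AE pretrained alone on L_AE (30 epochs, lr 1e−3); (2) IGAE
alone on L_IGAE (30 epochs); (3) a short joint phase (10 epochs) in which
both decoders decode the *fused* embedding with α, β frozen at (0.5, 0),
coupling the branches; (4) k-means++ (10 restarts, seeded) on Z̃
initializes the centers; (5) fine-tuning of everything — networks, ZINB
heads, α, β and the centers — on the quadruple loss (up to 80 epochs,
lr 1e−4). Epoch counts are sized for the desk-scale fixtures the package
ships; they are plain config fields.

Two schedule choices matter and were made after observing failure modes:

* **Target refresh interval.** One "epoch" here is a single full-batch
  gradient step. Refreshing the target P after every step makes P chase Q
  and can push fine-tuning *below* its own k-means starting point on weakly
  separated data. P is therefore held fixed for `p_update_interval = 10`
  steps, restoring the fixed-target self-training behaviour the
  distribution is designed for.
* **Early stopping.** Training stops when the fraction of cells changing
  cluster between target refreshes falls below 0.1% — but only after
  `min_epochs_finetune = 20` steps, because a single tiny full-batch step
  rarely flips any label and the rule would otherwise fire immediately.

Loss weights default to γ = (1, 1, 10, 0.1), chosen once so the four
components have comparable magnitudes on the bundled fixtures (L_KL is a
sum over cells and would otherwise be dwarfed; L_ZINB is a per-entry mean
over raw counts and runs hot early in training). No published values exist
for these weights; they are config-exposed.

Determinism: every random draw (weight init, k-means, simulation) derives
from named substreams of a single integer seed; two CPU runs with the same
seed produce bitwise-identical loss histories and labels.

Ablations: `use_ae`/`use_igae` drop a branch (the remaining branch's
embedding becomes Z̃), `fuse=False` replaces the fusion chain with the
plain mean of the branch embeddings, and `use_kl`/`use_zinb` drop loss
terms, equivalent to zeroing the corresponding γ.

## Synthetic data

The simulator draws per-gene baseline log-means uniformly on (−1, 2)
(natural log, i.e. means ≈ 0.37–7.4 counts), gives each cluster
Normal(0, logfc) log-fold-changes on a fraction of genes, multiplies in
log-normal(0, 0.3) per-cell library sizes (so normalization has something
to undo), draws NB counts via the exact Gamma–Poisson mixture with a single
simulation-wide dispersion, and zeroes entries with probability
`sigmoid(shift − log μ)` — dropout concentrated on low-mean genes, the
empirical scRNA-seq pattern. Optional batch shifts add Normal(0, batch_lfc)
per-gene offsets, with batch labels drawn independently of cluster labels.
Cells that end up fully zero (possible at extreme dropout) get one count
back at their largest-mean gene so size factors remain defined.

Pinned fixtures define the study conditions used by the tests: `easy3`
(N = 300, d = 500, k = 3, logfc 2.0 — strong separation), `hard3`
(logfc 0.6 — weak), `multicluster20` (N = 520, k = 20 with four rare
clusters of 10 cells), `batch2` (two batches, k = 4).

What the simulator does *not* emulate: gene–gene correlation beyond cluster
structure, trajectory/continuum structure, cell-cycle or ambient-RNA
artifacts, UMI saturation, and realistic gene-count scales (500 genes, not
20 000). Passing recovery tests on these fixtures shows the pipeline is
implemented correctly and behaves sanely under its own generative
assumptions; it does not certify performance on real tissue atlases.

## Numerical choices and degenerate inputs

* Softmax and ZINB zero-branch use max-subtraction / log-sum-exp.
* KL logs clamped at 1e−12; π clamped to (1e−6, 1−1e−6).
* KNN ties broken by ascending cell index (stable argsort); k-means seeded.
* Zero-total cells are a validation error naming the cell id; all-zero
  matrices are rejected before HVG selection.
* cLISI calibrates Gaussian kernel weights per cell to a target perplexity
  (default 30, capped at (N−1)/3) by binary search; rows with all-equal
  distances fall back to uniform weights. The per-cell inverse Simpson
  index is rescaled as (K_true − LISI)/(K_true − 1), so 1 is perfect local
  purity and 0 is complete mixing; the raw LISI values are available via
  `return_raw=True`. This rescaling is a package convention — reported
  alongside, not claimed identical to any published variant.
* NMI uses the arithmetic mean of entropies (geometric behind a flag).

## Known limitations

* Dense N × N adjacency, self-correlation and cLISI computations cap the
  practical size at desk scale (thousands of cells).
* K is taken as given; no model selection.
* The ZINB head uses entry-wise dispersion; gene-wise sharing is a config
  flag away conceptually but not implemented.
* CPU-only; no minibatched or distributed training.
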