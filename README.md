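# scdfn — deep fusion-network clustering for single-cell RNA-seq

Clustering cells from single-cell RNA sequencing (scRNA-seq) counts is hard
because the data are high-dimensional, sparse, overdispersed and
zero-inflated, and because expression values (what a cell makes) and
cell–cell neighborhood structure (who a cell resembles) carry complementary
signal. `scdfn` clusters a cells × genes count matrix by fusing two deep
branches and training them against their own cluster structure:

* an **attribute autoencoder (AE)** embeds the normalized expression matrix
  `X′ ∈ R^{N×d′}`;
* an **improved graph autoencoder (IGAE)** propagates every layer through
  the normalized KNN cell graph, `Z^{(l)} = σ(Ā Z^{(l−1)} Ŵ^{(l)})` with
  `Ā = D̃^{−1/2}(A + I) D̃^{−1/2}`, and reconstructs both the weighted
  attribute matrix `ĀX` and the adjacency:
  `L_IGAE = 1/(2N)‖ĀX − Ẑ‖²_F + γ·1/(2N)‖Ā − Â‖²_F`;
* an **attribute-topology fusion** combines the branch embeddings,
  `Z_I = αZ_AE + (1−α)Z_IGAE`, propagates locally `Z_L = ĀZ_I`, and adds a
  global self-correlation term `Z̃ = β(SZ_L) + Z_L` with
  `S = row-softmax(Z_L Z_Lᵀ)`; α and β are learned;
* a **triple self-supervised clustering loss** soft-assigns each embedding
  to shared cluster centers with a Student-t kernel
  `q_ij ∝ (1 + ‖z̃_i − μ_j‖²/v)^{−(v+1)/2}`, sharpens the fused assignment
  into a target `p_ij ∝ q_ij²/f_j`, and minimizes
  `L_KL = Σ_ij p_ij log[p_ij / ((q_ij + q′_ij + q″_ij)/3)]`;
* a **ZINB reconstruction loss** models the raw counts,
  `ZINB(x|π, μ, θ) = π δ₀(x) + (1−π) NB(x|μ, θ)`, with dropout, mean and
  dispersion heads decoded from the fused embedding.

The joint objective is `L = γ₁L_AE + γ₂L_IGAE + γ₃L_KL + γ₄L_ZINB`.
Training is two-phase (branch-wise pretraining plus a short joint phase,
then k-means++ center initialization and fine-tuning of everything), fully
deterministic on CPU for a given seed.

The package ships a ZINB count simulator with known cluster structure, a
metric suite (NMI, ARI, ASW, cLISI) and a CLI, so every stage is testable
without downloads. It is aimed at computational biologists who want a
transparent, desk-scale reference implementation of fusion-network
clustering rather than a GPU production pipeline.

## Worked example

```python
from scdfn import SCDFN, simulate

sim = simulate.fixture("easy3")        # 300 cells, 500 genes, 3 clusters
model = SCDFN.from_raw_counts(sim.counts, n_clusters=3)
result = model.fit(seed=0)
print(result.summary())
report = result.evaluate(sim.true_labels)
print(f"ARI={report.ari:.3f} NMI={report.nmi:.3f} "
      f"ASW={report.asw:.3f} cLISI={report.clisi:.3f}")
```

Output:

```
Deep fusion-network clustering results
==============================================
cells                 300
clusters (k)          3
latent dimension      20
epochs run            90
converged             True
fusion alpha          0.4995
fusion beta           0.0019
cluster sizes         [100, 100, 100]
----------------------------------------------
final L_AE            203.162255
final L_IGAE          10.969934
final L_KL            40.707044
final L_ZINB          4.037293
final total           621.606361
ARI=1.000 NMI=1.000 ASW=0.771 cLISI=1.000
```

All 300 cells land in their generating cluster (ARI = NMI = 1); the
silhouette of 0.77 says the fused embedding separates the three clusters
with wide margins, and cLISI = 1 says every cell's neighborhood is purely
its own type. The four loss components are on the scales the default
weights γ = (1, 1, 10, 0.1) were chosen for.

The same pipeline from the shell:

```sh
scdfn simulate --fixture easy3 --outdir data/
scdfn fit data/counts.tsv --n-clusters 3 --seed 0 --outdir run/
scdfn evaluate run/labels.tsv data/true_labels.tsv \
      --embedding run/embedding.tsv --outdir run/
```

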