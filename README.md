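# scgnn

Gene-expression imputation and cell clustering for single-cell RNA-Seq,
built around an iterative set of autoencoders coupled through a pruned
cell–cell graph.

Single-cell RNA-Seq matrices are dominated by technical zeros ("dropout"):
transcripts present in the cell but missed by the assay. This package
recovers plausible values for those entries and clusters cells at the same
time, using the idea that cells related in a graph built from the data
should inform each other's expression. It is aimed at computational
biologists who want a transparent, numpy-level implementation of this
family of methods — every model component is a plain function with a
documented loss — rather than a black-box tool.

## Method

Given a cells × genes matrix X (filtered, log-transformed, restricted to
the top variable genes):

1. A **left-truncated mixture Gaussian (LTMG)** is fitted per gene by
   censored-data EM; values ≤ 0 contribute the left-tail mass
   αᵢΦ((T−μᵢ)/σᵢ) to the likelihood, and BIC selects the number of
   components. The per-cell argmax component is the transcriptional
   regulatory signal TRS ∈ ℝ^{N×M}.
2. A **feature autoencoder** (512–128 encoder, sigmoid decoder) minimises

   Loss = (1−α) Σ (X−X̂)² + α Σ ((X−X̂)² ∘ TRS)

   and its 128-d bottleneck embeds the cells.
3. A **KNN cell graph** on the embedding is pruned per node by
   Isolation-Forest outlier scores on neighbour distances; a two-layer
   **GCN graph autoencoder** Z = ReLU(Ã ReLU(Ã X′W₁)W₂), Â = sigmoid(ZZᵀ)
   is trained by cross-entropy against the adjacency. Louvain on the graph
   fixes the cluster count k, and k-means on Z assigns cells.
4. **Cluster autoencoders** reconstruct each cluster's cells independently;
   the concatenation feeds the next iteration, with the propagation matrix
   mixed as Ã = λL₀ + (1−λ)A/ΣA. The loop stops when the adjacency or the
   clustering stabilises.
5. An **imputation autoencoder** retrains on the original pre-processed
   matrix with the TRS term, an L1 weight penalty β Σ|w| and graph/co-cluster
   regularizers γ₁ Σ(A·(X−X̂)²) + γ₂ Σ(B·(X−X̂)²); its reconstruction is the
   imputed matrix.

See `docs/methods.md` for every default, the numerical choices, and known
limitations. The autoencoders are implemented directly in numpy (hand-derived
gradients + Adam), so runs are exactly reproducible for a fixed seed.

## Worked example

Cluster and impute a synthetic matrix with three planted cell types
(200 cells each, 300 genes, ~67% zeros):

```python
from scgnn import (ScgnnConfig, SyntheticSpec, adjusted_rand_index,
                   generate_zinb, run_scgnn)

counts, truth, _ = generate_zinb(SyntheticSpec(seed=1))
result = run_scgnn(counts, ScgnnConfig.desk_scale(), seed=1)
print(result.report["stop_reason"], result.report["n_iterations"])
print("clusters:", result.clusters.n_clusters)
print("ARI vs planted labels:",
      round(adjusted_rand_index(truth.labels, result.clusters.labels), 3))
```

```
clustering_converged 2
clusters: 3
ARI vs planted labels: 0.975
```

The loop converged at the second iteration because consecutive clusterings
agreed (ARI > 0.99); Louvain on the pruned cell graph chose k = 3, matching
the planted structure, and the k-means assignment on the graph embedding
recovers the true cell types almost perfectly (ARI 0.975; 1.0 would be an
exact recovery). `result.imputed` holds the imputed matrix on the
log-transformed scale of the preprocessed input.

The same pipeline is available from the shell:

```bash
scgnn simulate --n-clusters 3 --cells-per-cluster 200 --n-genes 300 --seed 1 --out sim/
scgnn run --input sim/counts.csv --outdir out/ --seed 1
scgnn bench --input sim/counts.csv --dropout-rate 0.1 --repeats 3 --seed 1 --out bench.json
```

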