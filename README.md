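# spatialink

De novo reconstruction of cell–cell interaction networks from single-cell
spatial transcriptome data.

## The problem

Spatially resolved transcriptomics (seqFISH, MERFISH, HDST, ...) measures
gene expression per cell together with the cell's position in the tissue
section. Cells that touch each other are likely to interact, so the
proximity graph of a section is an observation of the cell–cell interaction
landscape — but a noisy and incomplete one: it misses distal interactions
(cytokine signalling, secreted vesicles), contains false contacts, and the
expression data behind it suffer dropout and noise. `spatialink` treats the
proximity graph as a corrupted subset of the true interaction network and
learns to regenerate a denoised, completed network directly from expression,
with no ligand–receptor annotations or other prior knowledge.

## The model

An adversarially regularized variational graph autoencoder. Given the
cells × genes expression matrix **X** and the binary cell adjacency matrix
**A** (3-nearest-neighbour contacts within a distance threshold), a
two-layer graph convolutional encoder produces a diagonal-Gaussian posterior
per cell:

    Ã = D^{-1/2} (A + I) D^{-1/2}
    μ = Ã · ReLU(Ã X W₀) · W₁_μ,      log σ = Ã · ReLU(Ã X W₀) · W₁_σ
    q(hᵢ | X, A) = N(μᵢ, diag(σᵢ²))

The inner-product decoder scores every cell pair, p(Aᵢⱼ = 1 | H) =
sigmoid(hᵢ·hⱼ). Training maximizes the evidence lower bound — class-weighted
reconstruction cross-entropy minus the KL divergence from the N(0, I) prior
— while a small adversarial MLP, trained to tell prior samples from encoder
samples, pushes the latent distribution toward the prior. Everything runs in
pure numpy with analytic gradients (no GPU or deep-learning framework
required); the gradients are verified against finite differences in the test
suite.

Downstream analyses built on the reconstructed network:

- **robustness** — corruption benchmarks (expression fold noise, gene/value
  dropout, edge deletion/insertion, tissue cropping) with AUROC/AUPRC/FPR
  metrics;
- **reconstruction** — accuracy-optimal probability threshold, network
  assembly, proximal/distal edge classification;
- **enrichment** — permutation tests for over/under-represented cell-type
  interaction pairs, overall and for distal edges only;
- **gene_sensitivity** — per-gene permutation-importance (ΔAUPRC) scores and
  simple-classifier benchmarks of gene panels;
- **latent_domains** — k-means spatial domains on the latent embedding
  (Calinski–Harabasz model selection) with domain marker genes
  (one-vs-rest *and* all one-vs-one Mann–Whitney U tests).

A synthetic-tissue generator (`simulate_tissue`) plants a known interaction
graph and a known informative-gene panel, providing ground truth for every
analysis.

## Worked example

```python
from spatialink import simulate_tissue, build_adjacency, split_edges, train, ModelConfig
from spatialink.vgae_core import decode, score_pairs
from spatialink.reconstruction import select_threshold, assemble_network, classify_distal
from spatialink.robustness import compute_auroc, compute_fpr_at_threshold

ds, truth = simulate_tissue(n_cells=500, n_types=5, n_genes=60,
                            n_informative=20, seed=0)
graph = build_adjacency(ds.coordinates, k=3, distance_threshold="auto")
split = split_edges(graph, test_fraction=0.1, neg_ratio=100, seed=0)
config = ModelConfig(feature_scaling="log1p_zscore", early_stopping=True, seed=0)
result = train(ds, split, config)

H = result.embedding.H
pos = score_pairs(H, sorted(split.test_pos))
neg = score_pairs(H, sorted(split.test_neg))
probs = decode(H)
threshold = select_threshold(probs, split)
net = assemble_network(probs, threshold, ds.coordinates)
classify_distal(net, cutoff="auto", original_graph=graph, coords=ds.coordinates)

print(f"observed contact graph: {graph.n_edges} edges over {graph.n_cells} cells")
print(f"held-out AUROC: {compute_auroc(pos, neg):.3f}")
print(f"FPR at selected threshold {threshold:.3f}: "
      f"{compute_fpr_at_threshold(neg, threshold):.4f}")
print(f"reconstructed network: {net.n_edges} edges "
      f"({len(net.distal_edges)} distal beyond "
      f"{net.distal_distance_cutoff:.1f} length units)")
```

prints

```
observed contact graph: 854 edges over 500 cells
held-out AUROC: 0.958
FPR at selected threshold 1.000: 0.0000
reconstructed network: 30 edges (4 distal beyond 5.4 length units)
```

The model recovers held-out contacts from expression alone (AUROC 0.958
against a 100:1 negative set). The accuracy-optimal threshold is pushed high
by the 100:1 class imbalance, so the assembled network at that threshold is
conservative and its false-positive rate is essentially zero;
`select_threshold(..., balanced=True)` trades precision for a denser
network. Four of the retained edges span distances beyond the direct-contact
regime — candidate distal interactions absent from the input graph.

The same workflows are available from the shell:

```sh
spatialink simulate --n-cells 500 --n-genes 60 --seed 0 --out-dir sim
spatialink graph --coords sim/coordinates.csv --threshold auto --out edges.tsv
spatialink train --expr sim/expression.csv --coords sim/coordinates.csv --out run
spatialink benchmark --expr ... --mode remove-edges --grid 0.1,0.3,0.5 --repeats 30 --out bench.tsv
spatialink sensitivity --expr ... --checkpoint run/checkpoint.npz --out sens.tsv
```

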