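# scnetpas

Gene–cell association networks and network-propagation pathway activity
scoring for single-cell transcriptomics and epigenomics.

## The problem

Single-cell RNA-seq and ATAC-seq matrices are sparse and noisy, and
per-cell pathway statements made from raw expression are fragile: a
pathway can be active in a cell even when several member genes drop out.
`scnetpas` addresses this by moving from the matrix to a *network*: genes
and cells become nodes of one heterogeneous weighted graph, and pathway
activity in a cell is measured by how much random-walk probability flows
from the pathway's genes to that cell. The package is for computational
biologists who want per-cell pathway activity profiles, phenotype-associated
gene modules, multi-omics (RNA + ATAC) network fusion over the same cells,
and cell-community summaries.

## The model

Starting from a gene × cell matrix *X* (m genes, n cells):

1. **TRS extraction.** Each gene's expression is fit with a left-truncated
   Gaussian mixture: values below a resolution threshold Z_cut contribute
   censored mass Σᵢ aᵢΦ((Z_cut − μᵢ)/σᵢ), values above contribute Gaussian
   densities; K is chosen by BIC. Each value maps to a discrete
   transcriptional-regulation state in {0, …, K}.
2. **Gene–cell association.** Two small encoders embed genes (E^g, m×d) and
   cells (E^c, n×d); the decoder X′ = E^g (E^c)ᵀ is trained with the
   TRS-regularised loss
   `(1−a)·Σ(X′−X)² + a·Σ(X′−X)² ⊙ S̃_TRS`, so reconstruction effort
   concentrates on confidently active entries. X′ is the gene–cell block K.
3. **Gene–gene / cell–cell networks.** Pearson correlation graphs filtered
   by a per-node empirical-p rule (p < 0.05 among positive partners), then
   refined by a variational graph autoencoder with inner-product decoder
   σ(z_iᵀz_j), giving blocks G and C.
4. **Propagation.** The blocks are min-max normalised, spliced as
   [[G, K], [Kᵀ, C]], and column-normalised into W. Random walk with
   restart, p_{t+1} = (1−r)·W·p_t + r·p₀ with r = 0.7, is run from pathway
   genes; the pathway activity score of cell j is the permutation-adjusted
   PAS_ij = 1 − |{p′_j ≥ p_ij}|/N over N = 100 random same-size gene seeds.
   Seeding a phenotype's cells instead yields per-gene association scores
   and permutation p-values; genes with p < 0.01 form the phenotype's gene
   module.
5. **Fusion and communities.** Same-cell RNA and ATAC networks merge via
   Brown's method on pseudo p-values p = 1 − w (shared edges combined, unique
   edges carried over); cell communities (Louvain, leading eigenvector, or
   edge betweenness) collapse into a community network whose edges average
   the inter-community cell–cell weights.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Simulate a small dataset with three phenotypes, each with a planted block of
active genes, build the network, and score the planted blocks as pathways:

```python
from scnetpas import simulate, pipeline, dnnae, graphs
from scnetpas.propagate import RWRConfig
from scnetpas.types import GeneSetCollection

spec = simulate.SimSpec(m=120, n=90, n_phenotypes=3, block_size=8,
                        dropout=0.2, seed=0)
x, phen, truth = simulate.simulate_expression(spec)

cfg = pipeline.PipelineConfig(
    dnnae=dnnae.DNNAEConfig(d=16, hidden_dims=(64,), lr=0.01, iters=300, seed=0),
    vgae=graphs.VGAEConfig(latent_dim=8, hidden_dim=16, iters=150, seed=0),
    rwr=RWRConfig(n_perm=100, seed=0),
)
net = pipeline.build_network(x, cfg)
print(f"network: {len(net.genes)} gene nodes, {len(net.cells)} cell nodes")

sets = GeneSetCollection({f"block_{k}": v for k, v in truth.items()})
pas = pipeline.score_pathways(net, sets, cfg)
for i, name in enumerate(pas.pathways):
    for label in ("pheno0", "pheno1", "pheno2"):
        cells = [j for j, c in enumerate(net.cells)
                 if phen.assignments[c] == label]
        print(f"{name} mean PAS in {label}: {pas.scores[i, cells].mean():.3f}")
```

Output:

```
network: 120 gene nodes, 90 cell nodes
block_pheno0 mean PAS in pheno0: 0.765
block_pheno0 mean PAS in pheno1: 0.598
block_pheno0 mean PAS in pheno2: 0.494
block_pheno1 mean PAS in pheno0: 0.793
block_pheno1 mean PAS in pheno1: 0.803
block_pheno1 mean PAS in pheno2: 0.770
block_pheno2 mean PAS in pheno0: 0.843
block_pheno2 mean PAS in pheno1: 0.781
block_pheno2 mean PAS in pheno2: 0.881
```

Each printed number is the mean pathway activity score (in [0, 1]) of one
planted gene block in the cells of one phenotype; a block scores highest in
its own phenotype, as planted. On noisy simulations of this size the margin
between own- and other-phenotype scores is real but modest — permutation
adjustment compresses extreme scores toward the grid {0, 0.01, …, 1}.

The same objects drive the rest of the API:
`pipeline.find_modules(net, phen, cfg)` returns per-phenotype gene modules
with permutation p-values, `scnetpas.fusion.fuse(net_rna, net_atac)` merges
two same-cell networks, and `scnetpas.community.detect_communities` +
`merge_to_community_network` summarise the cell–cell block.

A command-line interface mirrors the library
(`scnetpas simulate | preprocess | ltmg | train-dnnae | train-gae |
build-network | score-pathways | find-modules | fuse | community`); every
input and output is a plain-text format (Matrix Market directory, CSV/TSV,
GMT, BED, GTF, edge-list TSV, JSON).

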