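"""End-to-end convenience wrapper: matrix -> network -> scores/modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import assembly, dnnae, graphs, ltmg, preprocess, propagate
from .types import GeneCellMatrix, GeneCellNetwork, GeneSetCollection, PathwayScoreMatrix, PhenotypeTable


@dataclass
class PipelineConfig:
    hvg: int | None = None  # None: keep all genes
    k_max: int = 5
    dnnae: dnnae.DNNAEConfig = field(default_factory=dnnae.DNNAEConfig)
    vgae: graphs.VGAEConfig = field(default_factory=graphs.VGAEConfig)
    rwr: propagate.RWRConfig = field(default_factory=propagate.RWRConfig)
    corr_alpha: float = 0.05


def build_network(x_counts: GeneCellMatrix, cfg: PipelineConfig | None = None) -> GeneCellNetwork:
    """QC, normalise, (optionally) select HVGs, fit the TRS, train the
    autoencoder and the two VGAEs, and assemble the gene-cell network."""
    if cfg is None:
        cfg = PipelineConfig()
    x, _report = preprocess.qc_filter(x_counts)
    x = preprocess.log_normalize(x)
    if cfg.hvg is not None and cfg.hvg < x.n_genes:
        x = preprocess.select_hvg(x, cfg.hvg)
    trs = ltmg.fit_trs_matrix(x, k_max=cfg.k_max)
    emb, xprime, _trace = dnnae.train(x, trs, cfg.dnnae)
    gene_net = graphs.build_correlation_network(x, axis="gene", alpha=cfg.corr_alpha)
    cell_net = graphs.build_correlation_network(x, axis="cell", alpha=cfg.corr_alpha)
    gene_refined, _ = graphs.train_vgae(gene_net, emb.gene_embeddings, cfg.vgae)
    cell_refined, _ = graphs.train_vgae(cell_net, emb.cell_embeddings, cfg.vgae)
    K = np.clip(xprime, 0.0, None)  # RWR needs nonnegative weights
    return assembly.assemble(
        gene_refined.adjacency, cell_refined.adjacency, K,
        genes=list(x.genes), cells=list(x.cells),
    )


def score_pathways(
    net: GeneCellNetwork, pathways: GeneSetCollection, cfg: PipelineConfig | None = None
) -> PathwayScoreMatrix:
    if cfg is None:
        cfg = PipelineConfig()
    return propagate.pathway_scores(net, pathways, cfg.rwr)


def find_modules(
    net: GeneCellNetwork, phen: PhenotypeTable, cfg: PipelineConfig | None = None, p_threshold: float = 0.01
):
    if cfg is None:
        cfg = PipelineConfig()
    return propagate.gene_modules(net, phen, cfg.rwr, p_threshold=p_threshold)
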