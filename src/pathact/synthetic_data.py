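"""Synthetic scRNA-seq generator with planted pathway-level tumor structure.

Counts are negative binomial around lognormal per-gene baseline means, with
logistic mean-dependent dropout layered on top — the minimal generative
structure under which pathway-mean scoring provably pools signal, and the
standard shape for scRNA-seq simulation. Tumor cells differ from normal
cells in two ways that mirror real tumor data: a set of planted pathways is
shifted up or down on the mean scale by 2^(+/- effect_log2fc) (the
metabolic-up / immune-down pattern), and an optional library-size multiplier
makes tumor cells express more detected genes than normal cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .io_formats import CountMatrix, GeneSetCollection, LabelVector


@dataclass
class SimulationConfig:
    n_tumor: int = 500
    n_normal: int = 500
    n_genes: int = 2000
    n_pathways: int = 50
    genes_per_pathway: tuple[int, int] = (25, 60)
    n_up_pathways: int = 5
    n_down_pathways: int = 5
    effect_log2fc: float = 1.0
    baseline_mean_log_mu: float = -0.7
    baseline_mean_log_sd: float = 1.0
    dispersion: float = 0.5
    tumor_library_scale: float = 1.5
    dropout_midpoint: float = 0.0
    dropout_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tumor, self.n_normal, self.n_genes, self.n_pathways) < 1:
            raise ValueError("cell, gene and pathway counts must be positive")
        if self.n_up_pathways + self.n_down_pathways > self.n_pathways:
            raise ValueError("planted pathways exceed n_pathways")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.tumor_library_scale < 1:
            raise ValueError("tumor_library_scale must be >= 1")
        lo, hi = self.genes_per_pathway
        if lo < 1 or hi < lo:
            raise ValueError("genes_per_pathway must be a valid (lo, hi) range")


@dataclass
class SyntheticTruth:
    labels: LabelVector
    up_pathways: set[str]
    down_pathways: set[str]
    tumor_mean: np.ndarray
    normal_mean: np.ndarray


def _pathway_name(i: int) -> str:
    return f"PW{i + 1:04d}"


def _gene_name(i: int) -> str:
    return f"G{i + 1:05d}"


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, GeneSetCollection, SyntheticTruth]:
    """Draw a labeled count matrix plus its gene sets and planted truth.

    Genes are partitioned into non-overlapping pathways (sizes uniform in
    ``genes_per_pathway``; genes left over after partitioning belong to no
    pathway). Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_tumor + config.n_normal
    genes = [_gene_name(i) for i in range(config.n_genes)]
    barcodes = [f"CELL{i + 1:05d}" for i in range(n_cells)]

    # partition genes into pathways
    lo, hi = config.genes_per_pathway
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    if sizes.sum() > config.n_genes:
        raise ValueError(
            f"pathways need {sizes.sum()} genes but only {config.n_genes} exist"
        )
    gene_order = rng.permutation(config.n_genes)
    pathways: dict[str, set[str]] = {}
    member_rows: dict[str, np.ndarray] = {}
    offset = 0
    for p in range(config.n_pathways):
        rows = gene_order[offset:offset + sizes[p]]
        offset += sizes[p]
        name = _pathway_name(p)
        pathways[name] = {genes[i] for i in rows}
        member_rows[name] = rows
    gene_sets = GeneSetCollection(pathways, source="synthetic")

    planted = rng.choice(
        config.n_pathways,
        size=config.n_up_pathways + config.n_down_pathways,
        replace=False,
    )
    up_names = {_pathway_name(i) for i in planted[:config.n_up_pathways]}
    down_names = {_pathway_name(i) for i in planted[config.n_up_pathways:]}

    baseline = rng.lognormal(
        mean=config.baseline_mean_log_mu,
        sigma=config.baseline_mean_log_sd,
        size=config.n_genes,
    )
    tumor_mean = baseline.copy()
    for name in up_names:
        tumor_mean[member_rows[name]] *= 2.0 ** config.effect_log2fc
    for name in down_names:
        tumor_mean[member_rows[name]] *= 2.0 ** -config.effect_log2fc
    normal_mean = baseline

    labels = np.concatenate(
        [np.ones(config.n_tumor, dtype=int), np.zeros(config.n_normal, dtype=int)]
    )
    lib = np.where(labels == 1, config.tumor_library_scale, 1.0)
    mu = np.where(labels[None, :] == 1, tumor_mean[:, None],
                  normal_mean[:, None]) * lib[None, :]

    # NB with size r and mean mu: p = r / (r + mu)
    r = config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    p_drop = 1.0 / (1.0 + np.exp(
        config.dropout_slope * (np.log(mu) - config.dropout_midpoint)
    ))
    counts = np.where(rng.random(mu.shape) < p_drop, 0, counts)

    matrix = CountMatrix(
        genes=genes, barcodes=barcodes, counts=sp.csr_matrix(counts)
    )
    truth = SyntheticTruth(
        labels=LabelVector(barcodes=barcodes, labels=labels),
        up_pathways=up_names,
        down_pathways=down_names,
        tumor_mean=tumor_mean,
        normal_mean=normal_mean,
    )
    return matrix, gene_sets, truth


ACCEPTANCE_CONFIG = SimulationConfig(
    n_tumor=1000,
    n_normal=1000,
    n_genes=5000,
    n_pathways=100,
    genes_per_pathway=(25, 60),
    n_up_pathways=10,
    n_down_pathways=10,
    effect_log2fc=1.0,
    dispersion=0.5,
    tumor_library_scale=1.5,
)


@dataclass
class AcceptanceBundle:
    counts: CountMatrix
    gene_sets: GeneSetCollection
    truth: SyntheticTruth
    train_idx: np.ndarray
    test_idx: np.ndarray
    config: SimulationConfig


def make_acceptance_dataset(seed: int = 0) -> AcceptanceBundle:
    """The frozen benchmark configuration: 1000 tumor + 1000 normal cells,
    5000 genes, 100 pathways of 25-60 genes, 10 up + 10 down planted at one
    log2 unit, NB dispersion 0.5, tumor library scale 1.5; includes a
    stratified 8:2 train/test split."""
    config = replace(ACCEPTANCE_CONFIG, seed=seed)
    counts, gene_sets, truth = generate_dataset(config)
    from .classifier import _stratified_split

    train_idx, test_idx = _stratified_split(
        truth.labels.labels, split_ratio=0.8, seed=seed, min_per_class=2
    )
    return AcceptanceBundle(
        counts=counts,
        gene_sets=gene_sets,
        truth=truth,
        train_idx=train_idx,
        test_idx=test_idx,
        config=config,
    )
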