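"""Convert sparse per-gene counts into dense per-cell pathway activity scores.

The featurization pools dozens of genes per pathway, so a cell in which only
a handful of a pathway's genes survived dropout still receives a graded
activity value instead of the hard zero a single marker gene would give.

The score for pathway P in cell c is the mean library-normalized,
log1p-transformed expression over the pathway genes present in the matrix,
with undetected (zero) genes included in the mean: detection itself carries
signal, because tumor cells tend to express more genes than normal cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, GeneSetCollection


@dataclass
class NormalizationParams:
    """Library-size normalization settings, recorded in the model artifact."""

    target_sum: float = 10_000.0
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")


@dataclass
class PathwayScoreMatrix:
    """Pathways x cells real-valued activity scores."""

    pathway_names: list[str]
    barcodes: list[str]
    scores: np.ndarray
    n_genes_used: np.ndarray
    dropped: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.n_genes_used = np.asarray(self.n_genes_used, dtype=int)
        if self.scores.shape != (len(self.pathway_names), len(self.barcodes)):
            raise ValueError("score matrix shape does not match axis labels")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite pathway scores")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def subset_pathways(self, names: list[str]) -> "PathwayScoreMatrix":
        index = {n: i for i, n in enumerate(self.pathway_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"pathways absent from score matrix: {missing[:5]}")
        rows = [index[n] for n in names]
        return PathwayScoreMatrix(
            pathway_names=list(names),
            barcodes=list(self.barcodes),
            scores=self.scores[rows],
            n_genes_used=self.n_genes_used[rows],
        )

    def subset_cells(self, indices: np.ndarray) -> "PathwayScoreMatrix":
        indices = np.asarray(indices)
        return PathwayScoreMatrix(
            pathway_names=list(self.pathway_names),
            barcodes=[self.barcodes[i] for i in indices],
            scores=self.scores[:, indices],
            n_genes_used=self.n_genes_used,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.pathway_names,
                            columns=self.barcodes)


def normalize_counts(
    counts: CountMatrix, params: NormalizationParams | None = None
) -> sp.csr_matrix:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Returns a sparse genes x cells matrix of floats; zeros map to zeros.
    Cells with zero total counts cannot be normalized and raise an error
    naming them.
    """
    params = params or NormalizationParams()
    totals = np.asarray(counts.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        offenders = [counts.barcodes[i] for i in np.flatnonzero(totals == 0)[:10]]
        raise ValueError(f"cells with zero total counts: {offenders}")
    factors = params.target_sum / totals
    normalized = counts.counts.multiply(factors[np.newaxis, :]).tocsr()
    if params.log_transform:
        normalized.data = np.log1p(normalized.data)
    return normalized


def score_pathways(
    normalized: sp.spmatrix,
    genes: list[str],
    barcodes: list[str],
    gene_sets: GeneSetCollection,
    min_genes: int = 3,
) -> PathwayScoreMatrix:
    """Mean normalized expression per pathway and cell, zeros included.

    Pathway genes absent from the matrix's gene universe are ignored (not
    treated as zero); pathways matching fewer than ``min_genes`` genes are
    dropped and listed in ``dropped``. Raises if no pathway matches anything,
    which almost always means a gene-symbol namespace mismatch.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    normalized = sp.csr_matrix(normalized)
    gene_index = {g: i for i, g in enumerate(genes)}

    kept_names: list[str] = []
    kept_rows: list[list[int]] = []
    kept_counts: list[int] = []
    dropped: list[tuple[str, int]] = []
    any_match = False
    for name, members in gene_sets.pathways.items():
        rows = sorted(gene_index[g] for g in members if g in gene_index)
        if rows:
            any_match = True
        if len(rows) < min_genes:
            dropped.append((name, len(rows)))
            continue
        kept_names.append(name)
        kept_rows.append(rows)
        kept_counts.append(len(rows))
    if not any_match:
        raise ValueError(
            "no pathway shares any gene with the expression matrix; "
            "check the gene-symbol namespace"
        )
    if not kept_names:
        raise ValueError(
            f"every pathway matched fewer than min_genes={min_genes} genes"
        )

    # membership matrix (pathways x genes) with weights 1/|P ∩ G|
    indptr = np.cumsum([0] + kept_counts)
    indices = np.concatenate([np.array(r, dtype=int) for r in kept_rows])
    data = np.concatenate(
        [np.full(n, 1.0 / n) for n in kept_counts]
    )
    membership = sp.csr_matrix(
        (data, indices, indptr), shape=(len(kept_names), normalized.shape[0])
    )
    scores = np.asarray((membership @ normalized).todense())
    return PathwayScoreMatrix(
        pathway_names=kept_names,
        barcodes=list(barcodes),
        scores=scores,
        n_genes_used=np.array(kept_counts),
        dropped=dropped,
    )


def score_counts(
    counts: CountMatrix,
    gene_sets: GeneSetCollection,
    params: NormalizationParams | None = None,
    min_genes: int = 3,
) -> PathwayScoreMatrix:
    """Convenience wrapper: normalize a CountMatrix and score it."""
    normalized = normalize_counts(counts, params)
    return score_pathways(normalized, counts.genes, counts.barcodes,
                          gene_sets, min_genes=min_genes)


def write_scores(scores: PathwayScoreMatrix, path: str) -> None:
    """Score matrix TSV (pathways x cells, full float precision)."""
    scores.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_scores(path: str) -> PathwayScoreMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return PathwayScoreMatrix(
        pathway_names=[str(p) for p in frame.index],
        barcodes=[str(b) for b in frame.columns],
        scores=frame.to_numpy(dtype=float),
        n_genes_used=np.zeros(len(frame.index), dtype=int),
    )


def write_drop_report(scores: PathwayScoreMatrix, path: str, min_genes: int) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tn_matched\treason\n")
        for name, n_matched in scores.dropped:
            fh.write(f"{name}\t{n_matched}\tfewer than {min_genes} matched genes\n")
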