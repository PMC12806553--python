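"""Degradation protocols stress-testing the classifier.

Two protocols, each yielding an F1-versus-level curve:

* gene retention — per cell, keep a uniform random subset of the detected
  genes and zero the rest, then re-run scoring and prediction; emulates
  shallower sequencing / heavier dropout.
* pathway inactivation — zero a random fraction of standardized pathway
  score rows at prediction time; zeroing (the training mean) removes the
  feature's information, which is what "inactivation" means here, whereas
  shuffling would preserve its marginal distribution.

Also the paired ablation experiment: retrain on only the top-k most
important pathways versus on all pathways but those k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .classifier import (MetricsReport, TrainedModel, TrainingConfig,
                         evaluate, train_model)
from .io_formats import CountMatrix, GeneSetCollection, LabelVector
from .pathway_scoring import score_counts
from .importance import top_pathways

DEFAULT_GENE_LEVELS = (100, 200, 500, 1000, 2000, 5000)
DEFAULT_INACTIVATION_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8)


@dataclass
class RobustnessCurve:
    protocol: str
    levels: list[float]
    f1_mean: list[float]
    f1_sd: list[float]
    n_replicates: int
    seed: int
    replicates: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protocol": self.protocol,
                "level": self.levels,
                "f1_mean": self.f1_mean,
                "f1_sd": self.f1_sd,
                "n_replicates": self.n_replicates,
            }
        )


def retain_genes(counts: CountMatrix, n_retain: int, seed: int = 0) -> CountMatrix:
    """Per cell, keep a uniform random subset of its detected genes.

    Among each cell's nonzero genes, min(n_retain, n_detected) keep their
    counts and the rest are zeroed; the gene and cell axes are unchanged.
    """
    if n_retain < 1:
        raise ValueError("n_retain must be >= 1")
    rng = np.random.default_rng(seed)
    csc = counts.counts.tocsc()
    indptr, indices, data = csc.indptr, csc.indices, csc.data
    keep_mask = np.zeros(data.size, dtype=bool)
    cols = np.zeros(data.size, dtype=np.int64)
    for cell in range(csc.shape[1]):
        lo, hi = indptr[cell], indptr[cell + 1]
        cols[lo:hi] = cell
        n_detected = hi - lo
        if n_detected <= n_retain:
            keep_mask[lo:hi] = True
        elif n_retain > 0:
            chosen = rng.choice(n_detected, size=n_retain, replace=False)
            keep_mask[lo + chosen] = True
    kept = sp.csr_matrix(
        (data[keep_mask], (indices[keep_mask], cols[keep_mask])),
        shape=csc.shape,
    )
    return CountMatrix(genes=list(counts.genes), barcodes=list(counts.barcodes),
                       counts=kept)


def inactivate_pathways(
    standardized_scores: np.ndarray, fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Zero a uniform random floor(fraction * P) of standardized score rows.

    Zero is the training mean on the standardized scale. Returns the
    modified matrix (a copy) and the indices of the inactivated rows.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    n_pathways = standardized_scores.shape[0]
    n_off = int(np.floor(fraction * n_pathways))
    rng = np.random.default_rng(seed)
    off = np.sort(rng.choice(n_pathways, size=n_off, replace=False))
    modified = standardized_scores.copy()
    modified[off] = 0.0
    return modified, off


def robustness_curve(
    model: TrainedModel,
    labels: LabelVector,
    protocol: str,
    levels=None,
    n_replicates: int = 10,
    seed: int = 0,
    counts: CountMatrix | None = None,
    gene_sets: GeneSetCollection | None = None,
    scores=None,
) -> RobustnessCurve:
    """F1 (mean +/- SD over replicates) as a function of degradation level.

    ``gene_retention`` needs the raw counts and gene sets so scores can be
    recomputed after degradation; ``pathway_inactivation`` needs a score
    matrix for the evaluation cells.
    """
    if protocol == "gene_retention":
        if counts is None or gene_sets is None:
            raise ValueError("gene_retention needs counts and gene_sets")
        levels = sorted(levels if levels is not None else DEFAULT_GENE_LEVELS)
        y = labels.aligned_to(counts.barcodes)
    elif protocol == "pathway_inactivation":
        if scores is None:
            raise ValueError("pathway_inactivation needs a score matrix")
        levels = sorted(levels if levels is not None
                        else DEFAULT_INACTIVATION_LEVELS)
        y = labels.aligned_to(scores.barcodes)
        standardized = model.standardize(scores)
    else:
        raise ValueError(f"unknown protocol: {protocol}")

    rows = []
    for level_i, level in enumerate(levels):
        for rep in range(n_replicates):
            rep_seed = np.random.SeedSequence(
                entropy=seed, spawn_key=(level_i, rep)
            ).generate_state(1)[0]
            if protocol == "gene_retention":
                degraded = retain_genes(counts, int(level), seed=rep_seed)
                rep_scores = score_counts(
                    degraded, gene_sets, params=model.normalization,
                    min_genes=1,
                )
                _, calls = model.predict(rep_scores)
            else:
                modified, _ = inactivate_pathways(standardized, float(level),
                                                  seed=rep_seed)
                prob = model.predict_standardized(modified)
                calls = (prob >= model.threshold).astype(int)
            report = evaluate(calls, y)
            rows.append({"protocol": protocol, "level": level, "replicate": rep,
                         "f1": report.f1, "accuracy": report.accuracy,
                         "precision": report.precision, "recall": report.recall})
    frame = pd.DataFrame(rows)
    grouped = frame.groupby("level")["f1"]
    return RobustnessCurve(
        protocol=protocol,
        levels=[float(v) for v in levels],
        f1_mean=grouped.mean().reindex(levels).tolist(),
        f1_sd=grouped.std(ddof=0).reindex(levels).tolist(),
        n_replicates=n_replicates,
        seed=seed,
        replicates=frame,
    )


def top_pathway_ablation(
    train_scores,
    train_labels: LabelVector,
    test_scores,
    test_labels: LabelVector,
    importance_table: pd.DataFrame,
    k: int = 4,
    config: TrainingConfig | None = None,
) -> tuple[MetricsReport, MetricsReport]:
    """Retrain on only the top-k pathways vs on all pathways but those k.

    Returns (top-k-only report, all-but-top-k report) on the test cells.
    """
    n_pathways = len(importance_table)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n_pathways:
        raise ValueError(f"k={k} must be smaller than the {n_pathways} pathways")
    top = top_pathways(importance_table, k)
    rest = [n for n in importance_table["pathway"] if n not in set(top)]

    reports = []
    for names in (top, rest):
        model = train_model(train_scores.subset_pathways(names), train_labels,
                            config=config)
        _, calls = model.predict(test_scores.subset_pathways(names))
        reports.append(
            evaluate(calls, test_labels.aligned_to(test_scores.barcodes))
        )
    return reports[0], reports[1]
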