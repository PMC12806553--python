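"""Select pathways that separate tumor from normal cells.

Two distinct operations, applied at different pipeline stages:

* ``wilcoxon_filter`` — the training-time feature filter: a two-sided
  Wilcoxon rank-sum (Mann-Whitney U) test per pathway, retaining pathways
  with raw p < alpha (no multiplicity correction at this step).
* ``differential_pathways`` — the reporting table: the same rank-sum
  p-values, Benjamini-Hochberg adjusted, with a log2 fold change of mean
  scores (tumor over normal), flagged at |log2FC| > 1 and FDR < 0.05.

For group sizes up to 8 with no ties the p-value is the exact enumeration
value; otherwise the normal approximation with tie and continuity correction
is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import LabelVector
from .pathway_scoring import PathwayScoreMatrix

EXACT_MAX_N = 8
LOG2FC_EPS = 0.01


@dataclass
class PathwayTestResult:
    pathway: str
    statistic: float
    p_value: float
    log2fc: float
    fdr: float
    retained: bool


def rank_sum_test(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of tumor vs normal scores.

    Returns (U statistic for the tumor group, p-value). Exact enumeration for
    small tie-free groups, tie/continuity-corrected normal approximation
    otherwise. Fully degenerate input (all values identical) gets p = 1 by
    convention.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.size < 2 or normal.size < 2:
        raise ValueError("each group needs at least 2 cells")
    combined = np.concatenate([tumor, normal])
    if np.all(combined == combined[0]):
        return tumor.size * normal.size / 2.0, 1.0
    has_ties = np.unique(combined).size < combined.size
    if tumor.size <= EXACT_MAX_N and normal.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(tumor, normal, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Standard step-up FDR adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _split_groups(scores: PathwayScoreMatrix, labels: LabelVector):
    y = labels.aligned_to(scores.barcodes)
    tumor_mask = y == 1
    if tumor_mask.sum() < 2 or (~tumor_mask).sum() < 2:
        raise ValueError("need >= 2 tumor and >= 2 normal cells")
    return scores.scores[:, tumor_mask], scores.scores[:, ~tumor_mask]


def wilcoxon_filter(
    scores: PathwayScoreMatrix, labels: LabelVector, alpha: float = 0.05
) -> list[PathwayTestResult]:
    """Training-time pathway filter: retained = (raw rank-sum p < alpha)."""
    return _test_all(scores, labels, retain_rule=lambda r: r.p_value < alpha)


def differential_pathways(
    scores: PathwayScoreMatrix,
    labels: LabelVector,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> list[PathwayTestResult]:
    """Differential-pathway table: flag |log2FC| > 1 and BH FDR < 0.05."""
    return _test_all(
        scores,
        labels,
        retain_rule=lambda r: abs(r.log2fc) > lfc_threshold
        and r.fdr < fdr_threshold,
    )


def _test_all(scores, labels, retain_rule) -> list[PathwayTestResult]:
    tumor, normal = _split_groups(scores, labels)
    stats_u = np.empty(scores.shape[0])
    pvals = np.empty(scores.shape[0])
    for i in range(scores.shape[0]):
        stats_u[i], pvals[i] = rank_sum_test(tumor[i], normal[i])
    # scores are non-negative means of log1p values; the pseudocount guards
    # unexpressed pathways with a zero mean
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2(
            (tumor.mean(axis=1) + LOG2FC_EPS)
            / (normal.mean(axis=1) + LOG2FC_EPS)
        )
    fdr = benjamini_hochberg(pvals)
    results = []
    for i, name in enumerate(scores.pathway_names):
        r = PathwayTestResult(
            pathway=name,
            statistic=float(stats_u[i]),
            p_value=float(pvals[i]),
            log2fc=float(log2fc[i]),
            fdr=float(fdr[i]),
            retained=False,
        )
        r.retained = bool(retain_rule(r))
        results.append(r)
    return results


def retained_names(results: list[PathwayTestResult]) -> list[str]:
    return [r.pathway for r in results if r.retained]


def results_to_frame(results: list[PathwayTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "log2fc": [r.log2fc for r in results],
            "fdr": [r.fdr for r in results],
            "retained": [r.retained for r in results],
        }
    )


def write_results(results: list[PathwayTestResult], path: str) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False,
                                     float_format="%.17g")
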