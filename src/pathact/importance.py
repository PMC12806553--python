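"""Permutation-based pathway importance.

Each pathway's contribution to the classifier is measured as the increase in
mean binary cross-entropy when that pathway's standardized score row is
shuffled across cells while everything else is held fixed. Shuffling happens
on the standardized scale (post-scaler), so the scaler is not refit per
permutation — the standard permutation-importance contract. Each
(pathway, repeat) draw gets its own seed derived from (seed, pathway index,
repeat), making the table reproducible and order-independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import TrainedModel, _bce_from_logits
from .io_formats import LabelVector
from .pathway_scoring import PathwayScoreMatrix


def permutation_importance(
    model: TrainedModel,
    scores: PathwayScoreMatrix,
    labels: LabelVector,
    n_repeats: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and SD of the loss increase per pathway under column shuffling.

    Returns a DataFrame with columns ``pathway``, ``mean_delta_loss``,
    ``sd_delta_loss``, ``rank`` (1 = most important, ties broken by pathway
    name) and ``n_repeats``, sorted by rank.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = labels.aligned_to(scores.barcodes)
    standardized = model.standardize(scores)
    baseline = _bce_from_logits(model.logits_standardized(standardized), y)

    n_pathways, n_cells = standardized.shape
    mean_delta = np.empty(n_pathways)
    sd_delta = np.empty(n_pathways)
    for p in range(n_pathways):
        original_row = standardized[p].copy()
        deltas = np.empty(n_repeats)
        for r in range(n_repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(p, r))
            )
            standardized[p] = original_row[rng.permutation(n_cells)]
            loss = _bce_from_logits(
                model.logits_standardized(standardized), y
            )
            deltas[r] = loss - baseline
        standardized[p] = original_row
        mean_delta[p] = deltas.mean()
        sd_delta[p] = deltas.std()

    table = pd.DataFrame(
        {
            "pathway": model.pathway_names,
            "mean_delta_loss": mean_delta,
            "sd_delta_loss": sd_delta,
            "n_repeats": n_repeats,
        }
    )
    table = table.sort_values(
        ["mean_delta_loss", "pathway"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, n_pathways + 1)
    return table[["pathway", "mean_delta_loss", "sd_delta_loss", "rank",
                  "n_repeats"]]


def top_pathways(table: pd.DataFrame, k: int) -> list[str]:
    """Names of the k most important pathways (rank 1..k)."""
    return table.nsmallest(k, "rank")["pathway"].tolist()


def write_importance(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
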