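import numpy as np
import pytest
import scipy.sparse as sp

import pathact as pa
import pathact.classifier as clf
from pathact.feature_selection import retained_names, wilcoxon_filter
from pathact.io_formats import CountMatrix, GeneSetCollection, LabelVector
from pathact.synthetic_data import SimulationConfig, generate_dataset

CANONICAL_SEED = 0


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 2 cells with 4 nonzeros; column sums 10 and 5."""
    dense = np.array([[9, 0], [0, 2], [1, 3]])
    return CountMatrix(
        genes=["G1", "G2", "G3"],
        barcodes=["C1", "C2"],
        counts=sp.csr_matrix(dense),
    )


@pytest.fixture
def tiny_gene_sets() -> GeneSetCollection:
    return GeneSetCollection(
        {"P1": {"G1", "G2"}, "P2": {"G2", "G3"}, "P3": {"G1", "G2", "G3"}}
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate synthetic dataset with planted signal, shared across tests."""
    config = SimulationConfig(
        n_tumor=150, n_normal=150, n_genes=1200, n_pathways=30,
        genes_per_pathway=(15, 30), n_up_pathways=3, n_down_pathways=3,
        effect_log2fc=1.2, tumor_library_scale=1.0, seed=CANONICAL_SEED,
    )
    counts, gene_sets, truth = generate_dataset(config)
    scores = pa.score_counts(counts, gene_sets)
    return {"config": config, "counts": counts, "gene_sets": gene_sets,
            "truth": truth, "scores": scores}


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """Classifier trained on the small dataset's 8:2 split."""
    scores = small_dataset["scores"]
    labels = small_dataset["truth"].labels
    train_idx, test_idx = clf.split_data(scores, labels, 0.8,
                                         seed=CANONICAL_SEED)
    train_sc = scores.subset_cells(train_idx)
    test_sc = scores.subset_cells(test_idx)
    model = clf.train_model(
        train_sc, labels,
        config=clf.TrainingConfig(seed=CANONICAL_SEED, max_epochs=60),
    )
    return {"model": model, "train_sc": train_sc, "test_sc": test_sc,
            "labels": labels,
            "y_test": labels.aligned_to(test_sc.barcodes)}


@pytest.fixture(scope="session")
def acceptance_pipeline():
    """Full pipeline on the frozen benchmark dataset (shared by the
    end-to-end accuracy, inactivation-robustness and importance checks)."""
    from pathact.synthetic_data import make_acceptance_dataset

    bundle = make_acceptance_dataset(seed=CANONICAL_SEED)
    scores = pa.score_counts(bundle.counts, bundle.gene_sets)
    labels = bundle.truth.labels
    train_sc = scores.subset_cells(bundle.train_idx)
    test_sc = scores.subset_cells(bundle.test_idx)
    keep = retained_names(wilcoxon_filter(train_sc, labels))
    train_sc = train_sc.subset_pathways(keep)
    test_sc = test_sc.subset_pathways(keep)
    model = clf.train_model(
        train_sc, labels, config=clf.TrainingConfig(seed=CANONICAL_SEED)
    )
    return {"bundle": bundle, "scores": scores, "model": model,
            "train_sc": train_sc, "test_sc": test_sc, "labels": labels,
            "y_test": labels.aligned_to(test_sc.barcodes)}


def make_labels(barcodes, labels) -> LabelVector:
    return LabelVector(barcodes=list(barcodes), labels=np.asarray(labels))
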