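"""Readers and writers for the formats the pipeline touches.

Count matrices arrive either as 10x-style MatrixMarket triplet directories
(``matrix.mtx`` + ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``) or as
dense CSV/TSV tables; gene sets arrive as GMT files. Trained models are
serialized to a single self-describing JSON artifact so that predictions are
bit-reproducible across save/load without framework-specific pickles.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MODEL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def canonical_symbol(symbol: str) -> str:
    """Canonical gene-symbol form used for all matching: uppercased, stripped."""
    return symbol.strip().upper()


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer UMI/read counts.

    ``counts`` is stored sparse (CSR); zero entries are never materialized.
    Gene symbols are canonicalized and unique; barcodes are unique.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if n_genes < 1 or n_cells < 1:
            raise FormatError("count matrix needs at least 1 gene and 1 cell")
        if len(self.genes) != n_genes:
            raise FormatError(
                f"{len(self.genes)} gene symbols for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix columns"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols after canonicalization")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate cell barcodes")
        if self.counts.nnz:
            data = self.counts.data
            if (data < 0).any():
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.barcodes == other.barcodes
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class GeneSetCollection:
    """Ordered mapping of pathway name -> set of canonical gene symbols."""

    pathways: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        canon: dict[str, frozenset[str]] = {}
        for name, genes in self.pathways.items():
            if name in canon:
                raise FormatError(f"duplicate pathway name: {name}")
            genes = frozenset(canonical_symbol(g) for g in genes)
            if not genes:
                raise FormatError(f"pathway {name} has an empty gene set")
            canon[name] = genes
        self.pathways = canon

    @property
    def names(self) -> list[str]:
        return list(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.pathways[name]

    def subset(self, names: list[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: set(self.pathways[n]) for n in names}, source=self.source
        )


@dataclass
class LabelVector:
    """Per-cell ground-truth annotation: tumor = 1, normal = 0."""

    barcodes: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.barcodes) != self.labels.size:
            raise FormatError("barcode / label length mismatch")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise FormatError(f"labels must be 0 (normal) or 1 (tumor); got {bad}")

    def aligned_to(self, barcodes: list[str]) -> np.ndarray:
        """Label array reordered to match a matrix's cell axis."""
        lookup = dict(zip(self.barcodes, self.labels.tolist()))
        missing = [b for b in barcodes if b not in lookup]
        if missing:
            raise FormatError(f"no label for barcodes: {missing[:5]}")
        return np.array([lookup[b] for b in barcodes], dtype=int)


def _open_maybe_gzip(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_file(directory: str, stems: list[str]) -> str:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = os.path.join(directory, stem + suffix)
            if os.path.exists(candidate):
                return candidate
    raise FormatError(
        f"missing file in {directory}: expected one of {stems} (optionally .gz)"
    )


def _read_tsv_column(path: str) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _aggregate_duplicate_genes(
    genes: list[str], counts: sp.spmatrix
) -> tuple[list[str], sp.csr_matrix]:
    """Sum the count rows of duplicate gene symbols, keeping first occurrence."""
    genes = [canonical_symbol(g) for g in genes]
    if len(set(genes)) == len(genes):
        return genes, sp.csr_matrix(counts)
    order: list[str] = []
    index: dict[str, int] = {}
    for g in genes:
        if g not in index:
            index[g] = len(order)
            order.append(g)
    rows = np.array([index[g] for g in genes])
    agg = sp.csr_matrix(
        (np.ones(len(genes)), (rows, np.arange(len(genes)))),
        shape=(len(order), len(genes)),
    )
    return order, sp.csr_matrix(agg @ counts)


def read_10x_mtx(directory_path: str) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet directory into a CountMatrix.

    MatrixMarket 1-based coordinates are converted to the internal 0-based
    convention; duplicate gene symbols have their rows summed.
    """
    mtx_path = _find_file(directory_path, ["matrix.mtx"])
    genes_path = _find_file(directory_path, ["features.tsv", "genes.tsv"])
    barcodes_path = _find_file(directory_path, ["barcodes.tsv"])

    try:
        with _open_maybe_gzip(mtx_path, "rb") as fh:
            counts = scipy.io.mmread(fh)
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    counts = sp.csr_matrix(counts)
    if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
        raise FormatError(f"{mtx_path} contains non-integer values")

    genes = _read_tsv_column(genes_path)
    barcodes = _read_tsv_column(barcodes_path)
    if len(genes) != counts.shape[0]:
        raise FormatError(
            f"{genes_path} lists {len(genes)} genes but {mtx_path} "
            f"declares {counts.shape[0]} rows"
        )
    if len(barcodes) != counts.shape[1]:
        raise FormatError(
            f"{barcodes_path} lists {len(barcodes)} barcodes but {mtx_path} "
            f"declares {counts.shape[1]} columns"
        )
    genes, counts = _aggregate_duplicate_genes(genes, counts)
    return CountMatrix(genes=genes, barcodes=barcodes, counts=counts)


def write_10x_mtx(matrix: CountMatrix, directory_path: str) -> None:
    """Write a CountMatrix as a 10x-style triplet directory (1-based mtx)."""
    os.makedirs(directory_path, exist_ok=True)
    coo = matrix.counts.tocoo()
    with open(os.path.join(directory_path, "matrix.mtx"), "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]} {coo.nnz}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {int(v)}\n")
    with open(os.path.join(directory_path, "features.tsv"), "w") as fh:
        for g in matrix.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(os.path.join(directory_path, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(matrix.barcodes) + "\n")


def read_dense_matrix(path: str, orientation: str = "genes_by_cells") -> CountMatrix:
    """Read a dense CSV/TSV count table.

    ``orientation`` says how the file is laid out; the returned CountMatrix is
    always genes x cells.
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation: {orientation}")
    sep = "," if str(path).endswith((".csv", ".csv.gz")) else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~frame.map(lambda v: isinstance(v, (int, float))).to_numpy())
        row, col = bad[0] if len(bad) else (0, 0)
        raise FormatError(
            f"non-numeric entry at row {frame.index[row]!r}, "
            f"column {frame.columns[col]!r} in {path}"
        )
    if (values < 0).any():
        row, col = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count at row {frame.index[row]!r}, "
            f"column {frame.columns[col]!r} in {path}"
        )
    if orientation == "cells_by_genes":
        frame = frame.T
    genes, counts = _aggregate_duplicate_genes(
        [str(g) for g in frame.index], sp.csr_matrix(frame.to_numpy())
    )
    return CountMatrix(
        genes=genes, barcodes=[str(b) for b in frame.columns], counts=counts
    )


def write_dense_matrix(matrix: CountMatrix, path: str) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(
        matrix.counts.toarray().astype(int),
        index=matrix.genes,
        columns=matrix.barcodes,
    ).to_csv(path, sep=sep)


def read_gmt(path: str, source: str | None = None) -> GeneSetCollection:
    """Parse a GMT gene-set file: name, description, then gene symbols."""
    pathways: dict[str, set[str]] = {}
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name = fields[0]
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            genes = {canonical_symbol(g) for g in fields[2:] if g.strip()}
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
    return GeneSetCollection(pathways, source=source or str(path))


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.pathways.items():
            fh.write("\t".join([name, collection.source or "na", *sorted(genes)]) + "\n")


def read_labels(path: str) -> LabelVector:
    """Read a two-column TSV of (barcode, label) with label in {tumor, normal, 1, 0}."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["barcode", "label"],
                        dtype=str, comment="#")
    if frame["barcode"].iloc[0] == "barcode":  # tolerate a header row
        frame = frame.iloc[1:]
    mapping = {"tumor": 1, "normal": 0, "1": 1, "0": 0}
    try:
        labels = frame["label"].str.strip().str.lower().map(mapping)
    except AttributeError as exc:
        raise FormatError(f"cannot parse labels in {path}") from exc
    if labels.isna().any():
        bad = frame.loc[labels.isna(), "label"].iloc[0]
        raise FormatError(f"unrecognized label {bad!r} in {path}")
    return LabelVector(barcodes=frame["barcode"].tolist(),
                       labels=labels.to_numpy(dtype=int))


def write_labels(labels: LabelVector, path: str) -> None:
    with open(path, "w") as fh:
        for barcode, lab in zip(labels.barcodes, labels.labels):
            fh.write(f"{barcode}\t{'tumor' if lab else 'normal'}\n")


def write_predictions(path: str, barcodes: list[str], probabilities: np.ndarray,
                      calls: np.ndarray) -> None:
    """Predictions TSV: barcode, tumor probability (full precision), call."""
    with open(path, "w") as fh:
        fh.write("barcode\tprobability\tcall\n")
        for barcode, prob, call in zip(barcodes, probabilities, calls):
            fh.write(f"{barcode}\t{float(prob)!r}\t{'tumor' if call else 'normal'}\n")


def save_model(model, path: str) -> None:
    """Serialize a TrainedModel to a self-describing JSON artifact."""
    payload = model.to_dict()
    payload["format_version"] = MODEL_FORMAT_VERSION
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str):
    """Load a TrainedModel saved by :func:`save_model`."""
    from .classifier import TrainedModel

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"truncated or corrupt model file {path}: {exc}") from exc
    version = payload.pop("format_version", None)
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"unsupported model format version {version!r} in {path} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    return TrainedModel.from_dict(payload)
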