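"""Plain-text readers/writers for the formats the pipeline exchanges.

Count matrices and sample sheets travel as TSV; single-cell UMI matrices as
a MatrixMarket triplet (``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``)
with a cell-metadata TSV alongside.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from sexbias.datatypes import CountMatrix, validate_sample_table


def read_counts(path, annotation_path=None) -> CountMatrix:
    """Read a features-as-rows count TSV (first column = feature ID)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    annotation = None
    if annotation_path is not None:
        annotation = read_annotation(annotation_path)
    return CountMatrix(counts, annotation)


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature_id")


def read_annotation(path) -> pd.DataFrame:
    """Feature annotation TSV: feature_id, chromosome, biotype."""
    annot = pd.read_csv(path, sep="\t", index_col=0)
    return annot


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index_label="feature_id")


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    return validate_sample_table(samples)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def write_mtx_triplet(matrix: sp.spmatrix, genes, barcodes, outdir) -> None:
    """Write genes x cells sparse counts as an uncompressed MTX triplet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(matrix))
    pd.Series(list(genes)).to_csv(outdir / "features.tsv", sep="\t",
                                  index=False, header=False)
    pd.Series(list(barcodes)).to_csv(outdir / "barcodes.tsv", sep="\t",
                                     index=False, header=False)


def read_mtx_triplet(indir) -> tuple[sp.csr_matrix, list, list]:
    """Read an MTX triplet; returns (genes x cells CSR, genes, barcodes)."""
    indir = Path(indir)
    matrix = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    if matrix.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {matrix.shape} inconsistent with "
            f"{len(genes)} features / {len(barcodes)} barcodes"
        )
    return matrix, genes, barcodes
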