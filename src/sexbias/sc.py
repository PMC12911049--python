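"""Single-cell QC, log-normalization, and per-cell-type sex-biased DE.

Cell-type labels arrive as an input column of the cell metadata; clustering
and annotation are upstream of this module.  DE on the prioritized gene
panel is a Wilcoxon rank-sum test of male vs female cells within each type,
with BH correction per cell type across the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from sexbias.de import bh_adjust

#: Default QC thresholds: keep cells with mito <= 10%, UMI >= 1000,
#: and detected features in [300, 6000].
QC_DEFAULTS = {"max_mito": 0.10, "min_umi": 1000,
               "min_features": 300, "max_features": 6000}

SC_DE_COLUMNS = ["cell_type", "gene", "n_male", "n_female",
                 "log2fc", "p", "padj", "significant"]


@dataclass
class CellMatrix:
    """Sparse genes x cells UMI matrix with per-cell metadata.

    ``cell_meta`` is indexed by barcode and carries at least ``sample_id``,
    ``sex``, ``cell_type``; QC metric columns (``n_umi``, ``n_features``,
    ``mito_fraction``) are computed from the matrix when absent.
    """

    umi: sp.csr_matrix
    genes: list
    barcodes: list
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.umi = sp.csr_matrix(self.umi)
        if self.umi.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("matrix shape inconsistent with genes/barcodes")
        if list(self.cell_meta.index) != list(self.barcodes):
            self.cell_meta = self.cell_meta.loc[list(self.barcodes)]
        if (self.umi.data < 0).any():
            raise ValueError("UMI counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask, dtype=bool)
        barcodes = [b for b, m in zip(self.barcodes, mask) if m]
        return CellMatrix(self.umi[:, mask], self.genes, barcodes,
                          self.cell_meta.loc[barcodes])


def compute_cell_metrics(cells: CellMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Fill n_umi / n_features / mito_fraction from the matrix if missing."""
    meta = cells.cell_meta.copy()
    csc = cells.umi.tocsc()
    if "n_umi" not in meta.columns:
        meta["n_umi"] = np.asarray(csc.sum(axis=0)).ravel()
    if "n_features" not in meta.columns:
        meta["n_features"] = csc.getnnz(axis=0)
    if "mito_fraction" not in meta.columns:
        mito = np.array([g.startswith(mito_prefix) for g in cells.genes])
        totals = np.asarray(csc.sum(axis=0)).ravel()
        mito_counts = np.asarray(csc[mito].sum(axis=0)).ravel() if mito.any() \
            else np.zeros(cells.n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        meta["mito_fraction"] = frac
    return meta


def qc_filter(
    cells: CellMatrix,
    max_mito: float = QC_DEFAULTS["max_mito"],
    min_umi: int = QC_DEFAULTS["min_umi"],
    min_features: int = QC_DEFAULTS["min_features"],
    max_features: int = QC_DEFAULTS["max_features"],
    mito_prefix: str = "MT-",
) -> CellMatrix:
    """Drop cells violating any QC threshold.

    A cell is removed when mito_fraction > ``max_mito``, n_umi < ``min_umi``,
    or n_features < ``min_features`` or > ``max_features``.  Idempotent.
    """
    meta = compute_cell_metrics(cells, mito_prefix=mito_prefix)
    bad = (
        (meta["mito_fraction"] > max_mito)
        | (meta["n_umi"] < min_umi)
        | (meta["n_features"] < min_features)
        | (meta["n_features"] > max_features)
    ).to_numpy(dtype=bool)
    kept = cells.subset_cells(~bad)
    kept.cell_meta = meta.loc[kept.barcodes]
    return kept


def log_normalize(cells: CellMatrix, scale: float = 1e4) -> pd.DataFrame:
    """Per-cell depth normalization: ln(1 + count / cell_total * scale).

    Returns a dense genes x cells DataFrame (intended for panel-sized gene
    sets; subset first for large matrices).
    """
    totals = np.asarray(cells.umi.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("cells with zero total UMI cannot be normalized")
    dense = np.asarray(cells.umi.todense(), dtype=float)
    return pd.DataFrame(np.log1p(dense / totals * scale),
                        index=cells.genes, columns=cells.barcodes)


def per_celltype_sex_de(
    cells: CellMatrix,
    panel,
    alpha: float = 0.05,
    lfc: float = 0.58,
    min_cells: int = 10,
    scale: float = 1e4,
) -> pd.DataFrame:
    """Wilcoxon rank-sum male-vs-female DE per cell type on a gene panel.

    log2FC is computed from mean de-logged normalized expression with a +1
    pseudocount, positive = higher in males.  BH correction is applied within each cell
    type across the panel.  Cell types with fewer than ``min_cells`` cells
    of either sex are skipped with a warning.
    """
    panel = [g for g in panel if g in cells.genes]
    if not panel:
        raise ValueError("no panel gene present in the matrix")
    gene_idx = {g: i for i, g in enumerate(cells.genes)}
    sub = CellMatrix(cells.umi, cells.genes, cells.barcodes, cells.cell_meta)
    norm = log_normalize(sub, scale=scale).loc[panel]
    meta = cells.cell_meta
    rows = []
    for ct in sorted(meta["cell_type"].dropna().unique()):
        in_type = meta["cell_type"] == ct
        male = (in_type & (meta["sex"] == "male")).to_numpy(dtype=bool)
        female = (in_type & (meta["sex"] == "female")).to_numpy(dtype=bool)
        if male.sum() < min_cells or female.sum() < min_cells:
            warnings.warn(
                f"cell type {ct!r} has < {min_cells} cells in one sex; skipped",
                stacklevel=2,
            )
            continue
        pvals = []
        for gene in panel:
            xm = norm.iloc[:, male].loc[gene].to_numpy()
            xf = norm.iloc[:, female].loc[gene].to_numpy()
            if np.all(xm == xm[0]) and np.all(xf == xf[0]) and xm[0] == xf[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(xm, xf, alternative="two-sided").pvalue)
            # fold change on the de-logged normalized scale, +1 pseudocount
            mean_m = np.expm1(xm).mean()
            mean_f = np.expm1(xf).mean()
            rows.append({
                "cell_type": ct, "gene": gene,
                "n_male": int(male.sum()), "n_female": int(female.sum()),
                "log2fc": float(np.log2((mean_m + 1.0) / (mean_f + 1.0))),
                "p": p,
            })
            pvals.append(p)
    result = pd.DataFrame(rows, columns=["cell_type", "gene", "n_male",
                                         "n_female", "log2fc", "p"])
    if result.empty:
        result["padj"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["padj"] = np.nan
    for ct in result["cell_type"].unique():
        mask = result["cell_type"] == ct
        result.loc[mask, "padj"] = bh_adjust(result.loc[mask, "p"])
    result["significant"] = (result["padj"] < alpha) & (result["log2fc"].abs() > lfc)
    return result[SC_DE_COLUMNS]


def dotplot_data(cells: CellMatrix, panel, scale: float = 1e4) -> pd.DataFrame:
    """Fraction-expressing and mean expression per (gene, cell type, sex)."""
    panel = [g for g in panel if g in cells.genes]
    norm = log_normalize(cells, scale=scale).loc[panel]
    meta = cells.cell_meta
    rows = []
    for ct in sorted(meta["cell_type"].dropna().unique()):
        for sex in ("male", "female"):
            mask = ((meta["cell_type"] == ct) & (meta["sex"] == sex)).to_numpy(bool)
            if mask.sum() == 0:
                continue
            block = norm.iloc[:, mask]
            for gene in panel:
                vals = block.loc[gene].to_numpy()
                rows.append({
                    "gene": gene, "cell_type": ct, "sex": sex,
                    "n_cells": int(mask.sum()),
                    "frac_expressing": float((vals > 0).mean()),
                    "mean_expression": float(vals.mean()),
                })
    return pd.DataFrame(rows)
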