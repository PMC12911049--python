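"""Bulk sex-differential expression on raw counts.

The engine is a per-feature negative-binomial log-linear GLM fit by IRLS
with a log size-factor offset (median-of-ratios normalization), a Wald test
on the sex coefficient, and Benjamini-Hochberg correction.  Dispersions are
estimated per feature by method of moments on normalized counts, optionally
shrunk toward a mean-dispersion trend.

The contrast convention is male vs female: positive log2 fold change means
higher expression in males.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from sexbias.datatypes import CountMatrix

DISPERSION_FLOOR = 1e-8
#: Default significance thresholds: padj < ALPHA and |log2FC| > LFC (strict).
ALPHA = 0.05
LFC = 0.58

DE_COLUMNS = [
    "base_mean", "log2fc", "se", "wald_stat", "p", "padj",
    "significant", "direction", "converged",
]


# ---------------------------------------------------------------------------
# filtering / normalization
# ---------------------------------------------------------------------------

def filter_low_expression(
    counts: CountMatrix, min_count: int = 10, min_fraction: float = 0.2
) -> CountMatrix:
    """Keep features with counts >= ``min_count`` in >= ``min_fraction`` of samples."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    frac = (counts.counts.to_numpy() >= min_count).mean(axis=1)
    keep = counts.feature_ids[frac >= min_fraction]
    if len(keep) == 0:
        warnings.warn("low-expression filter removed every feature", stacklevel=2)
    return counts.subset_features(keep)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample, the median over features expressed in every sample of
    count / geometric-mean-across-samples.  Errors if no feature is
    expressed in all samples.
    """
    mat = counts.counts.to_numpy(dtype=float)
    expressed_everywhere = (mat > 0).all(axis=1)
    if not expressed_everywhere.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "apply a stricter low-expression filter first"
        )
    ref = mat[expressed_everywhere]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family and returned as NaN; input
    order is preserved.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    out[mask] = adjusted
    return out


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    normalized: np.ndarray, shrink: bool = True
) -> np.ndarray:
    """Per-feature NB dispersion by method of moments on normalized counts.

    ``alpha = max((var - mean) / mean^2, floor)`` per feature.  With
    ``shrink=True`` the raw estimates are pulled toward a ``a1/mean + a0``
    trend fitted across features (log-space midpoint), which stabilizes the
    noisy per-feature moments without replicating DESeq2's empirical Bayes
    machinery.
    """
    mean = normalized.mean(axis=1)
    var = normalized.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mean) / mean**2
    raw = np.where(np.isfinite(raw), raw, DISPERSION_FLOOR)
    raw = np.maximum(raw, DISPERSION_FLOOR)
    if not shrink or raw.size < 10:
        return raw
    # robust trend fit: regress raw dispersion on 1/mean, clipping negatives
    ok = mean > 0
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(x, raw[ok], rcond=None)
    a0, a1 = max(coef[0], DISPERSION_FLOOR), max(coef[1], 0.0)
    trend = np.full_like(raw, DISPERSION_FLOOR)
    trend[ok] = np.maximum(a0 + a1 / mean[ok], DISPERSION_FLOOR)
    return np.exp(0.5 * (np.log(raw) + np.log(trend)))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def design_matrix(
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    reference_sex: str = "female",
) -> pd.DataFrame:
    """Build the GLM design: intercept, sex indicator, then covariates.

    Sex is coded 1 for the non-reference level (default: male = 1, so the
    sex coefficient is the male-vs-female log fold change).  Stage/grade
    are encoded as ordered integers; age passes through numerically.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    covariates = covariates or []
    cols = {"intercept": np.ones(len(samples))}
    cols["sex"] = (samples["sex"] != reference_sex).astype(float).to_numpy()
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate '{cov}' not in sample sheet")
        col = samples[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            col = col.map({lv: i for i, lv in enumerate(levels)})
        cols[cov] = pd.to_numeric(col).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=samples.index)
    mat = X.to_numpy()
    if np.isnan(mat).any():
        bad = X.columns[np.isnan(mat).any(axis=0)].tolist()
        raise ValueError(f"design contains missing values in columns {bad}")
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError(
            f"design matrix is not full rank; collinear columns: "
            f"{_collinear_columns(X)}"
        )
    return X


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    names = []
    mat = X.to_numpy()
    for j, name in enumerate(X.columns):
        others = np.delete(mat, j, axis=1)
        fit, *_ = np.linalg.lstsq(others, mat[:, j], rcond=None)
        if np.allclose(others @ fit, mat[:, j], atol=1e-8):
            names.append(name)
    return names


# ---------------------------------------------------------------------------
# the NB GLM Wald engine
# ---------------------------------------------------------------------------

def _irls_nb(y, X, offset, disp, max_iter=60, tol=1e-10):
    """Fit an NB2 log-link GLM with fixed dispersion by Fisher-scoring IRLS.

    Returns (beta, cov, converged).  Weights are the NB2 Fisher weights
    mu / (1 + disp * mu); with disp -> 0 this reduces to the Poisson GLM.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    eta = offset + X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    converged = False
    xtwx = None
    for _ in range(max_iter):
        w = mu / (1.0 + disp * mu)
        z = (eta - offset) + (y - mu) / mu
        xw = X * w[:, None]
        xtwx = xw.T @ X
        try:
            beta_new = np.linalg.solve(xtwx, xw.T @ z)
        except np.linalg.LinAlgError:
            return beta, None, False
        step = beta_new - beta
        beta = beta_new
        eta = offset + X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    if xtwx is None:
        return beta, None, False
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        return beta, None, False
    return beta, cov, converged


def nb_wald(
    counts: CountMatrix,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    reference_sex: str = "female",
    shrink_dispersion: bool = True,
    dispersions: np.ndarray | None = None,
    alpha: float = ALPHA,
    lfc: float = LFC,
) -> pd.DataFrame:
    """Per-feature NB Wald test of sex (non-reference vs reference).

    Returns a DataFrame indexed by feature with ``base_mean``, ``log2fc``
    (and its standard error ``se``, both in log2 units), ``wald_stat``,
    two-sided normal ``p``, BH ``padj``, a significance call at the strict
    padj < alpha and \\|log2fc\\| > lfc thresholds, and ``direction``.

    Features whose IRLS fit fails to converge get ``p = NaN`` and are
    excluded from the BH family.
    """
    if not counts.sample_ids.equals(samples.index):
        samples = samples.loc[counts.sample_ids]
    X_df = design_matrix(samples, covariates, reference_sex=reference_sex)
    X = X_df.to_numpy()
    sex_idx = list(X_df.columns).index("sex")

    sf = size_factors(counts).to_numpy()
    offset = np.log(sf)
    mat = counts.counts.to_numpy(dtype=float)
    normalized = mat / sf
    if dispersions is None:
        dispersions = estimate_dispersions(normalized, shrink=shrink_dispersion)
    else:
        dispersions = np.maximum(
            np.atleast_1d(np.asarray(dispersions, float)), DISPERSION_FLOOR)
        if dispersions.size == 1:
            dispersions = np.full(mat.shape[0], dispersions[0])

    n_features = mat.shape[0]
    log2fc = np.full(n_features, np.nan)
    se = np.full(n_features, np.nan)
    wald = np.full(n_features, np.nan)
    pvals = np.full(n_features, np.nan)
    conv = np.zeros(n_features, dtype=bool)
    ln2 = np.log(2.0)
    for i in range(n_features):
        beta, cov, ok = _irls_nb(mat[i], X, offset, dispersions[i])
        if not ok or cov is None or cov[sex_idx, sex_idx] <= 0:
            continue
        conv[i] = True
        b = beta[sex_idx]
        s = np.sqrt(cov[sex_idx, sex_idx])
        log2fc[i] = b / ln2
        se[i] = s / ln2
        wald[i] = b / s
        pvals[i] = 2.0 * stats.norm.sf(abs(wald[i]))
    if not conv.all():
        warnings.warn(
            f"{(~conv).sum()} feature(s) failed IRLS convergence; "
            "excluded from the BH family",
            stacklevel=2,
        )
    res = pd.DataFrame(
        {
            "base_mean": normalized.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "wald_stat": wald,
            "p": pvals,
            "padj": bh_adjust(pvals),
            "converged": conv,
        },
        index=counts.feature_ids,
    )
    res.index.name = "feature"
    return call_significance(res, alpha=alpha, lfc=lfc)


def call_significance(res: pd.DataFrame, alpha: float = ALPHA, lfc: float = LFC) -> pd.DataFrame:
    """Attach significance calls: padj < alpha AND |log2fc| > lfc (strict)."""
    res = res.copy()
    sig = (res["padj"] < alpha) & (res["log2fc"].abs() > lfc)
    sig = sig.fillna(False)
    res["significant"] = sig.astype(bool)
    direction = np.where(
        ~res["significant"], "none",
        np.where(res["log2fc"] > 0, "male_biased", "female_biased"),
    )
    res["direction"] = direction
    return res


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def pca_qc(counts: CountMatrix, n_components: int = 2):
    """Sample PCA of the centered log2(normalized + 1) matrix.

    Returns (scores DataFrame samples x components, variance-fraction array).
    """
    if counts.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    sf = size_factors(counts).to_numpy()
    logmat = np.log2(counts.counts.to_numpy(dtype=float) / sf + 1.0)
    centered = logmat - logmat.mean(axis=1, keepdims=True)
    # samples are observations: SVD of the samples x features matrix
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    n_components = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components],
        index=counts.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    total = (s**2).sum()
    var_frac = (s**2) / total if total > 0 else np.zeros_like(s)
    return scores, var_frac[:n_components]
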