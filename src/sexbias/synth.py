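"""Seeded synthetic cohorts with planted ground truth.

Three generators share one integer seed through independent substreams
(adding a generator never perturbs the others' output):

- :func:`generate_bulk` — NB-distributed mRNA/miRNA counts with planted
  sex-biased features per tissue and planted miRNA-mediated repression.
- :func:`generate_survival` — exponential event times whose log-hazard
  depends on selected features within one sex stratum, with independent
  exponential censoring.
- :func:`generate_sc` — a small multi-cell-type UMI matrix with planted
  per-cell-type sex effects and a configurable fraction of QC-violating
  cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sexbias.datatypes import CountMatrix

_BULK, _SURVIVAL, _SC, _INTERACTIONS = 0, 1, 2, 3  # substream indices


@dataclass
class CohortConfig:
    """Knobs for the synthetic cohort; defaults give a quick desk-scale run."""

    n_male_tumor: int = 60
    n_female_tumor: int = 60
    n_male_normal: int = 10
    n_female_normal: int = 9
    n_genes: int = 200
    n_mirnas: int = 50
    frac_sex_biased_tumor: float = 0.10
    frac_sex_biased_normal: float = 0.05
    effect_log2fc: float = 1.5
    nb_dispersion: float = 0.1
    n_planted_pairs: int = 10
    repression_strength: float = -1.0
    baseline_hazard: float = 0.002
    survival_beta: float = 0.8
    censor_rate: float = 0.001
    seed: int = 0
    # shape of the baseline expression / depth distributions
    gene_log_mean: float = float(np.log(100.0))
    mirna_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.0
    depth_log_sd: float = 0.3
    # chromosome label proportions (autosomes, X, Y)
    chrom_props: tuple = (0.90, 0.07, 0.03)
    # sex-confounded covariates (off: covariates independent of sex)
    confound_covariates: bool = False
    # survival plumbing
    n_risk_features: int = 3
    risk_sex: str = "male"
    # single-cell plumbing
    sc_n_genes: int = 800
    sc_n_cells: int = 600
    sc_n_mito_genes: int = 5
    sc_cell_types: tuple = ("epithelial", "T_cell", "fibroblast")
    sc_male_samples: int = 4
    sc_female_samples: int = 2
    sc_mean_depth: float = 3000.0
    sc_qc_fail_frac: float = 0.10
    sc_panel_size: int = 10
    sc_effect_log2fc: float = 1.0
    sc_biased_cell_type: str = "epithelial"

    def __post_init__(self) -> None:
        for name in ("n_male_tumor", "n_female_tumor", "n_male_normal",
                     "n_female_normal", "n_genes", "n_mirnas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (zero-size cohort)")
        for name in ("frac_sex_biased_tumor", "frac_sex_biased_normal",
                     "sc_qc_fail_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.repression_strength > 0:
            raise ValueError("repression_strength must be <= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.n_planted_pairs > min(self.n_genes, self.n_mirnas):
            raise ValueError("n_planted_pairs exceeds available features")

    def rng(self, substream: int) -> np.random.Generator:
        # SeedSequence children depend only on their index, so spawning more
        # substreams later never perturbs existing generators
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[substream])


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    sex_biased: pd.DataFrame      # feature, assay, tissue, log2fc
    planted_pairs: pd.DataFrame   # mirna, gene, repression_strength
    risk_features: pd.DataFrame   # feature, stratum, beta
    chromosome_map: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def biased_features(self, assay: str, tissue: str) -> pd.DataFrame:
        t = self.sex_biased
        return t[(t["assay"] == assay) & (t["tissue"] == tissue)]


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB(mean, var = mean + dispersion * mean^2) via gamma-Poisson mixing."""
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean * dispersion))


def _chromosomes(rng, n, props):
    kind = rng.choice(3, size=n, p=props)
    autos = rng.integers(1, 23, size=n)
    return np.where(kind == 0, [f"chr{a}" for a in autos],
                    np.where(kind == 1, "chrX", "chrY"))


def generate_bulk(config: CohortConfig):
    """Simulate bulk mRNA + miRNA counts, a sample sheet, and ground truth.

    Counts are NB with mean = depth x baseline x 2^(sex_effect) (sex effects
    only in the designated tissue); for each planted pair the target gene's
    log-mean is shifted by repression_strength x the standardized log
    abundance of its miRNA in the same sample.
    """
    rng = config.rng(_BULK)

    groups = [
        ("male", "tumor", config.n_male_tumor),
        ("female", "tumor", config.n_female_tumor),
        ("male", "normal", config.n_male_normal),
        ("female", "normal", config.n_female_normal),
    ]
    rows = []
    for sex, tissue, n in groups:
        for i in range(n):
            rows.append({
                "sample_id": f"{tissue[0].upper()}{sex[0].upper()}{i + 1:04d}",
                "sex": sex, "tissue": tissue,
            })
    samples = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(samples)
    is_male = (samples["sex"] == "male").to_numpy()
    is_tumor = (samples["tissue"] == "tumor").to_numpy()
    samples["age"] = np.round(
        np.clip(rng.normal(65 + (3 if config.confound_covariates else 0) * is_male,
                           10), 30, 95)).astype(int)
    samples["stage"] = rng.integers(1, 5, size=n_samples)
    samples["grade"] = rng.integers(1, 4, size=n_samples)
    samples["os_time"] = np.nan
    samples["os_status"] = np.nan

    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    mirna_ids = [f"miR-{i + 1:04d}" for i in range(config.n_mirnas)]

    gene_chrom = _chromosomes(rng, config.n_genes, config.chrom_props)
    mirna_chrom = _chromosomes(rng, config.n_mirnas, config.chrom_props)

    gene_base = np.exp(rng.normal(config.gene_log_mean, config.baseline_log_sd,
                                  config.n_genes))
    mirna_base = np.exp(rng.normal(config.mirna_log_mean, config.baseline_log_sd,
                                   config.n_mirnas))
    gene_depth = np.exp(rng.normal(0.0, config.depth_log_sd, n_samples))
    mirna_depth = np.exp(rng.normal(0.0, config.depth_log_sd, n_samples))

    def plant_effects(n_features, frac_tumor, frac_normal):
        """Per-feature planted log2FC per tissue (0 = unbiased)."""
        lfc = {"tumor": np.zeros(n_features), "normal": np.zeros(n_features)}
        for tissue, frac in (("tumor", frac_tumor), ("normal", frac_normal)):
            k = int(round(frac * n_features))
            idx = rng.choice(n_features, size=k, replace=False)
            signs = rng.choice([-1.0, 1.0], size=k)
            lfc[tissue][idx] = signs * config.effect_log2fc
        return lfc

    gene_lfc = plant_effects(config.n_genes, config.frac_sex_biased_tumor,
                             config.frac_sex_biased_normal)
    mirna_lfc = plant_effects(config.n_mirnas, config.frac_sex_biased_tumor,
                              config.frac_sex_biased_normal)

    def mean_matrix(base, depth, lfc):
        tissue_lfc = np.where(is_tumor[None, :], lfc["tumor"][:, None],
                              lfc["normal"][:, None])
        log2_shift = tissue_lfc * is_male[None, :]
        return depth[None, :] * base[:, None] * np.exp2(log2_shift)

    mirna_mean = mean_matrix(mirna_base, mirna_depth, mirna_lfc)
    mirna_counts = _nb_draws(rng, mirna_mean, config.nb_dispersion)

    # planted repression: shift target genes' log-mean by the standardized
    # log-abundance of the paired miRNA
    pair_mirna_idx = rng.choice(config.n_mirnas, size=config.n_planted_pairs,
                                replace=False)
    pair_gene_idx = rng.choice(config.n_genes, size=config.n_planted_pairs,
                               replace=False)
    gene_mean = mean_matrix(gene_base, gene_depth, gene_lfc)
    log_abund = np.log1p(mirna_counts / mirna_depth[None, :])
    for mi, gi in zip(pair_mirna_idx, pair_gene_idx):
        z = log_abund[mi]
        sd = z.std()
        z = (z - z.mean()) / (sd if sd > 0 else 1.0)
        gene_mean[gi] *= np.exp(config.repression_strength * z)
    gene_counts = _nb_draws(rng, gene_mean, config.nb_dispersion)

    mrna = CountMatrix(
        pd.DataFrame(gene_counts, index=gene_ids, columns=samples.index),
        pd.DataFrame({"chromosome": gene_chrom, "biotype": "protein_coding"},
                     index=gene_ids),
    )
    mirna = CountMatrix(
        pd.DataFrame(mirna_counts, index=mirna_ids, columns=samples.index),
        pd.DataFrame({"chromosome": mirna_chrom, "biotype": "miRNA"},
                     index=mirna_ids),
    )

    biased_rows = []
    for assay, ids, lfc in (("mrna", gene_ids, gene_lfc),
                            ("mirna", mirna_ids, mirna_lfc)):
        for tissue in ("tumor", "normal"):
            for i in np.flatnonzero(lfc[tissue]):
                biased_rows.append({"feature": ids[i], "assay": assay,
                                    "tissue": tissue,
                                    "log2fc": lfc[tissue][i]})
    planted_pairs = pd.DataFrame({
        "mirna": [mirna_ids[i] for i in pair_mirna_idx],
        "gene": [gene_ids[i] for i in pair_gene_idx],
        "repression_strength": config.repression_strength,
    })
    risk_idx = rng.choice(config.n_genes, size=config.n_risk_features,
                          replace=False)
    risk = pd.DataFrame({
        "feature": [gene_ids[i] for i in risk_idx],
        "stratum": config.risk_sex,
        "beta": config.survival_beta,
    })
    truth = GroundTruth(
        sex_biased=pd.DataFrame(
            biased_rows, columns=["feature", "assay", "tissue", "log2fc"]),
        planted_pairs=planted_pairs,
        risk_features=risk,
        chromosome_map=pd.concat([
            pd.Series(gene_chrom, index=gene_ids),
            pd.Series(mirna_chrom, index=mirna_ids),
        ]),
    )
    return mrna, mirna, samples, truth


def generate_survival(
    samples: pd.DataFrame,
    expression: CountMatrix,
    truth: GroundTruth,
    config: CohortConfig,
) -> pd.DataFrame:
    """Fill os_time / os_status from a sex-specific proportional-hazards model.

    Event times are exponential with log-hazard = log(baseline_hazard) +
    sum of beta x standardized log1p-expression, each beta active only
    within its designated sex stratum; censoring is independent exponential
    at ``censor_rate`` (0 disables censoring).
    """
    if config.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    missing = [f for f in truth.risk_features["feature"]
               if f not in expression.feature_ids]
    if missing:
        raise ValueError(f"risk features absent from expression: {missing}")
    rng = config.rng(_SURVIVAL)
    samples = samples.copy()
    ids = [s for s in samples.index if s in expression.sample_ids]
    expr = np.log1p(expression.counts[ids].to_numpy(dtype=float))
    feat_pos = {f: i for i, f in enumerate(expression.feature_ids)}
    linpred = np.zeros(len(ids))
    sex = samples.loc[ids, "sex"].to_numpy()
    for _, rf in truth.risk_features.iterrows():
        z = expr[feat_pos[rf["feature"]]]
        sd = z.std()
        z = (z - z.mean()) / (sd if sd > 0 else 1.0)
        linpred += rf["beta"] * z * (sex == rf["stratum"])
    rate = config.baseline_hazard * np.exp(linpred)
    event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, size=len(ids))
    else:
        censor = np.full(len(ids), np.inf)
    os_time = np.minimum(event, censor)
    samples.loc[ids, "os_time"] = np.round(os_time, 3)
    samples.loc[ids, "os_status"] = (event <= censor).astype(int)
    return samples


def generate_sc(config: CohortConfig):
    """Simulate a UMI matrix with planted per-cell-type sex effects.

    Returns a :class:`sexbias.sc.CellMatrix` and a ground-truth table of
    planted (gene, cell_type, log2fc) effects.  A ``sc_qc_fail_frac``
    fraction of cells is planted to violate one QC rule each (high
    mitochondrial fraction, low UMI depth, or low detected-feature count),
    recorded in the metadata column ``planted_violation``.
    """
    from sexbias.sc import CellMatrix

    rng = config.rng(_SC)
    n_genes = config.sc_n_genes
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    genes += [f"MT-{i + 1}" for i in range(config.sc_n_mito_genes)]
    mito_mask = np.array([g.startswith("MT-") for g in genes])
    n_total = len(genes)

    sample_ids = ([f"SCM{i + 1}" for i in range(config.sc_male_samples)]
                  + [f"SCF{i + 1}" for i in range(config.sc_female_samples)])
    sample_sex = (["male"] * config.sc_male_samples
                  + ["female"] * config.sc_female_samples)

    n_cells = config.sc_n_cells
    cell_sample = rng.integers(0, len(sample_ids), size=n_cells)
    cell_type = rng.choice(list(config.sc_cell_types), size=n_cells)
    sex = np.array([sample_sex[i] for i in cell_sample])

    base_weight = np.exp(rng.normal(0.0, 1.0, n_total))
    base_weight[mito_mask] = base_weight[mito_mask] / base_weight[mito_mask].sum() \
        * 0.03 * base_weight[~mito_mask].sum() / 0.97

    panel = genes[: config.sc_panel_size]
    panel_idx = np.arange(config.sc_panel_size)
    panel_sign = rng.choice([-1.0, 1.0], size=config.sc_panel_size)

    n_fail = int(round(config.sc_qc_fail_frac * n_cells))
    fail_idx = rng.choice(n_cells, size=n_fail, replace=False)
    violation = np.array([""] * n_cells, dtype=object)
    violation[fail_idx] = rng.choice(["high_mito", "low_umi", "low_features"],
                                     size=n_fail)

    depth = np.exp(rng.normal(np.log(config.sc_mean_depth), 0.25, n_cells))
    depth[violation == "low_umi"] = rng.uniform(200, 900,
                                                (violation == "low_umi").sum())
    depth = np.maximum(depth.astype(int), 50)

    cols = []
    for c in range(n_cells):
        w = base_weight.copy()
        if (cell_type[c] == config.sc_biased_cell_type) and sex[c] == "male":
            w[panel_idx] *= np.exp2(panel_sign * config.sc_effect_log2fc)
        if violation[c] == "high_mito":
            target = rng.uniform(0.12, 0.30)
            w[mito_mask] *= target / max(w[mito_mask].sum() / w.sum(), 1e-9) * 1.0
        if violation[c] == "low_features":
            keep = rng.choice(np.flatnonzero(~mito_mask), size=100, replace=False)
            mask = np.zeros(n_total, dtype=bool)
            mask[keep] = True
            w = np.where(mask, w, 0.0)
        p = w / w.sum()
        cols.append(sp.csc_matrix(rng.multinomial(depth[c], p)[:, None]))
    umi = sp.hstack(cols).tocsr()

    barcodes = [f"CELL{c + 1:05d}" for c in range(n_cells)]
    meta = pd.DataFrame({
        "sample_id": [sample_ids[i] for i in cell_sample],
        "sex": sex,
        "cell_type": cell_type,
        "planted_violation": violation,
    }, index=barcodes)
    truth = pd.DataFrame({
        "gene": panel,
        "cell_type": config.sc_biased_cell_type,
        "log2fc": panel_sign * config.sc_effect_log2fc,
    })
    return CellMatrix(umi, genes, barcodes, meta), truth


def make_de_fixture(
    n_tumor: int,
    n_normal: int,
    n_shared: int,
    n_concordant: int,
    prefix: str = "F",
    lfc: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor/normal DE tables with a prescribed overlap structure.

    Builds significant-feature tables with ``n_tumor`` and ``n_normal``
    features sharing exactly ``n_shared`` of them, of which
    ``n_concordant`` agree in fold-change sign and the rest are reversed.
    Useful for worked-example cardinality checks.
    """
    if n_shared > min(n_tumor, n_normal) or n_concordant > n_shared:
        raise ValueError("inconsistent overlap cardinalities")
    shared = [f"{prefix}S{i}" for i in range(n_shared)]
    tumor_only = [f"{prefix}T{i}" for i in range(n_tumor - n_shared)]
    normal_only = [f"{prefix}N{i}" for i in range(n_normal - n_shared)]

    def table(features, lfcs):
        return pd.DataFrame(
            {"log2fc": lfcs, "padj": 0.001, "significant": True},
            index=pd.Index(features, name="feature"))

    tumor = table(shared + tumor_only, [lfc] * len(shared + tumor_only))
    normal_lfcs = [lfc if i < n_concordant else -lfc
                   for i in range(n_shared)] + [lfc] * len(normal_only)
    normal = table(shared + normal_only, normal_lfcs)
    return tumor, normal


def make_interaction_table(
    truth: GroundTruth,
    mrna: CountMatrix,
    mirna: CountMatrix,
    config: CohortConfig,
    n_decoys: int = 30,
    n_prediction_only: int = 10,
) -> pd.DataFrame:
    """Validated-interaction table covering planted pairs plus decoys.

    Planted pairs get direct evidence; decoys are random non-planted
    (miRNA, gene) combinations with direct evidence (null correlations);
    a few prediction-only rows exercise the evidence filter.
    """
    rng = config.rng(_INTERACTIONS)
    planted = {(m, g) for m, g in
               zip(truth.planted_pairs["mirna"], truth.planted_pairs["gene"])}
    rows = [{"mirna": m, "gene": g, "evidence": "direct",
             "source_id": f"PLANTED{i + 1:04d}"}
            for i, (m, g) in enumerate(sorted(planted))]
    genes = list(mrna.feature_ids)
    mirnas = list(mirna.feature_ids)
    seen = set(planted)
    n_wanted = n_decoys + n_prediction_only
    while len(seen) - len(planted) < n_wanted:
        pair = (mirnas[rng.integers(len(mirnas))], genes[rng.integers(len(genes))])
        if pair in seen:
            continue
        seen.add(pair)
        idx = len(seen) - len(planted)
        rows.append({
            "mirna": pair[0], "gene": pair[1],
            "evidence": "direct" if idx <= n_decoys else "prediction_only",
            "source_id": f"DECOY{idx:04d}",
        })
    return pd.DataFrame(rows, columns=["mirna", "gene", "evidence", "source_id"])


# ---------------------------------------------------------------------------
# on-disk layout (used by the CLI)
# ---------------------------------------------------------------------------

def write_cohort(config: CohortConfig, outdir, include_sc: bool = True) -> dict:
    """Generate and write the full cohort as plain-text artifacts."""
    from sexbias import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mrna, mirna, samples, truth = generate_bulk(config)
    samples = generate_survival(samples, mrna, truth, config)
    paths = {}
    io.write_counts(mrna, outdir / "mrna_counts.tsv")
    io.write_counts(mirna, outdir / "mirna_counts.tsv")
    io.write_samples(samples, outdir / "samples.tsv")
    annot = pd.concat([mrna.annotation, mirna.annotation])
    io.write_annotation(annot, outdir / "features.tsv")
    truth.sex_biased.to_csv(outdir / "truth_sex_biased.tsv", sep="\t", index=False)
    truth.planted_pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
    truth.risk_features.to_csv(outdir / "truth_risk.tsv", sep="\t", index=False)
    interactions = make_interaction_table(truth, mrna, mirna, config)
    interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    paths["interactions"] = outdir / "interactions.tsv"
    paths.update({
        "mrna": outdir / "mrna_counts.tsv",
        "mirna": outdir / "mirna_counts.tsv",
        "samples": outdir / "samples.tsv",
        "features": outdir / "features.tsv",
    })
    if include_sc:
        cells, sc_truth = generate_sc(config)
        scdir = outdir / "sc"
        io.write_mtx_triplet(cells.umi, cells.genes, cells.barcodes, scdir)
        cells.cell_meta.to_csv(scdir / "cell_meta.tsv", sep="\t",
                               index_label="barcode")
        sc_truth.to_csv(scdir / "truth_sc.tsv", sep="\t", index=False)
        paths["sc"] = scdir
    return {k: str(v) for k, v in paths.items()}
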