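"""End-to-end orchestration: simulate -> DE x4 -> TSSB -> pairs -> survival
-> enrichment -> single-cell, with a JSON run manifest.

The run is driven by a single declarative config (YAML/dict).  Every
analysis threshold is a named key defaulting to the pipeline's standard
values (alpha 0.05, lfc 0.58, correlation p 0.05, enrichment min count 2).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from sexbias import __version__, de, enrich, io, pairs, sc, surv, synth, tssb

DEFAULT_STAGES = ("simulate", "de", "tssb", "pairs", "survival",
                  "enrichment", "sc")


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    stages: tuple = DEFAULT_STAGES
    # thresholds (named after what they gate)
    alpha: float = 0.05
    lfc: float = 0.58
    correlation_p: float = 0.05
    enrichment_min_count: int = 2
    min_count: int = 10
    min_fraction: float = 0.2
    mrna_tumor_covariates: tuple = ("age", "stage", "grade")
    mrna_normal_covariates: tuple = ("age",)
    # inputs (filled from the simulate stage when enabled)
    mrna_counts: str | None = None
    mirna_counts: str | None = None
    samples: str | None = None
    annotation: str | None = None
    interactions: str | None = None
    gmt: str | None = None
    sc_dir: str | None = None
    cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "lfc", "correlation_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        cfg = cls(**data)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _sha256(path) -> str:
    path = Path(path)
    digest = hashlib.sha256()
    if path.is_dir():
        for child in sorted(p for p in path.rglob("*") if p.is_file()):
            digest.update(child.name.encode())
            digest.update(child.read_bytes())
    else:
        digest.update(path.read_bytes())
    return digest.hexdigest()


def _require(config: RunConfig, stage: str, *attrs):
    for attr in attrs:
        value = getattr(config, attr)
        if value is None or not Path(value).exists():
            raise StageError(
                stage,
                f"missing upstream artifact '{attr}' "
                f"({value}); rerun the stage that produces it",
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("cohort",)},
        "stages": {},
        "counts": {},
        "outputs": {},
    }
    artifacts: dict[str, Path] = {}

    def record(stage: str, **paths):
        manifest["stages"][stage] = "ok"
        for name, path in paths.items():
            artifacts[name] = Path(path)
            manifest["outputs"][name] = {
                "path": str(path), "sha256": _sha256(path)}

    if "simulate" in config.stages:
        cohort = synth.CohortConfig(seed=config.seed, **config.cohort)
        simdir = outdir / "sim"
        written = synth.write_cohort(cohort, simdir, include_sc="sc" in config.stages)
        config.mrna_counts = written["mrna"]
        config.mirna_counts = written["mirna"]
        config.samples = written["samples"]
        config.annotation = written["features"]
        config.interactions = written["interactions"]
        if "sc" in config.stages:
            config.sc_dir = written["sc"]
        record("simulate", **written)

    de_tables: dict[str, pd.DataFrame] = {}
    if "de" in config.stages:
        _require(config, "de", "mrna_counts", "mirna_counts", "samples")
        samples = io.read_samples(config.samples)
        mrna = io.read_counts(config.mrna_counts, config.annotation)
        mirna = io.read_counts(config.mirna_counts)
        jobs = [
            ("mrna_tumor", mrna, "tumor", tuple(config.mrna_tumor_covariates)),
            ("mrna_normal", mrna, "normal", tuple(config.mrna_normal_covariates)),
            ("mirna_tumor", mirna, "tumor", ()),
            ("mirna_normal", mirna, "normal", ()),
        ]
        written = {}
        for name, cm, tissue, covs in jobs:
            sub_samples = samples[samples["tissue"] == tissue]
            sub = cm.subset_samples(sub_samples.index)
            sub = de.filter_low_expression(sub, config.min_count,
                                           config.min_fraction)
            try:
                res = de.nb_wald(sub, sub_samples, covariates=list(covs),
                                 alpha=config.alpha, lfc=config.lfc)
            except ValueError as exc:
                raise StageError("de", str(exc)) from exc
            de_tables[name] = res
            path = outdir / f"de_{name}.tsv"
            res.to_csv(path, sep="\t")
            written[f"de_{name}"] = path
            manifest["counts"][f"{name}_tested"] = int(len(res))
            manifest["counts"][f"{name}_significant"] = int(res["significant"].sum())
        record("de", **written)

    tssb_sets: dict[str, tssb.TSSBSet] = {}
    if "tssb" in config.stages:
        if not de_tables:
            raise StageError("tssb", "DE tables unavailable; rerun the 'de' stage")
        annot = io.read_annotation(config.annotation) if config.annotation else None
        written = {}
        for mode, tkey, nkey in (("genes", "mrna_tumor", "mrna_normal"),
                                 ("mirnas", "mirna_tumor", "mirna_normal")):
            ts = tssb.build_tssb(de_tables[tkey], de_tables[nkey], mode=mode)
            tssb_sets[mode] = ts
            path = outdir / f"tssb_{mode}.tsv"
            ts.membership_table().to_csv(path, sep="\t", index=False)
            summary = ts.summary()
            if annot is not None:
                dist = tssb.chromosome_distribution(ts, annot)
                dist.to_csv(outdir / f"tssb_{mode}_chromosomes.tsv", sep="\t")
            json_path = outdir / f"tssb_{mode}_summary.json"
            json_path.write_text(json.dumps(summary, indent=2))
            written[f"tssb_{mode}"] = path
            written[f"tssb_{mode}_summary"] = json_path
            manifest["counts"][f"tssb_{mode}"] = summary["tssb"]
        record("tssb", **written)

    if "pairs" in config.stages:
        if not tssb_sets:
            raise StageError("pairs", "TSSB sets unavailable; rerun 'tssb'")
        _require(config, "pairs", "interactions")
        samples = io.read_samples(config.samples)
        mrna = io.read_counts(config.mrna_counts)
        mirna = io.read_counts(config.mirna_counts)
        tumor_ids = samples.index[samples["tissue"] == "tumor"]
        interactions = pairs.load_interactions(config.interactions)
        keep = (interactions["mirna"].isin(tssb_sets["mirnas"].tssb)
                & interactions["gene"].isin(tssb_sets["genes"].tssb))
        candidate = interactions[keep]
        mrna_vst = pairs.vst_transform(mrna.subset_samples(tumor_ids))
        mirna_vst = pairs.vst_transform(mirna.subset_samples(tumor_ids))
        records = pairs.sex_stratified_correlation(
            candidate, mrna_vst, mirna_vst, samples,
            p_threshold=config.correlation_p)
        if not records.empty:
            records = pairs.classify_direction(
                records, de_tables["mirna_tumor"], de_tables["mrna_tumor"])
        path = outdir / "pairs.tsv"
        records.to_csv(path, sep="\t", index=False)
        network = pairs.export_network(records, outdir / "network")
        manifest["counts"]["candidate_pairs"] = int(len(records))
        manifest["counts"]["retained_pairs"] = int(records["retained"].sum()) \
            if "retained" in records.columns and len(records) else 0
        record("pairs", pairs_table=path,
               **{f"network_{k}": v for k, v in network.items()})

    if "survival" in config.stages:
        if not tssb_sets:
            raise StageError("survival", "TSSB sets unavailable; rerun 'tssb'")
        samples = io.read_samples(config.samples)
        mrna = io.read_counts(config.mrna_counts)
        vst = pairs.vst_transform(mrna)
        features = sorted(tssb_sets["genes"].tssb)
        calls, summary = surv.survival_screen(features, vst, samples,
                                              alpha=config.alpha)
        path = outdir / "survival.tsv"
        calls.to_csv(path, sep="\t", index=False)
        summary_path = outdir / "survival_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2))
        for key in ("male_only", "female_only", "both"):
            manifest["counts"][f"survival_{key}"] = len(summary[key])
        record("survival", survival_calls=path, survival_summary=summary_path)

    if "enrichment" in config.stages and config.gmt:
        if not tssb_sets:
            raise StageError("enrichment", "TSSB sets unavailable; rerun 'tssb'")
        _require(config, "enrichment", "gmt")
        mrna = io.read_counts(config.mrna_counts)
        filtered = de.filter_low_expression(mrna, config.min_count,
                                            config.min_fraction)
        universe = set(filtered.feature_ids)
        gene_sets = enrich.read_gmt(config.gmt)
        result = enrich.ora(tssb_sets["genes"].tssb, gene_sets, universe,
                            alpha=config.alpha,
                            min_count=config.enrichment_min_count)
        path = outdir / "enrichment.tsv"
        result.to_csv(path, sep="\t", index=False)
        manifest["counts"]["enriched_terms"] = int(result["reported"].sum()) \
            if len(result) else 0
        record("enrichment", enrichment=path)

    if "sc" in config.stages and config.sc_dir:
        scdir = Path(config.sc_dir)
        matrix, genes, barcodes = io.read_mtx_triplet(scdir)
        meta = pd.read_csv(scdir / "cell_meta.tsv", sep="\t", index_col=0)
        cells = sc.CellMatrix(matrix, genes, barcodes, meta)
        kept = sc.qc_filter(cells)
        panel_path = scdir / "truth_sc.tsv"
        if panel_path.exists():
            panel = pd.read_csv(panel_path, sep="\t")["gene"].tolist()
        else:
            panel = sorted(tssb_sets["genes"].tssb) if tssb_sets else genes[:20]
        result = sc.per_celltype_sex_de(kept, panel, alpha=config.alpha,
                                        lfc=config.lfc)
        path = outdir / "sc_de.tsv"
        result.to_csv(path, sep="\t", index=False)
        manifest["counts"]["sc_cells_kept"] = int(kept.n_cells)
        manifest["counts"]["sc_de_significant"] = int(result["significant"].sum()) \
            if len(result) else 0
        record("sc", sc_de=path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
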