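"""Validated miRNA-mRNA pair filtering by sex-stratified negative correlation.

Validated interactions (miRTarBase-style, direct evidence only) are
intersected with TSSB miRNAs and genes; each candidate pair is tested by
Pearson correlation within male and within female tumor samples on
variance-stabilized expression, retained when significantly negative in at
least one sex, and classified by the sex-bias direction of its two members.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from sexbias.datatypes import CountMatrix
from sexbias.de import size_factors

CATEGORIES = {
    (-1, -1): "F_mirna_F_gene",
    (-1, +1): "F_mirna_M_gene",
    (+1, -1): "M_mirna_F_gene",
    (+1, +1): "M_mirna_M_gene",
}
DISCORDANT = {"F_mirna_M_gene", "M_mirna_F_gene"}

PAIR_COLUMNS = [
    "mirna", "gene", "r_male", "p_male", "r_female", "p_female",
    "retained", "retained_in", "mirna_log2fc", "gene_log2fc",
    "category", "discordant",
]


def load_interactions(path, evidence_filter: str = "direct") -> pd.DataFrame:
    """Parse an interaction TSV (mirna, gene, evidence, source_id).

    Rows whose evidence class differs from ``evidence_filter`` are dropped
    (the paper-style setting keeps direct experimental evidence only).
    Duplicate (mirna, gene) pairs collapse to one record.  Malformed rows
    raise with their line number.
    """
    records = []
    with open(path) as handle:
        header = None
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["mirna", "gene", "evidence", "source_id"]
                if [f.strip().lower() for f in header[:4]] != expected:
                    raise ValueError(
                        f"line {lineno}: expected header columns {expected}, "
                        f"got {header[:4]}"
                    )
                continue
            if len(fields) < 4 or any(not f.strip() for f in fields[:3]):
                raise ValueError(f"line {lineno}: malformed interaction row: {line!r}")
            records.append(fields[:4])
    table = pd.DataFrame(records, columns=["mirna", "gene", "evidence", "source_id"])
    if evidence_filter is not None:
        table = table[table["evidence"] == evidence_filter]
    table = table.drop_duplicates(subset=["mirna", "gene"]).reset_index(drop=True)
    return table


def vst_transform(counts: CountMatrix) -> pd.DataFrame:
    """Variance-stabilizing substitute: log2(count / size_factor + 1).

    Stands in for a fitted mean-dispersion VST; monotone in counts per
    sample, which is all downstream Pearson filtering relies on.
    """
    sf = size_factors(counts)
    return np.log2(counts.counts / sf.to_numpy() + 1.0)


def _stratum_correlation(x: np.ndarray, y: np.ndarray):
    """Pearson r and two-sided t-test p (n-2 df); (nan, nan) when undefined."""
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def sex_stratified_correlation(
    interactions: pd.DataFrame,
    mrna_vst: pd.DataFrame,
    mirna_vst: pd.DataFrame,
    samples: pd.DataFrame,
    p_threshold: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-pair Pearson correlation within male and female tumor samples.

    A pair is retained when r < 0 with p < ``p_threshold`` in at least one
    sex; ``retained_in`` records which.  ``adjust=True`` applies BH across
    pairs per stratum as a sensitivity analysis (default follows the raw
    p < 0.05 rule).
    """
    tumor = samples[samples["tissue"] == "tumor"]
    strata = {}
    for sex in ("male", "female"):
        ids = tumor.index[tumor["sex"] == sex]
        ids = [s for s in ids if s in mrna_vst.columns and s in mirna_vst.columns]
        if len(ids) < 3:
            raise ValueError(f"need >= 3 tumor samples in the {sex} stratum")
        strata[sex] = ids

    rows = []
    for _, rec in interactions.iterrows():
        mir, gene = rec["mirna"], rec["gene"]
        if mir not in mirna_vst.index or gene not in mrna_vst.index:
            continue
        row: dict = {"mirna": mir, "gene": gene}
        for sex in ("male", "female"):
            ids = strata[sex]
            r, p = _stratum_correlation(
                mirna_vst.loc[mir, ids].to_numpy(dtype=float),
                mrna_vst.loc[gene, ids].to_numpy(dtype=float),
            )
            row[f"r_{sex}"] = r
            row[f"p_{sex}"] = p
        rows.append(row)
    result = pd.DataFrame(rows, columns=["mirna", "gene", "r_male", "p_male",
                                         "r_female", "p_female"])
    if result.empty:
        result["retained"] = pd.Series(dtype=bool)
        result["retained_in"] = pd.Series(dtype=object)
        return result

    if adjust:
        from sexbias.de import bh_adjust
        p_male = bh_adjust(result["p_male"])
        p_female = bh_adjust(result["p_female"])
    else:
        p_male = result["p_male"].to_numpy()
        p_female = result["p_female"].to_numpy()
    hit_m = (result["r_male"] < 0) & (p_male < p_threshold)
    hit_f = (result["r_female"] < 0) & (p_female < p_threshold)
    hit_m = hit_m.fillna(False).to_numpy(dtype=bool)
    hit_f = hit_f.fillna(False).to_numpy(dtype=bool)
    result["retained"] = hit_m | hit_f
    result["retained_in"] = np.select(
        [hit_m & hit_f, hit_m, hit_f], ["both", "male_only", "female_only"], "none"
    )
    return result


def classify_direction(
    pairs: pd.DataFrame, mirna_de: pd.DataFrame, gene_de: pd.DataFrame
) -> pd.DataFrame:
    """Attach sex-bias direction categories from tumor log2 fold changes.

    Categories follow the sign pair (miRNA, gene): male-biased is positive.
    Discordant pairs have members biased toward opposite sexes.
    """
    pairs = pairs.copy()
    pairs["mirna_log2fc"] = pairs["mirna"].map(mirna_de["log2fc"]).astype(float)
    pairs["gene_log2fc"] = pairs["gene"].map(gene_de["log2fc"]).astype(float)
    if pairs[["mirna_log2fc", "gene_log2fc"]].isna().any().any():
        missing = pairs.loc[
            pairs[["mirna_log2fc", "gene_log2fc"]].isna().any(axis=1),
            ["mirna", "gene"],
        ]
        raise ValueError(f"pairs reference features absent from DE tables:\n{missing}")
    # TSSB membership guarantees |log2fc| > 0, so the sign is well defined
    assert (pairs["mirna_log2fc"] != 0).all() and (pairs["gene_log2fc"] != 0).all()
    signs = zip(np.sign(pairs["mirna_log2fc"]).astype(int),
                np.sign(pairs["gene_log2fc"]).astype(int))
    pairs["category"] = [CATEGORIES[s] for s in signs]
    pairs["discordant"] = pairs["category"].isin(DISCORDANT)
    return pairs


def export_network(records: pd.DataFrame, prefix) -> dict:
    """Write a SIF file plus node/edge attribute tables (and GraphML).

    Nodes carry their role (mirna/gene) and a sex-specificity class taken
    from the pair's ``retained_in`` strata (male_specific, female_specific,
    shared).  Returns the written paths.
    """
    import networkx as nx

    prefix = str(prefix)
    retained = records[records["retained"]] if "retained" in records.columns else records
    sif_path = prefix + ".sif"
    with open(sif_path, "w") as out:
        for _, rec in retained.iterrows():
            out.write(f"{rec['mirna']}\trepresses\t{rec['gene']}\n")

    graph = nx.DiGraph()
    node_class: dict[str, set] = {}
    for _, rec in retained.iterrows():
        stratum = rec.get("retained_in", "both")
        for node in (rec["mirna"], rec["gene"]):
            node_class.setdefault(node, set()).add(stratum)
    for _, rec in retained.iterrows():
        graph.add_node(rec["mirna"], role="mirna")
        graph.add_node(rec["gene"], role="gene")
        graph.add_edge(rec["mirna"], rec["gene"],
                       **{k: rec[k] for k in retained.columns
                          if k not in ("mirna", "gene") and pd.notna(rec[k])})

    def _sex_class(strata: set) -> str:
        if strata <= {"male_only"}:
            return "male_specific"
        if strata <= {"female_only"}:
            return "female_specific"
        return "shared"

    node_rows = []
    for node in graph.nodes:
        cls = _sex_class(node_class.get(node, set()))
        graph.nodes[node]["sex_class"] = cls
        node_rows.append({"node": node, "role": graph.nodes[node]["role"],
                          "sex_class": cls})
    nodes_path = prefix + "_nodes.tsv"
    pd.DataFrame(node_rows, columns=["node", "role", "sex_class"]).to_csv(
        nodes_path, sep="\t", index=False)
    edges_path = prefix + "_edges.tsv"
    retained.to_csv(edges_path, sep="\t", index=False)
    graphml_path = prefix + ".graphml"
    nx.write_graphml(graph, graphml_path)
    return {"sif": sif_path, "nodes": nodes_path, "edges": edges_path,
            "graphml": graphml_path}
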