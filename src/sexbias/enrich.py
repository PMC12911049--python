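"""Hypergeometric over-representation analysis against GMT gene sets."""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from sexbias.de import bh_adjust

ORA_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p", "padj",
               "overlap_genes", "reported"]


def read_gmt(path) -> dict[str, tuple[str, frozenset]]:
    """Parse a GMT file into {term_id: (description, gene set)}.

    Each line is term, description, then one gene per tab-separated field.
    Duplicate genes within a line are collapsed; lines with fewer than three
    fields raise with their line number; terms with no genes are dropped.
    """
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT line needs >= 3 fields")
            term, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if genes:
                sets[term] = (desc, genes)
    return sets


def ora(
    query,
    gene_sets: dict[str, tuple[str, frozenset]],
    universe,
    alpha: float = 0.05,
    min_count: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    ``p = P(X >= k)`` with population N = |universe|, K = |term in universe|,
    draws n = |query in universe|.  BH correction spans the tested terms;
    ``reported`` marks terms passing padj < ``alpha`` and overlap >= ``min_count``.
    Query genes outside the universe are dropped with a warning.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = frozenset(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
    query &= universe
    big_n, small_n = len(universe), len(query)
    rows = []
    for term, (desc, genes) in gene_sets.items():
        in_universe = genes & universe
        big_k = len(in_universe)
        if big_k == 0:
            continue
        overlap = in_universe & query
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, small_n))
        rows.append({
            "term_id": term, "term_name": desc,
            "k": k, "K": big_k, "n": small_n, "N": big_n,
            "p": p, "overlap_genes": ",".join(sorted(overlap)),
        })
    result = pd.DataFrame(rows, columns=[c for c in ORA_COLUMNS
                                         if c not in ("padj", "reported")])
    if result.empty:
        result["padj"] = pd.Series(dtype=float)
        result["reported"] = pd.Series(dtype=bool)
        return result
    result["padj"] = bh_adjust(result["p"])
    result["reported"] = (result["padj"] < alpha) & (result["k"] >= min_count)
    return result.sort_values("padj", kind="mergesort").reset_index(drop=True)[ORA_COLUMNS]
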