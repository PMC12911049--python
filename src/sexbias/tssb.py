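"""Tumor-specific sex-biased (TSSB) feature-set construction.

Significant features from the tumor and normal sex-DE analyses are
partitioned into tumor-specific, normal-specific, shared-concordant and
shared-reversed sets by the sign agreement of their fold changes.  The TSSB
set is tumor-specific plus shared-reversed: shared features whose sex bias
points the same way in both tissues are excluded as constitutive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class TSSBSet:
    """Disjoint partition of sex-DE features across tumor and normal tissue."""

    tumor_specific: frozenset
    normal_specific: frozenset
    shared_concordant: frozenset
    shared_reversed: frozenset
    tssb: frozenset = field(init=False)

    def __post_init__(self) -> None:
        parts = [
            self.tumor_specific, self.normal_specific,
            self.shared_concordant, self.shared_reversed,
        ]
        total = sum(len(p) for p in parts)
        if len(frozenset().union(*parts)) != total:
            raise ValueError("partitions overlap")
        self.tssb = self.tumor_specific | self.shared_reversed

    def membership_table(self) -> pd.DataFrame:
        rows = []
        for name, part in [
            ("tumor_specific", self.tumor_specific),
            ("normal_specific", self.normal_specific),
            ("shared_concordant", self.shared_concordant),
            ("shared_reversed", self.shared_reversed),
        ]:
            for feat in sorted(part):
                rows.append({"feature": feat, "partition": name,
                             "tssb": feat in self.tssb})
        return pd.DataFrame(rows, columns=["feature", "partition", "tssb"])

    def summary(self) -> dict:
        return {
            "tumor_specific": len(self.tumor_specific),
            "normal_specific": len(self.normal_specific),
            "shared_concordant": len(self.shared_concordant),
            "shared_reversed": len(self.shared_reversed),
            "tssb": len(self.tssb),
        }


def _significant(de: pd.DataFrame) -> pd.DataFrame:
    if not de.index.is_unique:
        dup = de.index[de.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate features in DE result: {dup}")
    return de[de["significant"].astype(bool)]


def build_tssb(tumor_de: pd.DataFrame, normal_de: pd.DataFrame,
               mode: str = "genes") -> TSSBSet:
    """Partition significant features and build the TSSB set.

    Both inputs are DE tables indexed by feature with ``significant`` and
    ``log2fc`` columns.  The identical rule applies to genes and miRNAs
    (``mode`` is recorded for reporting only).
    """
    if mode not in ("genes", "mirnas"):
        raise ValueError("mode must be 'genes' or 'mirnas'")
    tum = _significant(tumor_de)
    norm = _significant(normal_de)
    tum_set = set(tum.index)
    norm_set = set(norm.index)
    shared = tum_set & norm_set
    # significance requires |log2fc| > 0.58, so a zero sign cannot occur
    for feat in shared:
        assert tum.loc[feat, "log2fc"] != 0 and norm.loc[feat, "log2fc"] != 0
    concordant = frozenset(
        f for f in shared
        if tum.loc[f, "log2fc"] * norm.loc[f, "log2fc"] > 0
    )
    reversed_ = frozenset(shared) - concordant
    return TSSBSet(
        tumor_specific=frozenset(tum_set - shared),
        normal_specific=frozenset(norm_set - shared),
        shared_concordant=concordant,
        shared_reversed=reversed_,
    )


def chromosome_distribution(tssb: TSSBSet, annotation: pd.DataFrame) -> pd.DataFrame:
    """Count features per chromosome per partition.

    ``annotation`` is indexed by feature with a ``chromosome`` column.
    Unannotated features are counted under ``unknown`` with a warning.
    Returns a partitions x chromosomes count table.
    """
    chrom = annotation["chromosome"] if "chromosome" in annotation.columns else pd.Series(dtype=object)
    rows = {}
    missing = []
    for name, part in [
        ("tumor_specific", tssb.tumor_specific),
        ("normal_specific", tssb.normal_specific),
        ("shared_concordant", tssb.shared_concordant),
        ("shared_reversed", tssb.shared_reversed),
    ]:
        counts: dict[str, int] = {}
        for feat in part:
            label = chrom.get(feat)
            if label is None or pd.isna(label):
                missing.append(feat)
                label = "unknown"
            counts[str(label)] = counts.get(str(label), 0) + 1
        rows[name] = counts
    if missing:
        warnings.warn(
            f"{len(missing)} feature(s) lack chromosome annotation; "
            "counted as 'unknown'",
            stacklevel=2,
        )
    table = pd.DataFrame(rows).T.fillna(0).astype(int)
    table.index.name = "partition"
    return table


def chromosome_fraction(distribution: pd.DataFrame, partition: str,
                        chromosomes) -> float:
    """Fraction of a partition's features on the given chromosome label(s)."""
    if partition not in distribution.index:
        raise KeyError(partition)
    row = distribution.loc[partition]
    total = row.sum()
    if total == 0:
        return float("nan")
    if isinstance(chromosomes, str):
        chromosomes = [chromosomes]
    hit = sum(row.get(c, 0) for c in chromosomes)
    return hit / total
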