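"""Core data containers shared across the pipeline.

A :class:`CountMatrix` wraps a features x samples integer matrix together
with per-feature annotation (chromosome, biotype).  Sample sheets are plain
:class:`pandas.DataFrame` objects indexed by ``sample_id`` and validated by
:func:`validate_sample_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("male", "female")
TISSUES = ("tumor", "normal")

#: Columns a sample sheet must carry.  ``os_time``/``os_status`` may be NaN.
SAMPLE_COLUMNS = ("sex", "tissue", "age", "stage", "grade", "os_time", "os_status")


@dataclass
class CountMatrix:
    """Nonnegative integer feature x sample matrix with feature annotation.

    Parameters
    ----------
    counts
        DataFrame of shape (n_features, n_samples); index = feature IDs,
        columns = sample IDs.
    annotation
        DataFrame indexed by feature ID with at least ``chromosome`` and
        ``biotype`` columns.  Optional; an empty frame is substituted when
        omitted.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotation is None:
            self.annotation = pd.DataFrame(
                index=self.counts.index, columns=["chromosome", "biotype"]
            )
        if not self.counts.index.is_unique:
            raise ValueError("feature IDs must be unique")
        if not self.counts.columns.is_unique:
            raise ValueError("sample IDs must be unique")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be nonnegative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.annotation)

    def subset_features(self, feature_ids) -> "CountMatrix":
        idx = pd.Index(feature_ids)
        return CountMatrix(
            self.counts.loc[idx], self.annotation.reindex(idx)
        )


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet and return it with canonical dtypes.

    Requires unique ``sample_id`` index, ``sex`` in {male, female},
    ``tissue`` in {tumor, normal}, and nonnegative ``os_time`` wherever it
    is present.
    """
    if samples.index.name != "sample_id":
        if "sample_id" in samples.columns:
            samples = samples.set_index("sample_id")
        else:
            raise ValueError("sample sheet needs a 'sample_id' column or index")
    if not samples.index.is_unique:
        raise ValueError("sample_ids must be unique")
    missing = [c for c in ("sex", "tissue") if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    bad_sex = set(samples["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"invalid sex values: {sorted(bad_sex)}")
    bad_tissue = set(samples["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValueError(f"invalid tissue values: {sorted(bad_tissue)}")
    if "os_time" in samples.columns:
        t = pd.to_numeric(samples["os_time"], errors="coerce")
        if (t.dropna() < 0).any():
            raise ValueError("os_time must be >= 0")
    return samples


def align(counts: CountMatrix, samples: pd.DataFrame) -> tuple[CountMatrix, pd.DataFrame]:
    """Restrict a count matrix and sample sheet to their shared samples."""
    shared = [s for s in counts.sample_ids if s in samples.index]
    if not shared:
        raise ValueError("count matrix and sample sheet share no samples")
    return counts.subset_samples(shared), samples.loc[shared]
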