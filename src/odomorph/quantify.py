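"""Expression quantification: TPM, isoform-to-gene aggregation, fold changes.

TPM (transcripts per million) normalizes raw counts by feature effective
length and sequencing depth so that every sample column sums to 1e6.
Screening thresholds elsewhere in the package are absolute TPM values, so
no pseudocount enters the TPM computation itself; ``log2fc`` takes an
explicit pseudocount because it is a display/clustering quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "compute_tpm", "sum_isoforms", "log2fc"]


@dataclass
class CountMatrix:
    """Feature x sample raw counts plus per-feature effective lengths (bp).

    Parameters
    ----------
    counts
        DataFrame indexed by feature id with one column per sample id.
    lengths
        Series of effective lengths in bp, indexed by feature id.
    """

    counts: pd.DataFrame
    lengths: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()[:5]
            raise ValueError(f"features without effective length: {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("effective lengths must be > 0")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)], self.lengths)


def compute_tpm(cm: CountMatrix) -> pd.DataFrame:
    """TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j), per sample.

    Raises ``ValueError`` on an all-zero sample column (depth undefined).
    """
    rate = cm.counts.div(cm.lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return rate.div(denom, axis=1) * 1e6


def sum_isoforms(tpm: pd.DataFrame, annotation: pd.Series) -> pd.DataFrame:
    """Aggregate isoform-level TPM to gene level by summation.

    ``annotation`` maps feature id -> gene id and must cover every feature.
    Column sums are preserved because the isoform groups partition the
    feature set.
    """
    genes = annotation.reindex(tpm.index)
    if genes.isna().any():
        missing = genes.index[genes.isna()].tolist()[:5]
        raise ValueError(f"unannotated feature(s): {missing}")
    out = tpm.groupby(genes, sort=True).sum()
    out.index.name = "gene_id"
    return out


def log2fc(
    tpm: pd.DataFrame,
    group_a,
    group_b,
    pseudocount: float = 0.1,
) -> pd.Series:
    """Per-feature log2((mean_A + pc) / (mean_B + pc)) over sample groups."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("log2fc groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("log2fc groups must be disjoint")
    mean_a = tpm.loc[:, group_a].mean(axis=1)
    mean_b = tpm.loc[:, group_b].mean(axis=1)
    return pd.Series(
        np.log2((mean_a + pseudocount) / (mean_b + pseudocount)),
        index=tpm.index,
        name="log2fc",
    )
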