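"""Replicate averaging, total-count percent normalization, and gene filters.

The normalization deliberately reproduces total-count scaling to a percent
scale: each gene's mean count is divided by the summed mean counts of all
retained genes in its breed-sex group and multiplied by 100. This removes
between-library depth differences so hybrid-parent ratios are comparable.
Genes on the Z chromosome are excluded (chicken dosage compensation is
incomplete, so ZZ males systematically exceed ZW females), as are genes
with zero counts in every sample of the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: cross code -> breed/hybrid unit prefix used in ExpressionProfile columns
CROSS_TO_UNIT = {"CC": "Cor", "CW": "WL", "CL": "CL", "LC": "LC"}

#: chromosome names treated as Z-linked
Z_CHROM_NAMES = frozenset({"Z", "chrZ", "z"})


class PreprocessError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Raw gene x sample read counts with sample and gene annotation.

    ``counts``: genes x samples integer frame, index named ``gene_id``.
    ``samples``: one row per sample (index = sample name) with columns
    ``cross`` (CC/CW/CL/LC), ``sex`` (M/F), ``tissue``, ``replicate``.
    ``gene_chrom``: chromosome name per gene, aligned with ``counts.index``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_chrom: pd.Series

    def __post_init__(self) -> None:
        missing = {"cross", "sex", "tissue", "replicate"} - set(self.samples.columns)
        if missing:
            raise PreprocessError(f"sample table lacks columns: {sorted(missing)}")
        if list(self.counts.columns) != list(self.samples.index):
            raise PreprocessError("count columns and sample table rows disagree")
        if not self.gene_chrom.index.equals(self.counts.index):
            raise PreprocessError("gene_chrom index does not match count matrix genes")
        if (self.counts.to_numpy() < 0).any():
            raise PreprocessError("negative counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def subset_genes(self, keep: pd.Index) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[keep],
            samples=self.samples,
            gene_chrom=self.gene_chrom.loc[keep],
        )


def unit_label(cross: str, sex: str) -> str:
    """Breed-sex group label, e.g. ('CC','M') -> 'Cor_M'."""
    try:
        return f"{CROSS_TO_UNIT[cross]}_{sex}"
    except KeyError:
        raise PreprocessError(f"unknown cross code {cross!r}") from None


def filter_genes(matrix: CountMatrix, z_chroms: frozenset[str] = Z_CHROM_NAMES) -> CountMatrix:
    """Drop Z-linked genes and genes with zero counts in every sample.

    The zero filter is taken across all samples of the tissue the matrix
    holds; gene order is preserved.
    """
    if matrix.gene_chrom.isna().any():
        bad = matrix.gene_chrom.index[matrix.gene_chrom.isna()]
        raise PreprocessError(f"missing chromosome annotation for genes: {list(bad[:5])}...")
    on_z = matrix.gene_chrom.isin(z_chroms)
    all_zero = (matrix.counts == 0).all(axis=1)
    keep = matrix.gene_ids[~(on_z | all_zero)]
    return matrix.subset_genes(keep)


def average_replicates(matrix: CountMatrix) -> pd.DataFrame:
    """Arithmetic mean count per gene within each (cross, sex) group.

    Returns genes x groups, group columns labelled ``Cor_M``, ``WL_F``,
    ``CL_M``, ``LC_F`` etc. Means may be non-integer.
    """
    groups = matrix.samples.groupby(["cross", "sex"], sort=True).groups
    out = {}
    for (cross, sex), sample_names in groups.items():
        names = list(sample_names)
        if not names:
            raise PreprocessError(f"group ({cross},{sex}) has no replicates")
        out[unit_label(cross, sex)] = matrix.counts[names].mean(axis=1)
    return pd.DataFrame(out, index=matrix.gene_ids)


def normalize_percent(group_means: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-total expression: 100 * mean / column sum.

    Each group column of the result sums to 100. A zero column total is an
    error (an empty library cannot be scaled).
    """
    totals = group_means.sum(axis=0)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise PreprocessError(f"zero total mapped reads in group(s): {list(zero.index)}")
    return group_means.div(totals, axis=1) * 100.0


def make_profile(matrix: CountMatrix) -> pd.DataFrame:
    """filter -> average replicates -> percent-normalize, in that order.

    Filtering precedes normalization so every group shares one retained
    gene set and one denominator definition.
    """
    return normalize_percent(average_replicates(filter_genes(matrix)))
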