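"""Size-factor normalization, RPKM/nRPKM expression values and gene pre-filtering.

The expression unit used throughout is nRPKM: reads per kilobase of gene
model per million *adjusted* total reads.  Adjusted totals are proportional
to the per-sample median-of-ratios size factor but rescaled so that their
sum equals the sum of total uniquely aligned reads.  For a fixed gene, nRPKM
across samples is therefore exactly proportional to the size-factor
normalized count (count / size factor): the statistic is a single
size-factor normalization re-expressed on a reads-per-kilobase-per-million
scale, not a double normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "compute_size_factors",
    "compute_adjusted_totals",
    "compute_expression_matrix",
    "prefilter_genes",
]


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with gene lengths and library totals.

    Parameters
    ----------
    counts
        Genes x samples DataFrame of nonnegative integer read counts
        (reads overlapping exons of the gene model).
    gene_length_bp
        Positive union-exon length in bases per gene, indexed like
        ``counts.index``.
    total_uniq_reads
        Total uniquely aligned reads per sample (the "M" term), indexed
        like ``counts.columns``.  May exceed the column sums: totals
        include intronic and intergenic reads.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    total_uniq_reads: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
            object.__setattr__(self, "counts", counts)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        lengths = self.gene_length_bp.reindex(counts.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][:3].tolist()
            raise ValueError(f"gene lengths missing for genes: {missing}")
        if (lengths <= 0).any():
            raise ValueError("all gene lengths must be > 0")
        totals = self.total_uniq_reads.reindex(counts.columns)
        if totals.isna().any():
            missing = totals.index[totals.isna()][:3].tolist()
            raise ValueError(f"total_uniq_reads missing for samples: {missing}")
        if (totals <= 0).any():
            raise ValueError("all total_uniq_reads must be > 0")
        object.__setattr__(self, "gene_length_bp", lengths.astype(float))
        object.__setattr__(self, "total_uniq_reads", totals.astype(float))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


def compute_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample, anchored at geometric mean 1.

    Reference genes are those with nonzero counts in every sample (the
    gene-wise geometric mean is undefined otherwise).  For each sample the
    factor is the median over reference genes of count / geometric mean of
    that gene across samples; factors are then rescaled so their geometric
    mean is exactly 1, which makes the single-sample case return 1.

    Raises
    ------
    ValueError
        If no gene has nonzero counts in all samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = mat.to_numpy(dtype=float)
    if vals.shape[1] == 1:
        return pd.Series([1.0], index=mat.columns, name="size_factor")
    ref = (vals > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "cannot compute size factors: no gene has nonzero counts in every sample"
        )
    logv = np.log(vals[ref])
    geomean = np.exp(logv.mean(axis=1, keepdims=True))
    s = np.median(vals[ref] / geomean, axis=0)
    s = s / np.exp(np.log(s).mean())  # anchor: geometric mean of factors = 1
    return pd.Series(s, index=mat.columns, name="size_factor")


def compute_adjusted_totals(
    size_factors: pd.Series, total_uniq_reads: pd.Series
) -> pd.Series:
    """Rescale size factors to the level of total uniquely aligned reads.

    adjusted_total_j = s_j * C with C = sum(M) / sum(s), so that the sum of
    adjusted totals equals the sum of the observed totals.
    """
    if len(size_factors) != len(total_uniq_reads):
        raise ValueError(
            f"length mismatch: {len(size_factors)} size factors vs "
            f"{len(total_uniq_reads)} totals"
        )
    totals = total_uniq_reads.reindex(size_factors.index)
    if totals.isna().any():
        raise ValueError("size factors and totals have mismatched sample ids")
    if (totals <= 0).any():
        raise ValueError("all totals must be > 0")
    if (size_factors <= 0).any():
        raise ValueError("all size factors must be > 0")
    c = float(totals.sum()) / float(size_factors.sum())
    out = size_factors * c
    out.name = "adjusted_total_reads"
    return out


def compute_expression_matrix(
    counts: CountMatrix,
    size_factors: pd.Series | None = None,
    mode: str = "nRPKM",
) -> pd.DataFrame:
    """RPKM or nRPKM expression matrix.

    RPKM_ij  = count_ij / (length_i / 1000) / (M_j / 1e6).
    nRPKM_ij is identical except the adjusted total (size factor rescaled to
    the read level) replaces M_j.  Zero counts map to zero expression; no
    pseudocount is applied here.

    The returned DataFrame records ``mode``, ``size_factors`` and ``totals``
    in ``.attrs``.
    """
    if mode not in ("RPKM", "nRPKM"):
        raise ValueError(f"mode must be 'RPKM' or 'nRPKM', got {mode!r}")
    if mode == "nRPKM":
        if size_factors is None:
            size_factors = compute_size_factors(counts)
        totals = compute_adjusted_totals(size_factors, counts.total_uniq_reads)
    else:
        totals = counts.total_uniq_reads
    kb = counts.gene_length_bp.to_numpy() / 1e3
    millions = totals.to_numpy() / 1e6
    expr = counts.counts.to_numpy(dtype=float) / kb[:, None] / millions[None, :]
    out = pd.DataFrame(expr, index=counts.gene_ids, columns=counts.sample_ids)
    out.attrs["mode"] = mode
    out.attrs["size_factors"] = None if size_factors is None else dict(size_factors)
    out.attrs["totals"] = dict(totals)
    return out


def prefilter_genes(
    counts: CountMatrix | pd.DataFrame, min_count: int = 10, min_samples: int = 3
) -> pd.Series:
    """Per-gene boolean: >= ``min_count`` counts in >= ``min_samples`` samples.

    Samples are pooled over conditions.  Genes failing this filter are by
    convention assigned p = 1 and log2 fold change 0 downstream and are
    excluded from multiple-testing correction.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if min_samples > mat.shape[1]:
        warnings.warn(
            f"min_samples={min_samples} exceeds the number of samples "
            f"({mat.shape[1]}); all genes fail the pre-filter",
            stacklevel=2,
        )
    passing = (mat.to_numpy() >= min_count).sum(axis=1) >= min_samples
    return pd.Series(passing, index=mat.index, name="prefilter_pass")
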