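"""Count-matrix preprocessing: TPM, log transform, outlier masking, sample
filtering, and quantile normalization.

Expression matrices are pandas DataFrames with genes as rows and samples as
columns.  Masked (outlier) cells are represented as NaN and are excluded
from every downstream statistic; correlations are computed pairwise-complete.

The fixed pipeline order is TPM -> log2 -> zero-variance removal ->
iterative outlier masking -> intrasample-correlation (ISC) sample filter ->
quantile normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessReport",
    "counts_to_tpm",
    "log_transform",
    "iterative_outlier_mask",
    "filter_samples_by_isc",
    "quantile_normalize",
    "preprocess_counts",
]


@dataclass
class PreprocessReport:
    """Bookkeeping for every filter applied on the way to the network stage."""

    genes_removed_zero_variance: int = 0
    cells_masked_per_iteration: list[int] = field(default_factory=list)
    genes_dropped_low_coverage: list[str] = field(default_factory=list)
    samples_removed: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genes_removed_zero_variance": self.genes_removed_zero_variance,
            "cells_masked_per_iteration": list(self.cells_masked_per_iteration),
            "genes_dropped_low_coverage": list(self.genes_dropped_low_coverage),
            "samples_removed": list(self.samples_removed),
            "parameters": dict(self.parameters),
        }


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series | np.ndarray) -> pd.DataFrame:
    """Transcripts per million from raw counts and gene lengths (bp).

    Per sample: tpm_i = (count_i / length_i) / sum_j (count_j / length_j) * 1e6,
    so each sample's TPM column sums to one million whenever any count is
    positive.
    """
    lengths = (
        gene_lengths.reindex(counts.index).to_numpy(dtype=float)
        if isinstance(gene_lengths, pd.Series)
        else np.asarray(gene_lengths, dtype=float)
    )
    if lengths.shape[0] != counts.shape[0]:
        raise ValueError("gene_lengths must cover every gene in counts")
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    c = counts.to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    rate = c / lengths[:, None]
    totals = rate.sum(axis=0)
    zero = totals == 0
    if np.any(zero):
        bad = counts.columns[zero].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    tpm = rate / totals[None, :] * 1e6
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def log_transform(
    expr: pd.DataFrame, pseudocount: float = 1.0, zero_policy: str = "error"
) -> tuple[pd.DataFrame, int]:
    """log2(x + pseudocount), then drop zero-variance genes.

    Returns the transformed matrix and the number of genes removed for
    having no variance across samples.  With ``pseudocount=0`` a zero value
    raises by default (``zero_policy="error"``); ``zero_policy="neginf"``
    lets -inf through instead.
    """
    x = expr.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative before log transform")
    if pseudocount == 0 and np.any(x == 0):
        if zero_policy == "error":
            raise ValueError("zero values with pseudocount=0; set zero_policy='neginf' to allow")
        with np.errstate(divide="ignore"):
            logged = np.log2(x)
    else:
        logged = np.log2(x + pseudocount)
    out = pd.DataFrame(logged, index=expr.index, columns=expr.columns)
    finite = np.isfinite(logged).all(axis=1)
    variances = out.var(axis=1, ddof=1)
    # a row containing -inf is non-constant iff it has more than one value
    keep = np.where(finite, variances > 0, out.nunique(axis=1) > 1)
    n_removed = int((~keep).sum())
    return out.loc[keep], n_removed


def iterative_outlier_mask(
    expr: pd.DataFrame, sd_cutoff: float = 2.5, min_unmasked: int = 3
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Mask single-sample expression outliers per gene, iterating to convergence.

    Each pass computes every gene's mean and sample (n-1) SD over its
    currently unmasked cells and masks cells strictly more than
    ``sd_cutoff`` SDs from the mean; passes repeat until one masks nothing.
    Genes left with fewer than ``min_unmasked`` unmasked cells are dropped
    with a warning.
    """
    if expr.shape[1] < 4:
        raise ValueError("outlier masking needs at least 4 samples")
    values = expr.to_numpy(dtype=float).copy()
    report = PreprocessReport(parameters={"outlier_sd": sd_cutoff})
    while True:
        mean = np.nanmean(values, axis=1, keepdims=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            outliers = np.abs(values - mean) > sd_cutoff * sd
        n_masked = int(outliers.sum())
        report.cells_masked_per_iteration.append(n_masked)
        if n_masked == 0:
            break
        values[outliers] = np.nan
    out = pd.DataFrame(values, index=expr.index, columns=expr.columns)
    unmasked = out.notna().sum(axis=1)
    low = unmasked < min_unmasked
    if low.any():
        dropped = out.index[low].tolist()
        warnings.warn(f"dropping {len(dropped)} gene(s) with <{min_unmasked} unmasked samples")
        report.genes_dropped_low_coverage = dropped
        out = out.loc[~low]
    return out, report


def intrasample_correlation(expr: pd.DataFrame, how: str = "mean") -> pd.Series:
    """ISC per sample: mean (or median) Pearson correlation with every other sample."""
    corr = expr.corr(method="pearson")  # pairwise-complete over genes
    np.fill_diagonal(corr.values, np.nan)
    agg = corr.mean() if how == "mean" else corr.median()
    agg.name = "isc"
    return agg


def filter_samples_by_isc(
    expr: pd.DataFrame, sd_cutoff: float = 2.0, how: str = "mean"
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Remove samples whose ISC falls strictly below the group mean − cutoff·SD."""
    if expr.shape[1] < 3:
        raise ValueError("ISC filtering needs at least 3 samples")
    isc = intrasample_correlation(expr, how=how)
    threshold = isc.mean() - sd_cutoff * isc.std(ddof=1)
    removed = isc.index[isc < threshold].tolist()
    out = expr.drop(columns=removed)
    if out.shape[1] < 3:
        raise ValueError("fewer than 3 samples remain after ISC filtering")
    report = PreprocessReport(
        samples_removed=removed,
        parameters={"isc_sd": sd_cutoff, "isc_how": how, "isc_threshold": float(threshold)},
    )
    return out, report


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample to share the across-sample mean sorted-value vector.

    Masked cells are imputed to the gene's unmasked mean first (quantile
    normalization requires complete columns; mean imputation is
    correlation-neutral).  Ties within a sample receive the mean of the
    reference values at their tied ranks.
    """
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        gene_means = np.nanmean(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), gene_means, values)
    n_genes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        ranks = pd.Series(col).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (reference[lo] + reference[hi]) / 2.0
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def preprocess_counts(
    counts: pd.DataFrame,
    gene_lengths: pd.Series | np.ndarray,
    pseudocount: float = 1.0,
    outlier_sd: float = 2.5,
    isc_sd: float = 2.0,
    isc_how: str = "mean",
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full preprocessing pipeline from a count matrix to network-ready expression.

    TPM -> log2(+pseudocount) -> zero-variance removal -> iterative 2.5 SD
    outlier masking -> 2 SD ISC sample filter -> quantile normalization.
    """
    tpm = counts_to_tpm(counts, gene_lengths)
    logged, n_zero_var = log_transform(tpm, pseudocount=pseudocount)
    masked, mask_report = iterative_outlier_mask(logged, sd_cutoff=outlier_sd)
    filtered, isc_report = filter_samples_by_isc(masked, sd_cutoff=isc_sd, how=isc_how)
    normalized = quantile_normalize(filtered)
    report = PreprocessReport(
        genes_removed_zero_variance=n_zero_var,
        cells_masked_per_iteration=mask_report.cells_masked_per_iteration,
        genes_dropped_low_coverage=mask_report.genes_dropped_low_coverage,
        samples_removed=isc_report.samples_removed,
        parameters={
            "pseudocount": pseudocount,
            "outlier_sd": outlier_sd,
            "isc_sd": isc_sd,
            "isc_how": isc_how,
        },
    )
    return normalized, report
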