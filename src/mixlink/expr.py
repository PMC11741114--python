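"""Gene count filtering and normalization.

Raw input is a genes x samples matrix of non-negative integer read counts.
Genes passing the count filter are normalized either by log-CPM followed by
full quantile normalization (default, covariate-free) or by a
covariate-conditional variant that first removes the smoothed dependence of
log-rates on a per-gene covariate (length or GC fraction) estimated by
quantile-binned medians, then quantile-normalizes. The covariate-conditional
method is a deliberately simple one-covariate normalization, not a
reimplementation of full conditional quantile normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExprMatrix", "GeneFilterReport", "filter_genes", "normalize_expression"]


@dataclass
class ExprMatrix:
    """Genes x samples counts (raw integers) or normalized expression (reals)."""

    counts: pd.DataFrame
    gene_covariate: pd.Series | None = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicated gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicated sample ids")
        if not self.normalized and (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.gene_covariate is not None:
            self.gene_covariate = self.gene_covariate.reindex(self.counts.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class GeneFilterReport:
    n_input: int
    n_retained: int
    low_mean: int
    low_total: int
    too_many_zeros: int

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained


def filter_genes(expr: ExprMatrix, min_mean: float = 5.0, min_total: float = 10.0,
                 max_zero_frac: float = 0.6) -> tuple[ExprMatrix, GeneFilterReport]:
    """Keep genes with mean count >= 5, total count >= 10 and zeros in at
    most 60% of samples (a gene with zeros in *more than* 60% is excluded).

    A gene may fail several rules; the report tallies each rule but the gene
    counts once as excluded.
    """
    if expr.normalized:
        raise ValueError("filter_genes expects raw counts, got a normalized matrix")
    C = expr.counts.to_numpy()
    if not np.issubdtype(C.dtype, np.integer):
        if not np.allclose(C, np.round(C)):
            raise ValueError("counts must be integers")
        C = C.astype(np.int64)
    mean_ok = C.mean(axis=1) >= min_mean
    total_ok = C.sum(axis=1) >= min_total
    zero_frac = (C == 0).mean(axis=1)
    zeros_ok = zero_frac <= max_zero_frac
    keep = mean_ok & total_ok & zeros_ok
    report = GeneFilterReport(
        n_input=C.shape[0],
        n_retained=int(keep.sum()),
        low_mean=int((~mean_ok).sum()),
        low_total=int((~total_ok).sum()),
        too_many_zeros=int((~zeros_ok).sum()),
    )
    cov = None if expr.gene_covariate is None else expr.gene_covariate[keep]
    out = ExprMatrix(counts=expr.counts.loc[keep], gene_covariate=cov,
                     meta=dict(expr.meta, filtered=True))
    return out, report


def _quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Full quantile normalization across columns.

    Every sample's sorted value vector becomes the mean sorted vector, so the
    per-sample distributions are exactly identical afterwards. Ties within a
    sample are ordered stably by row position, so they receive adjacent
    reference values deterministically.
    """
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        out[order, j] = ref
    return out


def normalize_expression(expr: ExprMatrix, method: str = "log_cpm_quantile",
                         n_bins: int = 10) -> ExprMatrix:
    """Normalize filtered counts to a comparable log scale across samples.

    ``log_cpm_quantile``: log2 counts-per-million with a 0.5-count offset,
    then full quantile normalization (every sample ends with the identical
    sorted value vector).

    ``covariate_quantile``: the same log-rates, minus the per-gene covariate
    trend estimated as the median log-rate within ``n_bins`` covariate
    quantile bins (interpolated between bin centers), then full quantile
    normalization. Requires ``gene_covariate``.
    """
    if method not in ("log_cpm_quantile", "covariate_quantile"):
        raise ValueError(f"unknown method {method!r}")
    C = expr.counts.to_numpy(dtype=float)
    lib = C.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero total counts")
    lograte = np.log2((C + 0.5) / lib[None, :] * 1e6)

    if method == "covariate_quantile":
        if expr.gene_covariate is None or expr.gene_covariate.isna().any():
            raise ValueError("covariate_quantile requires a complete gene_covariate")
        cov = expr.gene_covariate.to_numpy(dtype=float)
        gene_mean = lograte.mean(axis=1)
        # binned median regression of mean log-rate on the covariate
        edges = np.quantile(cov, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        bins = np.clip(np.searchsorted(edges, cov, side="right") - 1, 0, len(edges) - 2)
        centers, medians = [], []
        for b in range(len(edges) - 1):
            in_bin = bins == b
            if in_bin.any():
                centers.append(np.median(cov[in_bin]))
                medians.append(np.median(gene_mean[in_bin]))
        trend = np.interp(cov, centers, medians)
        lograte = lograte - (trend - np.median(gene_mean))[:, None]

    norm = _quantile_normalize(lograte)
    return ExprMatrix(
        counts=pd.DataFrame(norm, index=expr.counts.index, columns=expr.counts.columns),
        gene_covariate=expr.gene_covariate,
        normalized=True,
        meta=dict(expr.meta, normalization=method, log_offset=0.5),
    )
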