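"""Chemical-fingerprint preprocessing: detection filter, kNN imputation,
standardization and PCA quality control.

The chemical block is a samples x chemicals concentration table in which
"absent" and "below detection limit" are both encoded as missing (NaN); no
LOD substitution is applied, since imputation subsumes substitution. The
fixed pipeline order is filter -> impute -> standardize: standardizing a
table that still contains missing values is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "ChemTable",
    "FilterReport",
    "filter_chemicals",
    "detection_summary",
    "knn_impute",
    "standardize",
    "pca_qc",
]


@dataclass
class ChemTable:
    """Samples x chemicals concentrations; missing entries are NaN.

    ``chemical_class`` optionally labels each chemical (e.g. PAH,
    pharmaceutical). ``meta`` carries provenance notes added by the
    preprocessing steps.
    """

    values: pd.DataFrame
    chemical_class: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicated sample ids in chemical table")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicated chemical ids in chemical table")
        observed = self.values.to_numpy(dtype=float)
        bad = ~np.isfinite(observed) & ~np.isnan(observed)
        if bad.any():
            raise ValueError("chemical table contains non-finite observed values")
        if self.chemical_class is not None:
            self.chemical_class = self.chemical_class.reindex(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def chemical_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_excluded: int
    detection_fraction: pd.Series            # per input chemical, fraction of samples observed
    exclusions: pd.Series                    # excluded chemical -> reason

    def __post_init__(self) -> None:
        assert self.n_input == self.n_retained + self.n_excluded

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"detection_fraction": self.detection_fraction})
        df["excluded"] = df.index.isin(self.exclusions.index)
        df["reason"] = self.exclusions.reindex(df.index).fillna("")
        return df


def filter_chemicals(table: ChemTable, max_missing_frac: float = 0.5) -> tuple[ChemTable, FilterReport]:
    """Drop chemicals missing (absent or below detection) in more than
    ``max_missing_frac`` of the samples.

    The inequality is strict: a chemical missing in exactly 50% of samples is
    retained under the default threshold.
    """
    if table.values.empty:
        raise ValueError("empty chemical table")
    if not (0.0 < max_missing_frac < 1.0):
        raise ValueError(f"max_missing_frac must be in (0, 1), got {max_missing_frac}")
    miss_frac = table.values.isna().mean(axis=0)
    keep = miss_frac <= max_missing_frac
    excluded = miss_frac.index[~keep]
    reasons = pd.Series(
        [f"missing in {miss_frac[c]:.1%} of samples (> {max_missing_frac:.0%})" for c in excluded],
        index=excluded, dtype=object,
    )
    out = ChemTable(
        values=table.values.loc[:, keep],
        chemical_class=None if table.chemical_class is None else table.chemical_class[keep],
        meta=dict(table.meta, filtered=True, max_missing_frac=max_missing_frac),
    )
    report = FilterReport(
        n_input=table.values.shape[1],
        n_retained=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        detection_fraction=1.0 - miss_frac,
        exclusions=reasons,
    )
    return out, report


def detection_summary(table: ChemTable) -> dict[str, int]:
    """Count ubiquitous and single-site chemicals.

    Returns ``n_detected`` (chemicals observed in at least one sample),
    ``n_ubiquitous`` (observed in every sample) and ``n_exclusive``
    (observed in exactly one sample).
    """
    obs = table.values.notna().sum(axis=0)
    n = table.values.shape[0]
    return {
        "n_detected": int((obs > 0).sum()),
        "n_ubiquitous": int((obs == n).sum()),
        "n_exclusive": int((obs == 1).sum()),
    }


def knn_impute(table: ChemTable, k: int = 5, distance_weighted: bool = False) -> ChemTable:
    """Impute missing entries from the k nearest samples.

    Distance between two samples is the Euclidean norm over chemicals
    observed in both, after standardizing each chemical with its
    observed-entry mean and (n-1) standard deviation. For each missing entry
    the k nearest samples *with that chemical observed* contribute; their
    values are averaged uniformly (or inverse-distance weighted when
    ``distance_weighted``). Ties in distance break by sample order. Observed
    entries are never altered.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    vals = table.values.to_numpy(dtype=float)
    n, p = vals.shape
    obs = ~np.isnan(vals)
    n_obs = obs.sum(axis=0)
    short = n_obs < k
    if short.any():
        names = list(table.values.columns[short])
        raise ValueError(
            f"chemicals observed in fewer than k={k} samples: {names[:5]}"
            f"{'...' if len(names) > 5 else ''}; run filter_chemicals first"
        )
    if obs.all():
        return table

    mu = np.nanmean(vals, axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(vals, axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (vals - mu) / sd_safe

    # pairwise distances over co-observed standardized chemicals
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            if both.any():
                d = np.sqrt(np.sum((z[i, both] - z[j, both]) ** 2))
            else:
                d = np.inf
            dist[i, j] = dist[j, i] = d

    out = vals.copy()
    order = np.arange(n)
    for j in range(p):
        miss_rows = np.where(~obs[:, j])[0]
        if miss_rows.size == 0:
            continue
        donors = np.where(obs[:, j])[0]
        for i in miss_rows:
            # stable sort on (distance, sample order) — ties by sample-id order
            d = dist[i, donors]
            idx = np.lexsort((order[donors], d))[:k]
            chosen = donors[idx]
            if distance_weighted:
                w = 1.0 / np.maximum(dist[i, chosen], 1e-12)
                out[i, j] = float(np.average(vals[chosen, j], weights=w))
            else:
                out[i, j] = float(np.mean(vals[chosen, j]))
    return ChemTable(
        values=pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        chemical_class=table.chemical_class,
        meta=dict(table.meta, imputed=True, knn_k=k, knn_weighted=distance_weighted),
    )


def standardize(table: ChemTable) -> ChemTable:
    """Center each chemical to mean 0 and scale to unit (n-1) standard deviation."""
    if table.values.isna().to_numpy().any():
        raise ValueError("missing values present; impute before standardizing")
    sd = table.values.std(axis=0, ddof=1)
    constant = sd[sd == 0]
    if len(constant) > 0:
        raise ValueError(f"constant chemical column(s): {list(constant.index)[:5]}")
    z = (table.values - table.values.mean(axis=0)) / sd
    return ChemTable(
        values=z,
        chemical_class=table.chemical_class,
        meta=dict(table.meta, standardized=True, sd_convention="sample (ddof=1)"),
    )


def pca_qc(table: ChemTable, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples on the top principal components of the fingerprint.

    Returns per-sample scores and the fraction of variance each component
    explains (non-increasing, summing to at most 1). Intended as the
    similarity QC view of the standardized fingerprint.
    """
    X = table.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute before PCA")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=table.values.index, columns=cols),
        pca.explained_variance_ratio_,
    )
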