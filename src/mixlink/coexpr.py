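"""Bootstrap-ensemble coexpression network and module detection.

Each ensemble run bootstraps the samples, perturbs the expression matrix
with Gaussian noise scaled to each gene's standard deviation, computes
Pearson correlations, and thresholds them at the correlation cutoff that
makes the run's network closest to scale-free (log-log linear degree
distribution). Edges retained in at least ``consensus_frac`` of the runs
form the consensus network, whose edge weights are the retention fractions.
Gene modules are communities of this weighted network under the map
equation (Infomap).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

from .expr import ExprMatrix

__all__ = [
    "EnsembleConfig",
    "ConsensusNetwork",
    "ModulePartition",
    "perturbed_bootstrap_correlation",
    "select_scale_free_threshold",
    "build_consensus_network",
    "detect_modules",
]

_DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.30, 0.91, 0.05), 2))


@dataclass(frozen=True)
class EnsembleConfig:
    """Knobs of the ensemble: run count, perturbation scale, threshold grid,
    consensus rule and scale-free fit target."""

    n_runs: int = 50
    noise_sd: float = 0.1                       # in units of per-gene sd
    candidate_thresholds: tuple[float, ...] = _DEFAULT_THRESHOLDS
    consensus_frac: float = 0.5
    r2_target: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValueError(f"n_runs must be >= 1, got {self.n_runs}")
        ts = list(self.candidate_thresholds)
        if not ts or any(not (0 < t < 1) for t in ts):
            raise ValueError("candidate_thresholds must be in (0, 1)")
        if ts != sorted(ts):
            raise ValueError("candidate_thresholds must be sorted ascending")
        if not (0 < self.consensus_frac <= 1):
            raise ValueError(f"consensus_frac must be in (0, 1], got {self.consensus_frac}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class ConsensusNetwork:
    """Undirected consensus graph over genes; no self-loops."""

    nodes: pd.Index                              # gene ids
    edges: pd.DataFrame                          # columns gene_a, gene_b, support (final edges)
    edge_support: dict[tuple[str, str], float]   # every edge seen in >= 1 run
    run_thresholds: list[float]
    n_runs: int
    consensus_frac: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_igraph(self) -> ig.Graph:
        idx = {g: i for i, g in enumerate(self.nodes)}
        es = [(idx[a], idx[b]) for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])]
        g = ig.Graph(n=len(self.nodes), edges=es, directed=False)
        g.vs["name"] = list(self.nodes)
        g.es["weight"] = list(self.edges["support"])
        return g


@dataclass
class ModulePartition:
    """Gene -> module id; 0 marks genes not assigned to any module
    (isolated or in communities below the minimum size). Module ids are
    1..M ordered by descending size."""

    assignment: pd.Series
    min_module_size: int = 10

    @property
    def module_sizes(self) -> pd.Series:
        s = self.assignment[self.assignment > 0].value_counts().sort_index()
        s.name = "size"
        return s

    def members(self, module_id: int) -> pd.Index:
        return self.assignment.index[self.assignment == module_id]


def perturbed_bootstrap_correlation(expr: ExprMatrix, noise_sd: float = 0.1,
                                    seed: int = 0, bootstrap: bool = True) -> pd.DataFrame:
    """Gene-gene Pearson correlation on a bootstrapped, noise-perturbed matrix.

    Samples are resampled with replacement to the original n (skipped in
    full-data mode, ``bootstrap=False``); noise is N(0, (noise_sd * per-gene
    sd)^2). Genes with zero variance in the resample get zero correlations
    (unit diagonal kept).
    """
    X = expr.counts.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 samples, got {n}")
    rng = np.random.default_rng(seed)
    Xb = X[:, rng.integers(0, n, size=n)] if bootstrap else X.copy()
    if noise_sd > 0:
        sd = X.std(axis=1, ddof=1)
        Xb = Xb + noise_sd * sd[:, None] * rng.standard_normal(Xb.shape)
    sb = Xb.std(axis=1)
    degenerate = sb == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(Xb)
    C = np.nan_to_num(C, nan=0.0)
    if degenerate.any():
        C[degenerate, :] = 0.0
        C[:, degenerate] = 0.0
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=expr.counts.index, columns=expr.counts.index)


def _scale_free_fit(degrees: np.ndarray, n_bins: int = 10) -> tuple[float, float, int]:
    """R^2 and slope of the log10 p(k) vs log10 k fit over log-spaced degree
    bins with nonzero mass; degree-0 nodes excluded. Returns (r2, slope,
    n_bins_used); r2 is NaN when fewer than 3 usable bins."""
    k = degrees[degrees > 0]
    if k.size == 0 or k.max() == k.min():
        return float("nan"), float("nan"), 0
    edges = np.logspace(np.log10(k.min()), np.log10(k.max()), max(n_bins, 10) + 1)
    edges[-1] += 1e-9
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mass = counts > 0
    if mass.sum() < 3:
        return float("nan"), float("nan"), int(mass.sum())
    x = np.log10(centers[mass])
    y = np.log10(counts[mass] / counts.sum() / widths[mass])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return r2, float(slope), int(mass.sum())


def select_scale_free_threshold(corr: pd.DataFrame | np.ndarray,
                                candidate_thresholds=_DEFAULT_THRESHOLDS,
                                r2_target: float = 0.8) -> tuple[float, pd.DataFrame]:
    """Pick the correlation cutoff giving the most scale-free network.

    For each candidate t the graph has an edge where |r| >= t. The chosen
    threshold is the smallest t whose degree distribution fits a power law
    with R^2 >= ``r2_target`` and negative slope; if none qualifies, the
    negative-slope candidate with maximal R^2. Returns the threshold and the
    full diagnostic grid (threshold, n_edges, n_nodes, r2, slope).
    """
    A = np.abs(np.asarray(corr, dtype=float))
    np.fill_diagonal(A, 0.0)
    rows = []
    for t in candidate_thresholds:
        adj = A >= t
        deg = adj.sum(axis=1)
        n_edges = int(deg.sum()) // 2
        r2, slope, nb = _scale_free_fit(deg)
        rows.append({"threshold": float(t), "n_edges": n_edges,
                     "n_nodes": int((deg > 0).sum()), "r2": r2, "slope": slope,
                     "n_bins": nb})
    diag = pd.DataFrame(rows)
    if (diag["n_edges"] == 0).all():
        raise ValueError("all candidate thresholds give an empty graph")
    valid = diag[(diag["slope"] < 0) & diag["r2"].notna()]
    if valid.empty:
        raise ValueError("no candidate threshold yields a negative-slope degree fit")
    good = valid[valid["r2"] >= r2_target]
    chosen = float(good["threshold"].iloc[0]) if not good.empty \
        else float(valid.loc[valid["r2"].idxmax(), "threshold"])
    return chosen, diag


def build_consensus_network(expr: ExprMatrix, config: EnsembleConfig) -> ConsensusNetwork:
    """Run the full ensemble and keep edges present in >= consensus_frac of runs."""
    config.validate()
    genes = expr.counts.index
    G = len(genes)
    run_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in np.random.SeedSequence(config.seed).spawn(config.n_runs)]
    counts = np.zeros((G, G), dtype=np.uint16)
    run_thresholds: list[float] = []
    for s in run_seeds:
        C = perturbed_bootstrap_correlation(expr, noise_sd=config.noise_sd, seed=s).to_numpy()
        t, _ = select_scale_free_threshold(C, config.candidate_thresholds, config.r2_target)
        run_thresholds.append(t)
        np.fill_diagonal(C, 0.0)
        counts += (np.abs(C) >= t).astype(np.uint16)
    iu, ju = np.triu_indices(G, k=1)
    seen = counts[iu, ju] > 0
    support_all = counts[iu, ju][seen] / config.n_runs
    pairs = list(zip(genes[iu[seen]], genes[ju[seen]]))
    edge_support = {p: float(s) for p, s in zip(pairs, support_all)}
    final = support_all >= config.consensus_frac - 1e-12
    edges = pd.DataFrame({
        "gene_a": [p[0] for p, f in zip(pairs, final) if f],
        "gene_b": [p[1] for p, f in zip(pairs, final) if f],
        "support": support_all[final],
    })
    return ConsensusNetwork(nodes=genes, edges=edges, edge_support=edge_support,
                            run_thresholds=run_thresholds, n_runs=config.n_runs,
                            consensus_frac=config.consensus_frac)


def detect_modules(network: ConsensusNetwork, min_module_size: int = 10,
                   seed: int = 0, trials: int = 10) -> ModulePartition:
    """Partition the consensus network into modules with the map equation.

    Edge weights are consensus supports. Communities smaller than
    ``min_module_size`` are marked unassigned (module 0). Module ids are
    relabelled 1..M by descending size, so module 1 is always the largest.
    """
    if network.n_edges == 0:
        raise ValueError("consensus network has no edges; cannot detect modules")
    g = network.to_igraph()
    random.seed(seed)                     # igraph draws from Python's random module
    clustering = g.community_infomap(edge_weights="weight", trials=trials)
    membership = np.asarray(clustering.membership)
    assignment = pd.Series(0, index=network.nodes, dtype=int)
    labels, sizes = np.unique(membership, return_counts=True)
    keep = [(sz, lb) for lb, sz in zip(labels, sizes) if sz >= min_module_size]
    keep.sort(key=lambda x: (-x[0], x[1]))
    names = np.asarray(g.vs["name"])
    for new_id, (_, lb) in enumerate(keep, start=1):
        assignment.loc[names[membership == lb]] = new_id
    # isolated nodes never entered the graph's edge set but are in vs; nodes
    # with degree 0 end up in singleton communities -> already unassigned
    deg = np.asarray(g.degree())
    assignment.loc[names[deg == 0]] = 0
    return ModulePartition(assignment=assignment, min_module_size=min_module_size)
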