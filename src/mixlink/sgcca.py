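"""Sparse Generalized Canonical Correlation Analysis (SGCCA).

Given J >= 2 blocks of column-centered data X_j (n samples x p_j variables)
and a symmetric non-negative design matrix C = (c_jk), SGCCA finds per-block
weight vectors a_j maximizing

    sum_{j<k} c_jk * g(cov(X_j a_j, X_k a_k))

subject to ||a_j||_2 = 1 and ||a_j||_1 <= s_j * sqrt(p_j), where g is the
scheme function (horst g(x)=x, centroid g(x)=|x|, factorial g(x)=x^2). The
per-sample projections y_j = X_j a_j are the block's low-dimension
representations (LDRs); because each a_j has unit l2 norm, the squared
weights a_j^2 sum to one per block and component and measure each
variable's relative contribution to its LDR.

Optimization is block-coordinate ascent: the update of a_j maximizes the
linearized objective over the l1/l2 constraint set, whose closed-form
maximizer is soft-thresholding followed by l2 normalization with the
threshold chosen by bisection. Successive components are obtained by
projection deflation of each block against its own score.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SgccaConfig",
    "SgccaFit",
    "project_l1_l2",
    "fit_sgcca",
    "squared_weights",
    "select_contributors",
    "variance_explained",
]

_SCHEMES = ("horst", "centroid", "factorial")


@dataclass(frozen=True)
class SgccaConfig:
    n_components: int = 5
    sparsity_per_block: tuple[float, ...] = (0.5, 0.3)
    design: np.ndarray | None = None          # JxJ symmetric, zero diagonal; default all-ones off-diagonal
    scheme: str = "centroid"
    max_iter: int = 1000
    tol: float = 1e-8
    seed: int = 0

    def validate(self, block_widths: list[int]) -> None:
        J = len(block_widths)
        if len(self.sparsity_per_block) != J:
            raise ValueError(f"sparsity_per_block has {len(self.sparsity_per_block)} entries for {J} blocks")
        for s, p in zip(self.sparsity_per_block, block_widths):
            lo = 1.0 / np.sqrt(p)
            if not (lo - 1e-12 <= s <= 1.0):
                raise ValueError(f"sparsity {s} outside [1/sqrt(p), 1] = [{lo:.4f}, 1] for block width {p}")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}, got {self.scheme!r}")
        if self.design is not None:
            C = np.asarray(self.design, dtype=float)
            if C.shape != (J, J) or not np.allclose(C, C.T) or (C < 0).any() or np.diag(C).any():
                raise ValueError("design must be a JxJ symmetric non-negative matrix with zero diagonal")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class SgccaFit:
    """Fitted weights, scores (LDRs), diagnostics and derived summaries."""

    block_names: list[str]
    weights: list[pd.DataFrame]            # per block: variables x components
    scores: list[pd.DataFrame]             # per block: samples x components (LDRs)
    component_correlation: np.ndarray      # Pearson between first two blocks' LDRs
    objective_trace: list[list[float]]     # per component, per iteration
    n_components: int
    config: SgccaConfig
    warnings: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def squared_weights(self) -> list[pd.DataFrame]:
        return [w ** 2 for w in self.weights]


def project_l1_l2(v: np.ndarray, l1_budget: float, tol: float = 1e-10) -> np.ndarray:
    """Unit-l2 vector proportional to soft-thresholded v with ||u||_1 <= l1_budget.

    Maximizes u.v over {||u||_2 <= 1, ||u||_1 <= l1_budget}: u =
    S(v, lam)/||S(v, lam)||_2 with the smallest lam >= 0 (bisection)
    satisfying the l1 budget; lam = 0 when the normalized v already
    satisfies it. ``l1_budget`` must be >= 1 (the l1 ball must contain a
    unit-l2 vector). A budget of exactly 1 returns the signed indicator of
    the largest-magnitude entry (ties to the lowest index).
    """
    v = np.asarray(v, dtype=float)
    if not np.any(v):
        raise ValueError("cannot project the zero vector")
    if l1_budget < 1.0:
        raise ValueError(f"l1_budget must be >= 1, got {l1_budget}")
    u = v / np.linalg.norm(v)
    if np.sum(np.abs(u)) <= l1_budget + 1e-12:
        return u
    if l1_budget == 1.0:
        i = int(np.argmax(np.abs(v)))
        out = np.zeros_like(v)
        out[i] = np.sign(v[i])
        return out
    absv = np.abs(v)
    lo, hi = 0.0, float(absv.max())

    def unit(lam: float) -> np.ndarray:
        s = np.sign(v) * np.maximum(absv - lam, 0.0)
        nrm = np.linalg.norm(s)
        return s / nrm if nrm > 0 else s

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.sum(np.abs(unit(mid))) <= l1_budget:
            hi = mid
        else:
            lo = mid
        if hi - lo <= tol * max(1.0, absv.max()):
            break
    return unit(hi)


def _scheme_weight(cov: float, scheme: str) -> float:
    if scheme == "horst":
        return 1.0
    if scheme == "centroid":
        return float(np.sign(cov)) if cov != 0 else 1.0
    return 2.0 * cov                                   # factorial


def _g(cov: float, scheme: str) -> float:
    if scheme == "horst":
        return cov
    if scheme == "centroid":
        return abs(cov)
    return cov * cov


def _objective(Y: list[np.ndarray], C: np.ndarray, scheme: str, n: int) -> float:
    J = len(Y)
    total = 0.0
    for j in range(J):
        for k in range(j + 1, J):
            if C[j, k] > 0:
                total += C[j, k] * _g(float(Y[j] @ Y[k]) / (n - 1), scheme)
    return total


def fit_sgcca(blocks, config: SgccaConfig = SgccaConfig(),
              block_names: list[str] | None = None) -> SgccaFit:
    """Fit SGCCA by block-coordinate ascent with projection deflation.

    ``blocks`` is a list of samples x variables matrices (DataFrames or
    arrays) with equal sample counts; columns are centered here if they are
    not already. Initialization is each block's first right singular vector
    (deterministic), with a seeded random fallback for degenerate blocks.
    The objective trace is non-decreasing per component; non-convergence at
    ``max_iter`` and early stops from rank-deficient deflation are recorded
    as warnings on the fit, not raised.
    """
    mats, var_ids, sample_ids = [], [], None
    for b in blocks:
        if isinstance(b, pd.DataFrame):
            mats.append(b.to_numpy(dtype=float))
            var_ids.append(list(b.columns))
            sample_ids = list(b.index) if sample_ids is None else sample_ids
        else:
            arr = np.asarray(b, dtype=float)
            mats.append(arr)
            var_ids.append([f"v{i}" for i in range(arr.shape[1])])
    J = len(mats)
    if J < 2:
        raise ValueError("need at least two blocks")
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("blocks must share the sample dimension")
    config.validate([m.shape[1] for m in mats])
    C = (np.ones((J, J)) - np.eye(J)) if config.design is None else np.asarray(config.design, dtype=float)
    if block_names is None:
        block_names = [f"block{j + 1}" for j in range(J)]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]

    rng = np.random.default_rng(config.seed)
    X = [m - m.mean(axis=0) for m in mats]
    budgets = [s * np.sqrt(m.shape[1]) for s, m in zip(config.sparsity_per_block, mats)]

    fit_warnings: list[str] = []
    all_weights = [np.zeros((m.shape[1], config.n_components)) for m in mats]
    all_scores = [np.zeros((n, config.n_components)) for _ in mats]
    traces: list[list[float]] = []
    n_fitted = 0

    for comp in range(config.n_components):
        # init: first right singular vector, random fallback
        a = []
        degenerate = False
        for j, Xj in enumerate(X):
            norms = np.linalg.norm(Xj)
            if norms < 1e-12:
                degenerate = True
                break
            try:
                _, _, Vt = np.linalg.svd(Xj, full_matrices=False)
                v0 = Vt[0]
            except np.linalg.LinAlgError:
                v0 = rng.standard_normal(Xj.shape[1])
            a.append(project_l1_l2(v0, budgets[j]))
        if degenerate:
            fit_warnings.append(f"component {comp + 1}: rank-deficient block after deflation; stopping early")
            break
        Y = [Xj @ aj for Xj, aj in zip(X, a)]
        trace = [_objective(Y, C, config.scheme, n)]
        converged = False
        for _ in range(config.max_iter):
            for j in range(J):
                z = np.zeros(n)
                for k in range(J):
                    if k != j and C[j, k] > 0:
                        covjk = float(Y[j] @ Y[k]) / (n - 1)
                        z += C[j, k] * _scheme_weight(covjk, config.scheme) * Y[k]
                grad = X[j].T @ z
                if np.any(grad):
                    a[j] = project_l1_l2(grad, budgets[j])
                    Y[j] = X[j] @ a[j]
            obj = _objective(Y, C, config.scheme, n)
            trace.append(obj)
            if obj - trace[-2] < config.tol:
                converged = True
                break
        if not converged:
            fit_warnings.append(f"component {comp + 1}: no convergence within max_iter={config.max_iter}")
        # sign convention: largest-magnitude weight entry positive
        for j in range(J):
            i = int(np.argmax(np.abs(a[j])))
            if a[j][i] < 0:
                a[j] = -a[j]
                Y[j] = -Y[j]
        for j in range(J):
            all_weights[j][:, comp] = a[j]
            all_scores[j][:, comp] = Y[j]
        traces.append(trace)
        n_fitted = comp + 1
        # projection deflation against the block's own score
        for j in range(J):
            denom = float(Y[j] @ Y[j])
            if denom > 1e-12:
                X[j] = X[j] - np.outer(Y[j], (Y[j] @ X[j]) / denom)

    if n_fitted == 0:
        raise ValueError("no components could be fitted (degenerate blocks)")

    comp_cols = [f"LDR{k + 1}" for k in range(n_fitted)]
    weights = [pd.DataFrame(w[:, :n_fitted], index=ids, columns=comp_cols)
               for w, ids in zip(all_weights, var_ids)]
    scores = [pd.DataFrame(s[:, :n_fitted], index=sample_ids, columns=comp_cols)
              for s in all_scores]
    corr = np.zeros(n_fitted)
    for k in range(n_fitted):
        y0, y1 = all_scores[0][:, k], all_scores[1][:, k]
        if y0.std() > 0 and y1.std() > 0:
            corr[k] = float(np.corrcoef(y0, y1)[0, 1])
    return SgccaFit(
        block_names=block_names,
        weights=weights,
        scores=scores,
        component_correlation=corr,
        objective_trace=traces,
        n_components=n_fitted,
        config=config,
        warnings=fit_warnings,
        meta={"deflation": "projection against own score",
              "sign_convention": "largest-magnitude weight positive"},
    )


def squared_weights(fit: SgccaFit) -> list[pd.DataFrame]:
    """Per block: variables x components squared weights (sum to 1 per column)."""
    return fit.squared_weights


def select_contributors(fit: SgccaFit, block: int = 0, component: int | str = 1,
                        sw_cutoff: float = 0.01) -> pd.Series:
    """Variables whose squared weight exceeds the cutoff, ranked by SW."""
    col = component if isinstance(component, str) else f"LDR{component}"
    sw = fit.squared_weights[block][col]
    return sw[sw > sw_cutoff].sort_values(ascending=False)


def variance_explained(fit: SgccaFit, gene_block, chem_scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fraction of total gene-block variance explained by the chemical-side
    scores, per component and cumulative.

    Scores are orthogonalized in component order, so the cumulative fraction
    equals the R^2 of the joint regression of the (centered) gene block on
    all scores. Zero-variance gene columns are excluded with a warning.
    """
    Xg = gene_block.to_numpy(dtype=float) if isinstance(gene_block, pd.DataFrame) else np.asarray(gene_block, dtype=float)
    Xg = Xg - Xg.mean(axis=0)
    keep = Xg.std(axis=0) > 0
    if not keep.all():
        _warnings.warn(f"excluding {int((~keep).sum())} zero-variance gene columns from variance explained")
        Xg = Xg[:, keep]
    S = (fit.scores[0] if chem_scores is None else chem_scores).to_numpy(dtype=float)
    S = S - S.mean(axis=0)
    Q, R = np.linalg.qr(S)
    # guard rank deficiency: zero out directions with negligible diagonal
    ok = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    total = float(np.sum(Xg ** 2))
    fracs = np.zeros(S.shape[1])
    for k in range(S.shape[1]):
        if ok[k]:
            proj = Q[:, k] @ Xg
            fracs[k] = float(np.sum(proj ** 2)) / total
    out = pd.DataFrame({
        "component": [f"LDR{k + 1}" for k in range(S.shape[1])],
        "fraction": fracs,
        "cumulative": np.cumsum(fracs),
    }).set_index("component")
    return out
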