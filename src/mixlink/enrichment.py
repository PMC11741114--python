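"""Module enrichment and pathway overrepresentation.

Per component (LDR), each coexpression module is tested for genes with
stochastically larger squared weights (SW) than genes outside the module
(one-sided Mann-Whitney U), with Benjamini-Hochberg control of the false
discovery rate across the family of (module, component) tests. Pathways are
then tested for overrepresentation within each significant module by a
Pearson chi-square on the 2x2 module x pathway table over the analyzed gene
universe, again BH-adjusted; a pathway is called enriched only when its
observed overlap also exceeds the expected overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpr import ModulePartition
from .sgcca import SgccaFit, select_contributors
from . import io as mio

__all__ = [
    "PathwayAnnotation",
    "benjamini_hochberg",
    "module_enrichment",
    "pathway_overrepresentation",
    "link_report",
    "LinkReport",
]


@dataclass
class PathwayAnnotation:
    """Pathway id -> gene set, with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [p for p, g in self.sets.items() if not g]
        if empty:
            raise ValueError(f"empty gene set(s): {empty[:5]}")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "PathwayAnnotation":
        sets, desc = mio.read_gmt(path)
        return cls(sets=sets, descriptions=desc)

    def restricted_to(self, universe: set[str]) -> "PathwayAnnotation":
        """Drop genes outside the universe and pathways left empty."""
        sets = {p: g & universe for p, g in self.sets.items()}
        sets = {p: g for p, g in sets.items() if g}
        return PathwayAnnotation(sets=sets, descriptions={p: self.descriptions.get(p, "") for p in sets})


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjustment, returned in input order and clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _mannwhitney_greater(x: np.ndarray, y: np.ndarray,
                         max_enumeration: int = 200_000) -> tuple[float, float]:
    """One-sided Mann-Whitney U (x stochastically larger) with an exact
    small-sample branch.

    When the smaller group has at most 8 values and full enumeration is
    affordable, the p-value is the exact permutation probability
    P(U >= U_obs) over all group assignments of the pooled values (tie-aware,
    ties contribute 1/2 to U). Otherwise the normal approximation with tie
    and continuity corrections is used.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled, method="average")
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    small = min(n1, n2)
    from math import comb
    if small <= 8 and comb(n1 + n2, small) <= max_enumeration:
        from itertools import combinations
        k = n1 if n1 <= n2 else n2
        total = hits = 0
        for idx in combinations(range(n1 + n2), k):
            u_small = float(ranks[list(idx)].sum() - k * (k + 1) / 2)
            u = u_small if k == n1 else n1 * n2 - u_small
            total += 1
            if u >= u_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return u_obs, float(res.pvalue)


def _as_sw_mapping(sw) -> dict[str, pd.Series]:
    if isinstance(sw, pd.Series):
        return {"LDR1": sw}
    if isinstance(sw, pd.DataFrame):
        return {str(c): sw[c] for c in sw.columns}
    if isinstance(sw, Mapping):
        return {str(k): pd.Series(v) for k, v in sw.items()}
    raise TypeError("sw must be a Series, DataFrame, or mapping component -> Series")


def module_enrichment(sw, partition: ModulePartition, alpha: float = 0.05,
                      per_component_fdr: bool = False) -> pd.DataFrame:
    """Mann-Whitney enrichment of high-SW genes per (module, component).

    ``sw`` is a gene -> SW Series for one component, a genes x components
    DataFrame, or a mapping component -> Series; every partitioned gene must
    have an SW value. The alternative is one-sided: module genes have larger
    SWs. The exact permutation null is enumerated when the smaller group has
    at most 8 genes (tie-aware); otherwise the normal approximation with tie
    and continuity corrections. BH adjustment is applied across the whole
    (module, component) family by default (per-component families via
    ``per_component_fdr``).
    """
    by_comp = _as_sw_mapping(sw)
    modules = partition.module_sizes.index
    if len(modules) == 0:
        raise ValueError("partition has no modules")
    rows = []
    for comp, s in by_comp.items():
        missing = partition.assignment.index.difference(s.index)
        if len(missing) > 0:
            raise ValueError(f"SW missing for {len(missing)} partitioned genes (component {comp})")
        s = s.reindex(partition.assignment.index)
        for m in modules:
            in_mod = partition.assignment == m
            x = s[in_mod].to_numpy()
            y = s[~in_mod].to_numpy()
            if y.size == 0:
                raise ValueError(f"module {m} equals the entire gene set; no out-group")
            u, p = _mannwhitney_greater(x, y)
            rows.append({
                "module": int(m), "component": comp, "module_size": int(in_mod.sum()),
                "U": u, "p_value": p,
                "median_sw_in": float(np.median(x)), "median_sw_out": float(np.median(y)),
            })
    table = pd.DataFrame(rows)
    if per_component_fdr:
        table["adj_p_value"] = np.nan
        for comp in by_comp:
            mask = table["component"] == comp
            table.loc[mask, "adj_p_value"] = benjamini_hochberg(table.loc[mask, "p_value"])
    else:
        table["adj_p_value"] = benjamini_hochberg(table["p_value"])
    table["significant"] = table["adj_p_value"] < alpha
    return table


def pathway_overrepresentation(module_genes: set[str], universe: set[str],
                               annotation: PathwayAnnotation, alpha: float = 0.05,
                               min_overlap: int = 3) -> pd.DataFrame:
    """Chi-square overrepresentation of each pathway in one module.

    The 2x2 table counts the universe by module membership x pathway
    membership; Pearson chi-square without continuity correction. Pathways
    overlapping the module in fewer than ``min_overlap`` genes are skipped
    (reported with NaN statistics). Enriched means BH-adjusted p < alpha AND
    observed overlap above expectation. Cells with expected count < 5 are
    flagged, not suppressed.
    """
    if not universe:
        raise ValueError("empty gene universe")
    module_genes = set(module_genes)
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    ann = annotation.restricted_to(universe)
    N, nm = len(universe), len(module_genes)
    rows = []
    for pid, genes in ann.sets.items():
        a = len(module_genes & genes)                    # in module, in pathway
        b = nm - a                                       # in module, not pathway
        c = len(genes) - a                               # not module, in pathway
        d = N - a - b - c
        expected_a = nm * len(genes) / N
        row = {"pathway": pid, "description": ann.descriptions.get(pid, ""),
               "n_in_module_in_pathway": a, "n_in_module_not_pathway": b,
               "n_not_module_in_pathway": c, "n_not_module_not_pathway": d,
               "expected_overlap": expected_a}
        if a < min_overlap:
            row.update({"chi2": np.nan, "p_value": np.nan, "skipped": True, "low_expected": False})
        else:
            obs = np.array([[a, b], [c, d]], dtype=float)
            exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
            if (exp == 0).any():
                chi2, p = 0.0, 1.0
            else:
                chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
            row.update({"chi2": float(chi2), "p_value": float(p), "skipped": False,
                        "low_expected": bool((exp < 5).any())})
        rows.append(row)
    table = pd.DataFrame(rows)
    tested = ~table["skipped"]
    table["adj_p_value"] = np.nan
    if tested.any():
        table.loc[tested, "adj_p_value"] = benjamini_hochberg(table.loc[tested, "p_value"])
    table["enriched"] = (
        tested
        & (table["adj_p_value"] < alpha)
        & (table["n_in_module_in_pathway"] > table["expected_overlap"])
    )
    return table.sort_values("p_value", na_position="last").reset_index(drop=True)


@dataclass
class LinkReport:
    """Per-component linkage summary: contributing chemicals, significant
    modules, enriched pathways."""

    components: list[str]
    contributors: dict[str, pd.Series]           # component -> chemical SW > cutoff, ranked
    significant_modules: dict[str, list[int]]
    enriched_pathways: dict[str, pd.DataFrame]
    sw_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.components:
            paths = self.enriched_pathways.get(comp)
            rows.append({
                "component": comp,
                "n_contributing_chemicals": len(self.contributors[comp]),
                "contributing_chemicals": ";".join(self.contributors[comp].index),
                "significant_modules": ";".join(map(str, self.significant_modules[comp])),
                "n_enriched_pathways": 0 if paths is None else int(paths["enriched"].sum()),
                "enriched_pathways": "" if paths is None
                else ";".join(paths.loc[paths["enriched"], "pathway"].unique()),
            })
        return pd.DataFrame(rows).set_index("component")

    def to_text(self) -> str:
        lines = [f"Linkage summary (SW cutoff {self.sw_cutoff})", ""]
        for comp in self.components:
            lines.append(f"## {comp}")
            cont = self.contributors[comp]
            lines.append(f"contributing chemicals ({len(cont)}):")
            for name, sw in cont.items():
                lines.append(f"  {name}\tSW={sw:.4f}")
            lines.append(f"significant modules: {self.significant_modules[comp] or 'none'}")
            paths = self.enriched_pathways.get(comp)
            if paths is not None and paths["enriched"].any():
                for _, r in paths[paths["enriched"]].iterrows():
                    lines.append(f"  pathway {r['pathway']} (module {r['module']}) adj_p={r['adj_p_value']:.3g}")
            else:
                lines.append("  no enriched pathways")
            lines.append("")
        return "\n".join(lines)


def link_report(fit: SgccaFit, enrichment: pd.DataFrame,
                pathways: pd.DataFrame | None = None, sw_cutoff: float = 0.01,
                partition: ModulePartition | None = None,
                chem_block: int = 0, gene_block: int = 1) -> LinkReport:
    """Assemble the per-component summary linking chemicals to modules and
    pathways. ``pathways`` must carry 'module' and 'component' columns when
    given. A partition passed alongside is cross-checked against the fit's
    gene block variable ids."""
    gene_ids = set(fit.weights[gene_block].index)
    if partition is not None and set(partition.assignment.index) != gene_ids:
        raise ValueError("gene universe mismatch between fit and module partition")
    components = list(fit.weights[chem_block].columns)
    contributors, sig_modules, enriched = {}, {}, {}
    for comp in components:
        contributors[comp] = select_contributors(fit, block=chem_block, component=comp,
                                                 sw_cutoff=sw_cutoff)
        sig = enrichment[(enrichment["component"] == comp) & enrichment["significant"]]
        sig_modules[comp] = sorted(sig["module"].tolist())
        if pathways is not None and len(pathways) > 0:
            sub = pathways[pathways["component"] == comp]
            enriched[comp] = sub.reset_index(drop=True)
    return LinkReport(components=components, contributors=contributors,
                      significant_modules=sig_modules, enriched_pathways=enriched,
                      sw_cutoff=sw_cutoff)
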