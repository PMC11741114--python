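"""Delimited-text readers and writers for the pipeline's on-disk formats.

All tables are plain delimited text (TSV by default, comma configurable):
chemical tables have a header row of chemical ids and a first column of
sample ids; count matrices have genes in rows and samples in columns; the
missing-value token is configurable ("NA" default). Gene-set annotations use
the GMT format (set id, description, member genes, tab-separated).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .chem import ChemTable, FilterReport
from .expr import ExprMatrix

__all__ = [
    "read_chem_table", "write_chem_table",
    "read_count_matrix", "write_count_matrix",
    "read_gene_covariate", "write_filter_report",
    "read_gmt", "write_edge_list", "write_partition",
]


def read_chem_table(path: str | Path, sep: str = "\t", missing_token: str = "NA",
                    class_path: str | Path | None = None) -> ChemTable:
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=[missing_token],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = None
    classes = None
    if class_path is not None:
        cs = pd.read_csv(class_path, sep=sep, index_col=0)
        classes = cs.iloc[:, 0]
    return ChemTable(values=df, chemical_class=classes)


def write_chem_table(table: ChemTable, path: str | Path, sep: str = "\t",
                     missing_token: str = "NA") -> None:
    table.values.to_csv(path, sep=sep, na_rep=missing_token, index_label="sample_id")


def read_count_matrix(path: str | Path, sep: str = "\t",
                      covariate_path: str | Path | None = None) -> ExprMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    cov = None
    if covariate_path is not None:
        cov = read_gene_covariate(covariate_path, sep=sep)
    normalized = bool(df.dtypes.apply(lambda t: t.kind == "f").any())
    return ExprMatrix(counts=df, gene_covariate=cov, normalized=normalized)


def write_count_matrix(expr: ExprMatrix, path: str | Path, sep: str = "\t") -> None:
    expr.counts.to_csv(path, sep=sep, index_label="gene_id")


def read_gene_covariate(path: str | Path, sep: str = "\t") -> pd.Series:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df.iloc[:, 0]


def write_filter_report(report: FilterReport, path: str | Path, sep: str = "\t") -> None:
    report.to_frame().to_csv(path, sep=sep, index_label="chemical_id")


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse a GMT file into (pathway -> gene set, pathway -> description)."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need id, description, >=1 gene): {line[:80]!r}")
        pid, d, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if pid in sets:
            raise ValueError(f"duplicate pathway id {pid!r}")
        if not genes:
            raise ValueError(f"pathway {pid!r} has an empty gene set")
        sets[pid] = set(genes)
        desc[pid] = d
    return sets, desc


def write_edge_list(edges: dict[tuple[str, str], float], path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["gene_a", "gene_b", "support"]) + "\n")
        for (a, b), s in sorted(edges.items()):
            fh.write(sep.join([a, b, f"{s:.6g}"]) + "\n")


def write_partition(assignment: pd.Series, path: str | Path, sep: str = "\t") -> None:
    assignment.rename("module_id").to_csv(path, sep=sep, index_label="gene_id")
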