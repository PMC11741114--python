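"""End-to-end pipeline orchestration with reproducibility metadata.

Stages run in a fixed order — chemical preprocessing, expression
preprocessing, consensus coexpression network, SGCCA, enrichment, linkage
report — each persisting its outputs as delimited text under the run
directory. A manifest records the config snapshot, per-stage dimensions,
warnings and output checksums; identical configs yield identical manifests.
The global seed fans out to per-stage seeds through a stage-name-keyed hash
so any stage can be rerun standalone and reproduce its pipeline-level
result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .chem import ChemTable, filter_chemicals, knn_impute, standardize, pca_qc
from .coexpr import EnsembleConfig, build_consensus_network, detect_modules
from .enrichment import PathwayAnnotation, link_report, module_enrichment, pathway_overrepresentation
from .expr import filter_genes, normalize_expression
from .sgcca import SgccaConfig, fit_sgcca, variance_explained

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_inputs", "stage_seed"]

logger = logging.getLogger("mixlink")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    chem_table: str | None = None
    count_matrix: str | None = None
    gene_covariate: str | None = None
    gmt: str | None = None
    output_dir: str = "mixlink_run"
    synthetic: "object | None" = None            # SynthConfig for synthetic mode
    sep: str = "\t"
    missing_token: str = "NA"
    max_missing_frac: float = 0.5
    knn_k: int = 5
    normalization: str = "log_cpm_quantile"
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    min_module_size: int = 10
    sgcca: SgccaConfig = field(default_factory=SgccaConfig)
    alpha: float = 0.05
    sw_cutoff: float = 0.01
    min_overlap: int = 3
    enrichment_enabled: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None:
            for name in ("chem_table", "count_matrix"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} path missing or not found: {p}")
        if self.enrichment_enabled and self.gmt is None:
            raise ValueError("gmt path required when enrichment is enabled")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise ValueError(f"gmt path not found: {self.gmt}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value config file ('#' starts a comment).

        Nested keys use dotted names, e.g. ``ensemble.n_runs = 25`` or
        ``sgcca.n_components = 5``.
        """
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
        cfg = cls()
        ens, sg = {}, {}
        for k, v in kv.items():
            if k.startswith("ensemble."):
                ens[k.split(".", 1)[1]] = v
            elif k.startswith("sgcca."):
                sg[k.split(".", 1)[1]] = v
            elif hasattr(cfg, k):
                current = getattr(cfg, k)
                setattr(cfg, k, _coerce(v, current))
            else:
                raise ValueError(f"unknown config key: {k}")
        if ens:
            base = dataclasses.asdict(cfg.ensemble)
            base.update({k: _coerce(v, base[k]) for k, v in ens.items()})
            base["candidate_thresholds"] = tuple(base["candidate_thresholds"])
            cfg.ensemble = EnsembleConfig(**base)
        if sg:
            base = {f.name: getattr(cfg.sgcca, f.name) for f in dataclasses.fields(SgccaConfig)}
            base.update({k: _coerce(v, base[k]) for k, v in sg.items()})
            cfg.sgcca = SgccaConfig(**base)
        return cfg


def _coerce(text: str, like):
    if isinstance(like, bool):
        return text.lower() in ("1", "true", "yes")
    if isinstance(like, int):
        return int(text)
    if isinstance(like, float):
        return float(text)
    if isinstance(like, tuple):
        parts = [p for p in text.replace(",", " ").split() if p]
        return tuple(type(like[0])(p) for p in parts) if like else tuple(float(p) for p in parts)
    return text


@dataclass
class RunManifest:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path], **info) -> None:
        checksums = {name: _sha256(p) for name, p in outputs.items()}
        self.stages[stage] = {"outputs": {k: str(v) for k, v in outputs.items()},
                              "checksums": checksums, **info}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages, "warnings": self.warnings},
            indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def validate_inputs(chem_path: str | Path, expr_path: str | Path,
                    gmt_path: str | Path | None = None, sep: str = "\t",
                    missing_token: str = "NA") -> dict:
    """Check parseability, id uniqueness, sample concordance and GMT form.

    Returns a report with ``defects`` (must be empty to proceed) and
    ``notes`` (e.g. sample reordering applied); never raises for data
    defects.
    """
    defects: list[str] = []
    notes: list[str] = []
    chem = expr = None
    try:
        df = pd.read_csv(chem_path, sep=sep, index_col=0, na_values=[missing_token],
                         keep_default_na=False)
        if df.index.has_duplicates:
            defects.append("duplicate sample id in chemical table")
        if df.columns.has_duplicates:
            defects.append("duplicate chemical id in chemical table")
        chem = df
    except Exception as exc:
        defects.append(f"chemical table unparseable: {exc}")
    try:
        dfe = pd.read_csv(expr_path, sep=sep, index_col=0)
        if dfe.index.has_duplicates:
            defects.append("duplicate gene id in count matrix")
        if dfe.columns.has_duplicates:
            defects.append("duplicate sample id in count matrix")
        expr = dfe
    except Exception as exc:
        defects.append(f"count matrix unparseable: {exc}")
    if chem is not None and expr is not None:
        chem_samples, expr_samples = list(chem.index.astype(str)), list(expr.columns.astype(str))
        common = set(chem_samples) & set(expr_samples)
        for s in sorted(set(chem_samples) - common):
            defects.append(f"unmatched sample: {s!r} in chemical table only")
        for s in sorted(set(expr_samples) - common):
            defects.append(f"unmatched sample: {s!r} in count matrix only")
        if common and chem_samples != expr_samples and \
                sorted(chem_samples) == sorted(expr_samples):
            notes.append("sample ids match after reordering; blocks will be aligned")
    if gmt_path is not None:
        try:
            mio.read_gmt(gmt_path)
        except Exception as exc:
            defects.append(f"GMT malformed: {exc}")
    return {"defects": defects, "notes": notes, "ok": not defects}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, persisting artifacts under output_dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(config))
    stage = "setup"
    try:
        if config.synthetic is not None:
            stage = "simulate"
            from .synthetic import generate_dataset, write_fixture
            synth = dataclasses.replace(config.synthetic, seed=stage_seed(config.seed, "simulate"))
            dataset = generate_dataset(synth)
            paths = write_fixture(dataset, out / "synthetic", sep=config.sep,
                                  missing_token=config.missing_token)
            config.chem_table = str(paths["chem"])
            config.count_matrix = str(paths["expr"])
            manifest.record(stage, paths, n_samples=synth.n_samples,
                            n_chemicals=synth.n_chemicals, n_genes=synth.n_genes)

        stage = "chem_preprocess"
        chem = mio.read_chem_table(config.chem_table, sep=config.sep,
                                   missing_token=config.missing_token)
        chem_f, report = filter_chemicals(chem, config.max_missing_frac)
        chem_i = knn_impute(chem_f, k=config.knn_k)
        chem_z = standardize(chem_i)
        n_pc = min(5, len(chem_z.sample_ids) - 1, len(chem_z.chemical_ids))
        scores, evr = pca_qc(chem_z, n_components=n_pc)
        outputs = {
            "filtered": out / "chem_filtered.tsv", "report": out / "chem_filter_report.tsv",
            "standardized": out / "chem_standardized.tsv", "pca_scores": out / "chem_pca_scores.tsv",
        }
        mio.write_chem_table(chem_f, outputs["filtered"], sep=config.sep,
                             missing_token=config.missing_token)
        mio.write_filter_report(report, outputs["report"], sep=config.sep)
        mio.write_chem_table(chem_z, outputs["standardized"], sep=config.sep)
        scores.assign(**{"explained_fraction": list(evr) + [np.nan] * (len(scores) - len(evr))}) \
            .to_csv(outputs["pca_scores"], sep=config.sep)
        logger.info("chem_preprocess: %d -> %d chemicals", report.n_input, report.n_retained)
        manifest.record(stage, outputs, n_input=report.n_input, n_retained=report.n_retained)

        stage = "expr_preprocess"
        expr = mio.read_count_matrix(config.count_matrix, sep=config.sep,
                                     covariate_path=config.gene_covariate)
        expr_f, greport = filter_genes(expr)
        expr_n = normalize_expression(expr_f, method=config.normalization)
        outputs = {"normalized": out / "expr_normalized.tsv"}
        mio.write_count_matrix(expr_n, outputs["normalized"], sep=config.sep)
        logger.info("expr_preprocess: %d -> %d genes", greport.n_input, greport.n_retained)
        manifest.record(stage, outputs, n_input=greport.n_input, n_retained=greport.n_retained)

        stage = "coexpression"
        ens = dataclasses.replace(config.ensemble, seed=stage_seed(config.seed, "coexpression"))
        network = build_consensus_network(expr_n, ens)
        partition = detect_modules(network, min_module_size=config.min_module_size,
                                   seed=stage_seed(config.seed, "modules"))
        outputs = {"edges": out / "network_edges.tsv", "partition": out / "modules.tsv"}
        mio.write_edge_list(network.edge_support, outputs["edges"], sep=config.sep)
        mio.write_partition(partition.assignment, outputs["partition"], sep=config.sep)
        n_modules = int((partition.module_sizes > 0).sum())
        logger.info("coexpression: %d edges, %d modules", network.n_edges, n_modules)
        manifest.record(stage, outputs, n_edges=network.n_edges, n_modules=n_modules,
                        n_genes_in_modules=int((partition.assignment > 0).sum()))

        stage = "sgcca"
        # align samples between blocks (drop unmatched with a warning)
        chem_block = chem_z.values
        gene_block = expr_n.counts.T
        common = chem_block.index.intersection(gene_block.index)
        dropped = (len(chem_block) - len(common)) + (len(gene_block) - len(common))
        if dropped:
            manifest.warnings.append(f"sgcca: dropped {dropped} unmatched samples across blocks")
        chem_block, gene_block = chem_block.loc[common], gene_block.loc[common]
        sg = dataclasses.replace(config.sgcca, seed=stage_seed(config.seed, "sgcca"))
        fit = fit_sgcca([chem_block, gene_block], sg, block_names=["chemicals", "genes"])
        manifest.warnings.extend(fit.warnings)
        ve = variance_explained(fit, gene_block)
        outputs = {}
        for j, name in enumerate(fit.block_names):
            outputs[f"weights_{name}"] = out / f"sgcca_weights_{name}.tsv"
            outputs[f"scores_{name}"] = out / f"sgcca_scores_{name}.tsv"
            outputs[f"sw_{name}"] = out / f"sgcca_sw_{name}.tsv"
            fit.weights[j].to_csv(outputs[f"weights_{name}"], sep=config.sep)
            fit.scores[j].to_csv(outputs[f"scores_{name}"], sep=config.sep)
            fit.squared_weights[j].to_csv(outputs[f"sw_{name}"], sep=config.sep)
        outputs["correlations"] = out / "sgcca_correlations.tsv"
        pd.DataFrame({"component": list(fit.weights[0].columns),
                      "correlation": fit.component_correlation}) \
            .to_csv(outputs["correlations"], sep=config.sep, index=False)
        outputs["variance_explained"] = out / "sgcca_variance_explained.tsv"
        ve.to_csv(outputs["variance_explained"], sep=config.sep)
        logger.info("sgcca: %d components, correlations %s", fit.n_components,
                    np.round(fit.component_correlation, 3))
        manifest.record(stage, outputs, n_components=fit.n_components,
                        correlations=[float(c) for c in fit.component_correlation])

        if config.enrichment_enabled:
            stage = "enrichment"
            ann = PathwayAnnotation.from_gmt(config.gmt)
            gene_sw = fit.squared_weights[1]
            enr = module_enrichment(gene_sw, partition, alpha=config.alpha)
            universe = set(gene_block.columns)
            path_tables = []
            for _, row in enr[enr["significant"]].iterrows():
                members = set(partition.members(int(row["module"])))
                pt = pathway_overrepresentation(members, universe, ann, alpha=config.alpha,
                                                min_overlap=config.min_overlap)
                pt.insert(0, "module", int(row["module"]))
                pt.insert(0, "component", row["component"])
                path_tables.append(pt)
            pathways = pd.concat(path_tables, ignore_index=True) if path_tables else pd.DataFrame(
                columns=["component", "module", "pathway", "enriched"])
            rep = link_report(fit, enr, pathways, sw_cutoff=config.sw_cutoff,
                              partition=partition)
            outputs = {"module_enrichment": out / "module_enrichment.tsv",
                       "pathways": out / "pathway_overrepresentation.tsv",
                       "link_report": out / "link_report.tsv",
                       "summary": out / "link_summary.txt"}
            enr.to_csv(outputs["module_enrichment"], sep=config.sep, index=False)
            pathways.to_csv(outputs["pathways"], sep=config.sep, index=False)
            rep.to_frame().to_csv(outputs["link_report"], sep=config.sep)
            outputs["summary"].write_text(rep.to_text())
            logger.info("enrichment: %d significant (module, component) pairs",
                        int(enr["significant"].sum()))
            manifest.record(stage, outputs,
                            n_significant_modules=int(enr["significant"].sum()),
                            n_enriched_pathways=0 if pathways.empty else int(pathways["enriched"].sum()))
    except Exception as exc:
        manifest.warnings.append(f"stage {stage} failed: {exc}")
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    for key in ("ensemble", "sgcca", "synthetic"):
        if dataclasses.is_dataclass(getattr(config, key, None)):
            snap[key] = dataclasses.asdict(getattr(config, key))
    if isinstance(snap.get("sgcca"), dict) and snap["sgcca"].get("design") is not None:
        snap["sgcca"]["design"] = np.asarray(snap["sgcca"]["design"]).tolist()
    return snap
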