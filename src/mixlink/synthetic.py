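"""Synthetic two-block datasets with planted latent structure.

Generates paired (chemical fingerprint, gene expression) tables in which a
small number of latent sample factors drive both a sparse subset of chemicals
and module-structured gene covariation — the situation the downstream
coexpression / multiblock-correlation pipeline is designed to recover. The
generator emulates a ~30-sample field survey: a few hundred measured
chemicals with left-censoring at a per-chemical detection limit plus
completely-at-random missingness, and ~10^4 genes with negative-binomial
counts whose log-means carry the factor signal.

Every stochastic choice flows from ``SynthConfig.seed``; identical configs
produce bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ChemTable
from .expr import ExprMatrix
from . import io as mio

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "write_fixture",
    "read_fixture",
    "synthetic_survey_fingerprint",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the planted-factor generator.

    Counts must be >= 1; fractions live in [0, 1); ``n_factors`` may not
    exceed ``min(n_samples - 1, n_chemicals, n_genes)`` so the planted
    components stay identifiable.
    """

    n_samples: int = 30
    n_chemicals: int = 215
    n_genes: int = 10_000
    n_factors: int = 5
    chem_sparsity: float = 0.1
    n_modules: int = 10
    module_size_range: tuple[int, int] = (25, 100)
    factor_effect: float = 1.0
    noise_sd_chem: float = 0.5
    nb_dispersion: float = 0.2
    missing_rate: float = 0.05
    lod_quantile: float = 0.05
    baseline_log_range: tuple[float, float] = (np.log(0.5), np.log(2000.0))
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_chemicals", "n_genes", "n_factors", "n_modules"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("missing_rate", "lod_quantile"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not (0.0 < self.chem_sparsity <= 1.0):
            raise ValueError(f"chem_sparsity must be in (0, 1], got {self.chem_sparsity}")
        lo, hi = self.module_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"module_size_range must satisfy 1 <= min <= max, got {self.module_size_range}")
        if self.n_modules * hi > self.n_genes:
            raise ValueError(
                f"module_size_range: {self.n_modules} modules of up to {hi} genes "
                f"may exceed n_genes={self.n_genes}")
        cap = min(self.n_samples - 1, self.n_chemicals, self.n_genes)
        if self.n_factors > cap:
            raise ValueError(f"n_factors must be <= min(n_samples-1, n_chemicals, n_genes) = {cap}, got {self.n_factors}")
        if self.nb_dispersion < 0:
            raise ValueError(f"nb_dispersion must be >= 0, got {self.nb_dispersion}")
        if self.noise_sd_chem < 0:
            raise ValueError(f"noise_sd_chem must be >= 0, got {self.noise_sd_chem}")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside a generated dataset."""

    factor_scores: np.ndarray          # samples x factors
    chem_loadings: np.ndarray          # chemicals x factors, sparse support
    gene_loadings: np.ndarray          # genes x factors, module-structured
    module_assignment: pd.Series       # gene_id -> module id (0 = background)
    module_factor: dict[int, int]      # module id -> driving factor index
    censored_mask: pd.DataFrame        # samples x chemicals
    missing_mask: pd.DataFrame         # union mask actually applied
    expected_survivors: pd.Index       # genes whose expected mean count passes the count filter
    baseline_log_mean: np.ndarray = field(repr=False, default=None)


def generate_dataset(config: SynthConfig) -> tuple[ChemTable, ExprMatrix, GroundTruth]:
    """Draw one paired dataset from the planted-factor model.

    Chemical block: ``factor_scores @ chem_loadings.T`` plus i.i.d. Gaussian
    noise, then per-chemical left-censoring at the ``lod_quantile`` quantile
    (censored entries become missing, as below-detection values are treated as
    excludable/imputable rather than substituted) and additional MCAR
    missingness at ``missing_rate``. Gene block: negative-binomial counts
    with log-mean = per-gene baseline + factor signal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, g, f = config.n_samples, config.n_chemicals, config.n_genes, config.n_factors

    # Orthogonalized standard-normal factor scores so planted components are
    # identifiable in recovery tests; columns rescaled to unit sample variance.
    raw = rng.standard_normal((n, f))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    factor_scores = q[:, :f] * np.sqrt(n - 1)

    # Sparse chemical loadings: constant magnitude, random sign, disjoint draws
    # per factor (with replacement across factors is fine; support per factor fixed).
    support = max(1, round(config.chem_sparsity * p))
    chem_loadings = np.zeros((p, f))
    for j in range(f):
        idx = rng.choice(p, size=support, replace=False)
        chem_loadings[idx, j] = config.factor_effect * rng.choice([-1.0, 1.0], size=support)

    chem_values = factor_scores @ chem_loadings.T
    chem_values += config.noise_sd_chem * rng.standard_normal((n, p))

    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    chem_ids = [f"chem_{j + 1:04d}" for j in range(p)]
    gene_ids = [f"g{j + 1:05d}" for j in range(g)]

    # Left-censoring at the per-chemical LOD quantile, then MCAR missingness.
    if config.lod_quantile > 0:
        lod = np.quantile(chem_values, config.lod_quantile, axis=0)
        censored = chem_values < lod[None, :]
    else:
        censored = np.zeros((n, p), dtype=bool)
    mcar = rng.random((n, p)) < config.missing_rate
    missing = censored | mcar
    values = chem_values.copy()
    values[missing] = np.nan

    # Module-structured gene loadings: module m is driven by factor m mod f,
    # with a module-level sign; background genes carry no factor signal.
    sizes = rng.integers(config.module_size_range[0], config.module_size_range[1] + 1, size=config.n_modules)
    total = int(sizes.sum())
    if total > g:
        raise ValueError(f"planted modules need {total} genes but n_genes={g}")
    perm = rng.permutation(g)
    assignment = np.zeros(g, dtype=int)
    gene_loadings = np.zeros((g, f))
    module_factor: dict[int, int] = {}
    pos = 0
    for m in range(config.n_modules):
        members = perm[pos:pos + sizes[m]]
        pos += sizes[m]
        assignment[members] = m + 1
        drv = m % f
        module_factor[m + 1] = drv
        sign = rng.choice([-1.0, 1.0])
        gene_loadings[members, drv] = sign * config.factor_effect

    baseline = rng.uniform(*config.baseline_log_range, size=g)
    log_mean = baseline[None, :] + factor_scores @ gene_loadings.T
    mean = np.exp(log_mean)
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)

    # Expected survivors of the downstream average-count filter, from the
    # analytic mean E[count] = exp(baseline) * E[exp(factor signal)].
    expected_mean = (np.exp(baseline[None, :] + factor_scores @ gene_loadings.T)).mean(axis=0)
    survivors = pd.Index([gid for gid, m in zip(gene_ids, expected_mean) if m >= 5.0])

    chem = ChemTable(values=pd.DataFrame(values, index=sample_ids, columns=chem_ids))
    expr = ExprMatrix(counts=pd.DataFrame(counts.T, index=gene_ids, columns=sample_ids))
    truth = GroundTruth(
        factor_scores=factor_scores,
        chem_loadings=chem_loadings,
        gene_loadings=gene_loadings,
        module_assignment=pd.Series(assignment, index=gene_ids, name="module"),
        module_factor=module_factor,
        censored_mask=pd.DataFrame(censored, index=sample_ids, columns=chem_ids),
        missing_mask=pd.DataFrame(missing, index=sample_ids, columns=chem_ids),
        expected_survivors=survivors,
        baseline_log_mean=baseline,
    )
    return chem, expr, truth


def write_fixture(dataset: tuple[ChemTable, ExprMatrix, GroundTruth], directory: str | Path,
                  sep: str = "\t", missing_token: str = "NA") -> dict[str, Path]:
    """Persist a generated dataset as delimited text plus a JSON truth sidecar.

    Round-trips losslessly through :func:`read_fixture` / the io readers.
    """
    chem, expr, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "chem": directory / "chemicals.tsv",
        "expr": directory / "counts.tsv",
        "truth": directory / "ground_truth.json",
    }
    mio.write_chem_table(chem, paths["chem"], sep=sep, missing_token=missing_token)
    mio.write_count_matrix(expr, paths["expr"], sep=sep)
    sidecar = {
        "factor_scores": truth.factor_scores.tolist(),
        "chem_loadings": truth.chem_loadings.tolist(),
        "gene_loadings": truth.gene_loadings.tolist(),
        "module_assignment": truth.module_assignment.to_dict(),
        "module_factor": {str(k): v for k, v in truth.module_factor.items()},
        "censored_mask": truth.censored_mask.to_numpy().astype(int).tolist(),
        "missing_mask": truth.missing_mask.to_numpy().astype(int).tolist(),
        "expected_survivors": list(truth.expected_survivors),
        "sample_ids": list(truth.missing_mask.index),
        "chemical_ids": list(truth.missing_mask.columns),
        "baseline_log_mean": truth.baseline_log_mean.tolist(),
    }
    paths["truth"].write_text(json.dumps(sidecar))
    return paths


def read_fixture(directory: str | Path, sep: str = "\t",
                 missing_token: str = "NA") -> tuple[ChemTable, ExprMatrix, GroundTruth]:
    directory = Path(directory)
    chem = mio.read_chem_table(directory / "chemicals.tsv", sep=sep, missing_token=missing_token)
    expr = mio.read_count_matrix(directory / "counts.tsv", sep=sep)
    raw = json.loads((directory / "ground_truth.json").read_text())
    sample_ids, chem_ids = raw["sample_ids"], raw["chemical_ids"]
    assignment = pd.Series(raw["module_assignment"], name="module")
    truth = GroundTruth(
        factor_scores=np.asarray(raw["factor_scores"]),
        chem_loadings=np.asarray(raw["chem_loadings"]),
        gene_loadings=np.asarray(raw["gene_loadings"]),
        module_assignment=assignment,
        module_factor={int(k): v for k, v in raw["module_factor"].items()},
        censored_mask=pd.DataFrame(np.asarray(raw["censored_mask"], dtype=bool),
                                   index=sample_ids, columns=chem_ids),
        missing_mask=pd.DataFrame(np.asarray(raw["missing_mask"], dtype=bool),
                                  index=sample_ids, columns=chem_ids),
        expected_survivors=pd.Index(raw["expected_survivors"]),
        baseline_log_mean=np.asarray(raw["baseline_log_mean"]),
    )
    return chem, expr, truth


def synthetic_survey_fingerprint(seed: int = 0, n_samples: int = 30) -> ChemTable:
    """Synthetic stand-in for a 30-site field-survey fingerprint table.

    Constructs a samples x chemicals concentration table whose *detection
    profile* matches a real multi-river survey: 385 detected chemicals of
    which 90 are detected at every site, 44 at exactly one site, and 215 at
    more than half the sites (so that a 50%-missingness filter retains
    exactly 215). Concentrations are log-normal draws; only the
    detected/missing pattern is controlled. This is a synthetic object for
    exercising detection-based filters, not real measurement data.
    """
    rng = np.random.default_rng(seed)
    # detection counts per chemical (out of n_samples sites)
    counts: list[int] = []
    counts += [n_samples] * 90                                  # ubiquitous
    counts += list(rng.integers(16, n_samples, size=125))       # common, 16..29 sites
    counts += [1] * 44                                          # single-site
    counts += list(rng.integers(2, 15, size=126))               # rare, 2..14 sites
    assert len(counts) == 385
    classes = (["inorganic"] * 19 + ["PAH"] * 16 + ["polar_organic"] * 350)
    sample_ids = [f"site_{i + 1:02d}" for i in range(n_samples)]
    chem_ids = [f"cmp_{j + 1:03d}" for j in range(385)]
    values = np.exp(rng.normal(0.0, 1.0, size=(n_samples, 385)))
    for j, c in enumerate(counts):
        absent = rng.choice(n_samples, size=n_samples - c, replace=False)
        values[absent, j] = np.nan
    return ChemTable(
        values=pd.DataFrame(values, index=sample_ids, columns=chem_ids),
        chemical_class=pd.Series(classes, index=chem_ids, name="class"),
    )
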