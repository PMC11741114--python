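# Methods

This note documents the models, estimators and numerical choices behind
`mixlink`, and what the synthetic benchmarks do and do not establish.

## Data model and notation

Two blocks are observed on the same n samples: X₁ (n × p chemicals,
concentrations with missingness) and X₂ (n × q genes, read counts). The
analysis assumes a small number of latent sample-level factors — mixture
gradients — each expressed as (i) a sparse pattern over chemicals and
(ii) coordinated expression of one or more gene modules. All downstream
machinery (module discovery, SGCCA, enrichment) is a pipeline for
recovering these factors and attributing them to variables.

## Chemical preprocessing

*Missingness.* "Absent" and "below detection limit" are both coded missing;
no limit-of-detection substitution (e.g. LOD/2) is applied because kNN
imputation subsumes substitution and avoids inventing a point mass at an
arbitrary value.

*Detection filter.* A chemical is excluded iff its missing fraction is
strictly greater than `max_missing_frac` (default 0.5): a chemical missing
in exactly half the samples is retained. The filter is idempotent and
column-order invariant.

*kNN imputation (k = 5).* Sample-to-sample distance is the Euclidean norm
over chemicals observed in both samples, after standardizing each chemical
with its observed-entry mean and (n−1)-denominator standard deviation.
For each missing cell, the k nearest samples *with that chemical observed*
contribute; averaging is uniform by default (inverse-distance weighting is
available behind a flag). Distance ties break by sample order, making the
result deterministic. Requiring every chemical to be observed in at least
k samples is what the detection filter guarantees upstream; the pipeline
order filter → impute → standardize is therefore fixed, and standardizing
a table that still has missing values is an error.

*Standardization.* Per-chemical mean 0, sample (ddof = 1) standard
deviation 1; constant columns are an error naming the chemical. PCA QC is
an ordinary eigendecomposition of the standardized table (scikit-learn,
full SVD solver).

## Expression preprocessing

Genes are kept iff mean count ≥ 5 AND total count ≥ 10 AND zero fraction
≤ 0.6 (zeros in strictly more than 60% of samples exclude a gene). The
per-rule tallies are reported; a gene failing several rules counts once.

Normalization maps counts to log2 rates, log2((c + 0.5) / library_size ×
10⁶); the 0.5 offset handles zeros. The default `log_cpm_quantile` method
then applies full quantile normalization: every sample's sorted value
vector is replaced by the across-sample mean sorted vector, so per-sample
distributions are *exactly* identical afterwards. Ties within a sample are
ordered stably by row position and receive adjacent reference values; this
keeps the identical-distribution contract exact, at the cost of splitting
tied raw values by at most one quantile step (averaging ties instead would
perturb the common distribution). The `covariate_quantile` method first
removes the dependence of log-rates on one per-gene covariate (length or
GC), estimated as the median log-rate within 10 covariate-quantile bins and
interpolated between bin centers, then quantile-normalizes. This is a
deliberately simple one-covariate conditional normalization — adequate for
feeding the correlation machinery, not a substitute for a full
spline-based conditional quantile fit; users with strong covariate effects
should normalize upstream and pass the matrix in directly.

## Consensus coexpression network

Each ensemble run (default 50; smaller counts are used in some tests for
runtime, stated per test):

1. bootstrap the samples with replacement to the original n;
2. add Gaussian noise with standard deviation `noise_sd` × the gene's own
   (original-data) standard deviation; the default `noise_sd` = 0.1 keeps
   the perturbation an order of magnitude below the signal while breaking
   ties among near-duplicate genes;
3. compute Pearson correlations (zero-variance genes in a resample get
   zero correlations and a unit diagonal);
4. choose the threshold t from a candidate grid (default 0.30–0.90, step
   0.05) at which the graph with edges |r| ≥ t is most scale-free.

The scale-free criterion fits log₁₀ p(k) against log₁₀ k by least squares
over ≥ 10 log-spaced degree bins with nonzero mass, excluding degree-0
nodes. The chosen threshold is the smallest candidate with R² ≥ 0.8 and a
negative slope; if none qualifies, the negative-slope candidate with
maximal R². When no candidate gives a negative-slope fit at all (e.g. a
near-complete, degree-homogeneous graph) the selection errors rather than
guessing — such inputs are outside the model class this criterion assumes.

An edge enters the consensus network iff it appears in at least
`consensus_frac` (default 0.5) of the runs; its weight is that retention
fraction. Support is a count over runs, so it is invariant to run order;
per-run seeds spawn deterministically from the ensemble seed.

Modules are map-equation (Infomap) communities of the weighted consensus
graph, best of 10 optimization trials with a seeded RNG. Communities below
`min_module_size` (default 10) and isolated genes are left unassigned
(module 0). Module ids are relabelled 1..M by descending size, so module 1
is always the largest.

## SGCCA

For blocks X_j (column-centered; the chemical block standardized, the gene
block quantile-normalized — no further rescaling) with design weights
c_jk ≥ 0 and scheme g ∈ {x, |x|, x²} (horst / centroid / factorial), each
component solves

    max Σ_{j<k} c_jk · g( cov(X_j a_j, X_k a_k) )
    s.t. ‖a_j‖₂ = 1,  ‖a_j‖₁ ≤ s_j √p_j .

Defaults: two blocks with c₁₂ = 1 (the API accepts J ≥ 2), centroid scheme
(robust to the sign of block covariance), sparsity s = 0.5 for the
chemical block and 0.3 for the gene block. Sparsity is the parameter that
matters most and should be stated with any analysis; the package makes no
attempt to select it automatically beyond exposing it prominently.

*Optimization.* Block-coordinate ascent: updating a_j maximizes the
linearized objective over the constraint set, whose closed-form maximizer
is soft-thresholding of X_jᵀ z_j followed by l2 normalization, with the
threshold λ found by bisection (tolerance 1e-10) as the smallest value
meeting the l1 budget. An l1 budget of exactly 1 returns the signed
indicator of the largest-magnitude entry (ties to the lowest index). This
update never decreases the objective, so the per-component objective trace
is non-decreasing — asserted in tests at the convergence tolerance
(default 1e-8, max 1000 sweeps; non-convergence is recorded as a warning
on the fit, not raised).

*Initialization, signs, deflation.* a_j starts at the block's first right
singular vector (deterministic), with a seeded random fallback for
degenerate blocks. After convergence, each weight vector is flipped so its
largest-magnitude entry is positive; LDR correlation signs are therefore
arbitrary and reported as-is. Successive components are obtained by
projection deflation of each block against its own score; rank-deficient
deflation stops the fit early with a warning.

*Squared weights.* SW = a² inherits Σ SW = 1 per block and component from
the unit l2 norm; "contributors" are variables with SW above a cutoff
(0.01 by default, matching the reporting convention for chemical
contributions per LDR).

*Variance explained.* Chemical-side scores are orthogonalized in component
order (QR); the per-component fraction is ‖Xᵀq_k‖² / ‖X‖²_F on the
centered gene block, so the cumulative value equals the joint-regression
R². This definition is one of several in use; it is fixed and documented
here so numbers are comparable across runs.

*Relation to classical CCA.* SGCCA maximizes covariance under unit-norm
weights, not correlation; the two coincide when blocks are whitened. The
test-suite cross-check against the classical CCA eigenproblem therefore
whitens its toy blocks first.

## Enrichment

*Module enrichment.* Per (module, component): one-sided Mann–Whitney U,
alternative "module genes have larger SWs". When the smaller group has ≤ 8
genes and enumeration is affordable (≤ 2×10⁵ assignments), the p-value is
the exact tie-aware permutation probability P(U ≥ U_obs); otherwise the
normal approximation with tie and continuity corrections. BH adjustment is
applied across the full module × component family by default — one
coherent FDR — with per-component families behind a flag.

*Pathway overrepresentation.* Per pathway: the 2×2 module × pathway table
over the analyzed gene universe (genes surviving the count filter and
present in the SGCCA gene block; annotation genes outside it are dropped),
Pearson chi-square without continuity correction. Pathways overlapping the
module in fewer than `min_overlap` (default 3) genes are skipped and
flagged; cells with expected count < 5 are flagged but still tested.
"Enriched" requires BH-adjusted p < α and observed overlap above
expectation.

## Synthetic-data generator

`SynthConfig` defaults emulate a ~30-sample field survey: 215 chemicals,
10⁴ genes, 5 latent factors, 5% MCAR missingness plus 5% left-censoring,
negative-binomial dispersion 0.2. Factor scores are i.i.d. standard normal,
then orthogonalized and scaled to unit sample variance so planted
components are identifiable. Chemical loadings have constant magnitude
`factor_effect` with random signs on a support of `chem_sparsity` × p
chemicals per factor. Gene modules are disjoint index sets; module m loads
on factor m mod n_factors with a module-level sign and constant magnitude.
Baseline log-mean counts are log-uniform over a configurable range
(default 0.5–2000 mean counts) so the count filter removes a real planted
fraction; the generator records which genes are expected to survive.
Censoring is applied per chemical at the `lod_quantile` quantile of its
own values and recorded as missing — censored values are never substituted.

What the generator does *not* emulate: analytical-chemistry measurement
error structure (matrix effects, ionization suppression, correlated batch
effects), read-level RNA-seq artifacts (length/GC bias beyond the optional
covariate, mapping ambiguity), or non-Gaussian mixture gradients. Passing
recovery tests on this generator shows the estimators recover planted
linear-factor structure at realistic sizes and noise; it does not certify
performance on real field data, where factor structure may be weaker,
non-linear, or confounded.

## Benchmark problem sizes

The recovery benchmarks use sizes at which the planted structure is
identifiable yet the full suite stays quick: module recovery on 4 × 50
genes across 30 samples; chemical-support recovery with 100 samples,
50 chemicals (5 in the support) and 2000 genes over 20 generator seeds
with 25 ensemble runs per seed; enrichment calibration over 1000 null
simulations. The chemical-block sparsity in the support-recovery benchmark
is 0.31: with equal-magnitude planted loadings, a binding l1 budget b
bounds the achievable cosine to b/√5, so the budget must sit just inside
√5 (s = √5/√50 ≈ 0.316) — a worked illustration of how sparsity choices
trade support precision against weight shrinkage.

## Known limitations

- The scale-free threshold criterion is meaningless for degree-homogeneous
  graphs; the selector errors there by design.
- SGCCA sparsity is not auto-tuned; results are sensitive to it.
- The covariate-conditional normalization is a binned-median
  approximation, not a full conditional quantile fit.
- Enrichment treats modules as fixed; uncertainty in module detection is
  not propagated into the enrichment p-values.
- With more planted modules than factors, modules sharing a factor are
  (correctly) merged by coexpression — module counts are recoverable only
  up to factor identifiability.
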