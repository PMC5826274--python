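# Methods

## Scope and model

`coexnet` implements the complete computational path from a bulk RNA-seq
count matrix and a per-animal behavioural table to behaviour-correlated
coexpression modules, cross-condition module-preservation statistics, and
prioritized gene/interaction lists.  The organism-facing use case is the
songbird striatopallidum (Area X and the adjacent ventral striatopallidum),
where one expression sample per animal is paired with four behavioural
metrics; nothing in the code is specific to that system beyond the fixed
trait column names.

The statistical object is the signed weighted coexpression network.  For
genes *i, j* with expression correlation `S_ij` over samples:

* adjacency `a_ij = ((1 + S_ij)/2)^β` (signed; anti-correlated genes get
  weight ~0 rather than high weight);
* connectivity `k_i = Σ_{j≠i} a_ij`.  The self-term is excluded everywhere:
  with `a_ii` included, an isolated perfectly correlated gene pair would not
  reach topological overlap 1, which contradicts the overlap formula's
  normalisation;
* topological overlap `ω_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
  `l_ij = Σ_{u≠i,j} a_iu a_uj`; `1 − ω` is the clustering dissimilarity;
* module eigengene: first principal component of the standardized module
  block, scaled to unit variance and sign-aligned with the module's mean
  standardized profile (SVD signs are arbitrary; the alignment makes
  eigengenes deterministic);
* module membership `kME_i = cor(x_i, ME)`; gene significance
  `GS_i = cor(x_i, trait)`.

## Preprocessing

Fixed order: TPM → log2(x + pseudocount) → zero-variance gene removal →
iterative outlier masking → intrasample-correlation (ISC) sample filter →
quantile normalization.

* TPM: `(count/length) / Σ(count/length) × 10^6` per sample; an all-zero
  sample is an error naming the sample.
* Pseudocount default 1 (zeros occur in real counts; log2(TPM+1) is the
  common convention).  A pseudocount of 0 with zero values is an error by
  default; a `neginf` policy is available.
* Outlier masking: per gene, cells strictly more than 2.5 sample (n−1) SDs
  from the gene's mean over currently unmasked cells are masked; passes
  repeat until one masks nothing, so the operation is idempotent at
  convergence.  Genes left with fewer than 3 unmasked cells are dropped
  with a warning.
* ISC: mean pairwise Pearson correlation of each sample with all others
  (configurable to median); samples strictly below mean − 2 SD are removed.
  Boundary cases sit on the retained side, matching the strict-inequality
  reading of the cutoffs.
* Quantile normalization: masked cells are first imputed to the gene's
  unmasked mean (the transform needs complete columns; mean imputation is
  correlation-neutral), ties receive the average of their tied-rank
  reference values.  Idempotent.

## Network construction

The soft threshold β is the smallest candidate power whose signed
scale-free fit reaches `fit_cut` (default 0.8): connectivities are binned
into 10 equal-width bins and log10(frequency) regressed on log10(mean k);
the fit index is `−sign(slope)·R²`.  If no candidate qualifies the scan
table is returned with a `None` selection and the iterative builder falls
back to the largest candidate.

Modules come from average-linkage hierarchical clustering on `1 − ω` with a
dynamic-height cut: candidate cut heights are scanned across the
merge-height range, the retained cut maximizes the number of branches of at
least the minimum module size, and `deepSplit` ∈ {0..4} selects among tied
cuts from coarsest to finest.  This is a deliberately simplified
dynamic-height procedure, not a line-by-line port of the dynamic hybrid
tree-cut algorithm: the acceptance surface is planted-module recovery, not
label-identical replication of any particular implementation.  Labels are
arbitrary colour names assigned largest-first; `grey` is reserved for
unassigned genes.

Membership pruning after each cut: genes with `kME < 0.3` against their own
module eigengene go to grey; a module survives only if at least
⌈minModuleSize/3⌉ members have `kME ≥ 0.5`; eigengenes are recomputed after
pruning.  The whole chain (adjacency → TOM → cut → eigengenes → rules) is
iterated with grey genes removed until no gene lands in grey (cap 10
iterations, warning on non-convergence).  One memory block is used
throughout; at desk scale the full matrices fit comfortably.

## Behavioural metrics and module-trait statistics

* Effect size of singing on an acoustic feature's variability:
  `(NS − UD)/(NS + UD)` where NS/UD are the feature CVs after two hours of
  non-singing vs undirected singing.  Negative values mean singing
  increased variability; the transform weights an absolute shift more when
  the baseline is low.
* Motif identity: `similarity% × accuracy% / 100` of a motif self-comparison
  batch; higher identity = less variable song.
* Module-trait association: Pearson ρ between eigengene and trait, two-sided
  p from the Fisher transform `z = atanh(ρ)√(n−3)` (|ρ| = 1 clamps to
  p = 0); a Student-t variant is available.  Benjamini–Hochberg q-values are
  computed over the full modules × traits family, padding with p = 1 when
  fewer values are supplied than the declared family size.  Both the
  uncorrected p ≤ 0.05 view and the FDR pass flag (q ≤ 0.05) are emitted,
  since at ~19 samples FDR correction removes nearly everything and the
  uncorrected values serve as a ranked guide.

## Module preservation

For each reference module the test data yields three density statistics
(mean within-module adjacency, eigengene variance explained, mean kME) and
three connectivity statistics (cor of kIN, of kME, and of the vectorized
within-module correlation matrices between datasets).  The null emulates a
permutation of module labels in the test data: the reference side of every
statistic keeps the true module genes while the test side uses a random
same-size gene set drawn without replacement from the genes common to both
datasets.  `Z = (obs − null mean)/null SD` per statistic; `Zdensity` and
`Zconnectivity` are medians of their groups and `Zsummary` their mean.
`median_rank` orders modules by observed statistics, insensitive to module
size.  Thresholds 2 (no evidence) and 10 (strong preservation) are the
conventional reference lines, not estimates.  The statistic roster is a
fixed six-statistic subset of the published composite; the test-side
adjacency uses the test dataset's own selected power.

## Synthetic data

Each planted module *m* has a latent eigengene `E_m`, i.i.d. standard
normal across samples, and gene *i* in *m* is

    x_i = μ_i + r_i E_m + sqrt(1 − r_i²) · noise_sd · ε

with baselines `μ_i ~ N(4, 2²)` (log2-TPM-like scale) and loadings
`r_i ~ N(target, 0.10²)` clipped to [0.05, 0.98] — modules span hubs and
peripheral members as real modules do.  With `noise_sd = 1` (default) the
expected gene-eigengene correlation equals the kME target exactly;
background genes are independent noise.  Traits are `ρ·E_m` plus scaled
noise mapped affinely onto behavioural scales (counts of motifs, percent
similarity, effect size, identity score), which leaves Pearson correlations
intact.  Counts are negative binomial (gamma-Poisson) with expected reads ∝
abundance × gene length, so expected TPM recovers the planted abundances;
dispersion 0 is the Poisson limit.

Condition 2 redraws every latent eigengene.  A module with preservation
strength `s` gives gene *i* the shared component `r_i(s·E'_m +
√(1−s²)·u_i)` with `u_i` a private per-gene latent: `s = 1` reproduces the
module's coexpression from the same loadings with fresh noise, `s = 0`
(scrambled) reassigns every loading onto an independent latent —
within-module correlation is destroyed while each gene's marginal mean and
variance are untouched, mirroring the empirical situation where raw
expression stays correlated across conditions but connectivity does not.

The default configuration reproduces the study scale (19 samples, 21
modules of 100–2000 genes totalling 7461, 6204 background genes, four
trait couplings).  `study_replica_config()` is the preservation-analysis
replica at desk scale: the same 21-module size distribution divided by 5
with a 60-gene floor, background in the same proportion, 19 samples, and
the green module (the learning-module analogue) scrambled in condition 2.
The skewed size distribution matters: a large dominant module inflates the
permutation-null SD, which is what places a scrambled module inside the
|Zsummary| < 2 band while fully preserved modules stay above 10 — few-module
equal-size toy designs instead push scrambled modules to Z ≈ −3.

What the generator does **not** emulate: batch effects, library-size
artifacts, count-level overdispersion heterogeneity, correlated background
structure, or non-linear trait couplings.  Passing recovery tests therefore
demonstrates correctness of the estimators under the declared generative
model, not robustness to real-data pathologies.

## Motif scanning

A PWM is a 4 × L log2-odds matrix against a uniform background, built from
count matrices with a pseudocount (default 0.8 split over the four bases;
JASPAR text is parsed via Biopython).  A window's relative score is
`(raw − min)/(max − min)` over the matrix's attainable score range — the
"80% hit score" is interpreted on this range, matching the semantics of the
standard Bioconductor scanning function; a fraction-of-maximum variant
would differ for matrices with negative minima.  Windows containing N are
skipped; both strands are scanned by default, with reverse-strand hits
reported at forward 0-based half-open coordinates.  Promoters are the 1000
bases upstream of the TSS (reverse-complemented for minus-strand genes),
truncated with a warning at contig edges.  The bundled forkhead-like demo
matrix is synthetic (constructed counts, consensus TGTTTACTTTAC), not a
database motif.

## Prioritization

Module significance of an annotation term: mean kME (own module) of the
term's genes inside the module × (1 − p).  Term significance weights that
by the mean |GS| of the same genes for a chosen trait; absolute values are
used so negatively correlated genes are not penalized (signed mean
available).  Interaction edges below 0.9 confidence are discarded; the four
ranking metrics multiply confidence by per-endpoint kIN, differential kIN,
GS, or kIN·GS, with ties broken lexicographically.  Visualization
sparsification keeps the top fraction of edges by weight (ties at the
cutoff retained), drops edge-less nodes, then keeps the largest connected
component (size ties broken by smallest node id); the stage is idempotent.

## Numerical and design notes

* Correlations are Pearson, pairwise-complete over unmasked cells; sample
  (n−1) SDs throughout.
* All randomness flows through explicit `numpy` generators; the pipeline
  derives stable per-stage sub-seeds (SHA-256 of seed:stage, reduced below
  2^31) so toggling one stage never shifts another's draws.
* Problem sizes in the test and acceptance runs are desk-scale choices:
  planted-recovery uses 5 modules of 100–300 genes × 60 samples; the
  preservation replica is the 1/5-scale 21-module design above with 200
  permutations.  These sizes keep full runs in seconds-to-minutes while
  leaving every recovery margin wide.
* Known limitations: the tree cut is a granularity-parameterized
  simplification (module boundaries can differ from other implementations
  on weakly separated data); preservation reports a six-statistic subset of
  the published composite; gene identifiers are assumed pre-harmonized
  across datasets (no homolog mapping); behavioural raw feature extraction
  from audio is upstream of the package.
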