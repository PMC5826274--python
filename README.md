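# coexnet

Weighted gene coexpression network analysis for linking bulk RNA-seq
expression to quantitative behaviour, built around the songbird basal-ganglia
study design: a handful of animals, each contributing one expression sample
and a set of per-animal behavioural metrics (amount of singing, tutor-song
imitation, singing-induced vocal variability, overall vocal variability).

The package takes a gene × sample count matrix from TPM normalization through
module detection, module–trait statistics, cross-condition module
preservation, annotation-term and protein-interaction prioritization, and
promoter motif scanning.  A fully instrumented synthetic-data generator
plants known modules, trait couplings, and motif instances so that every
stage has a parameter-recovery test.

## The model

Coexpression is summarised by a signed weighted network.  With `S_ij` the
Pearson correlation of genes *i* and *j* across samples:

    a_ij = ((1 + S_ij) / 2) ** β          signed adjacency, β chosen so the
                                          degree distribution approximates a
                                          scale-free fit
    ω_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)
    l_ij = Σ_{u≠i,j} a_iu · a_uj          topological overlap

Genes are clustered by average linkage on `1 − ω`; branches of at least the
minimum module size become modules; each module is summarised by its
eigengene (first principal component, `ME`), and membership is pruned by
`kME = cor(x_i, ME)` rules (members need kME ≥ 0.3; a module core of
⌈minSize/3⌉ genes needs kME ≥ 0.5).  Grey (unassigned) genes are removed and
the network rebuilt until none remain.

Module–trait association is `ρ = cor(ME, trait)` with two-sided p-values
from the Fisher transform, `z = atanh(ρ)·√(n−3)`, and Benjamini–Hochberg
correction over the full modules × traits family.  Module preservation
between two datasets is the permutation composite
`Zsummary = (Zdensity + Zconnectivity)/2` (label-permutation null; < 2 means
no evidence of preservation, > 10 strong preservation).

## Worked example

```python
from coexnet import CoexpressionNetwork, ModuleTraitAnalysis
from coexnet.synthdata import SynthConfig, generate_expression, generate_traits

cfg = SynthConfig(
    n_samples=40,
    module_sizes=(120, 90, 60),
    n_background_genes=180,
    kme_targets=0.8,
    trait_couplings={"motifs": ("blue", 0.85), "tutor_similarity": ("brown", 0.8)},
    preserved_modules=("turquoise", "blue"),
    seed=42,
)
expr, truth = generate_expression(cfg)
traits = generate_traits(truth, cfg)

res = CoexpressionNetwork(expr, power="auto", min_module_size=50, deep_split=2).fit()
print("selected power:", res.power)
print(res.summary().round(3).to_string(index=False))
print(ModuleTraitAnalysis(res.eigengenes, traits).fit().summary().head(4).to_string(index=False))
```

prints

```
selected power: 14.0
   module  size  var_explained  mean_kME  mean_kIN  mean_kTotal
turquoise   120          0.642     0.794    11.502       11.514
     blue    89          0.649     0.800     8.214        8.301
    brown    58          0.654     0.802     5.713        5.860
   module            trait    rho            p            q  pass
     blue           motifs  0.831 4.226665e-13 2.535999e-12  True
    brown           motifs  0.159 3.307424e-01 3.402998e-01 False
turquoise           motifs -0.155 3.402998e-01 3.402998e-01 False
    brown tutor_similarity  0.777 2.841908e-10 8.525723e-10  True
```

All three planted modules are recovered at their planted sizes (the module
eigengene explains ~65% of each module's variance, mean kME ≈ the 0.8
target), and each behavioural trait is significant exactly at the module it
was coupled to — `motifs` at blue (ρ = 0.83), `tutor_similarity` at brown
(ρ = 0.78) — surviving FDR correction, while uncoupled module–trait pairs do
not.

The same analysis runs from the shell:

```bash
coexnet simulate --outdir sim --seed 42
coexnet preprocess --counts sim/counts.tsv --lengths sim/gene_lengths.tsv --out expr.tsv
coexnet network --expr sim/expr.tsv --power auto --min-size 100 --modules modules.tsv
coexnet run --outdir full_run --seed 42     # everything, simulate → scan
```

## Layout

| module | contents |
| --- | --- |
| `coexnet.synthdata` | planted-structure generators (expression, traits, condition 2, counts, annotations, interactions, promoters) |
| `coexnet.preprocess` | TPM, log2, outlier masking, ISC sample filter, quantile normalization |
| `coexnet.network` | adjacency/TOM, soft-threshold scan, dynamic tree cut, eigengenes, `CoexpressionNetwork` model |
| `coexnet.traits` | behavioural metrics, gene significance, module–trait statistics, FDR |
| `coexnet.preservation` | permutation `Zsummary` module preservation, `ModulePreservation` model |
| `coexnet.annotate` | term/module significance, interaction scaling, visualization sparsifier |
| `coexnet.motifscan` | PWMs, promoter extraction, relative-score scanning |
| `coexnet.pipeline`, `coexnet.cli` | orchestration, YAML config, `coexnet` command |
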