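# lnctrace

Transcriptomic analysis of tumor initiation in a lineage-traced mouse
mammary-cancer model: stage-matched differential expression, temporal
clustering of expression trajectories, hallmark-style enrichment, and a
genomic-window correlation screen that nominates cis-regulating
lncRNA–protein-coding-gene pairs.

## The problem

In a Cre/lox mammary tumor model, sorted GFP+ epithelial cells are profiled
by bulk RNA-seq across two genotypes (wild-type and a conditional knockout
whose tumor onset is delayed), two conditions (tumor and age-matched
tumor-free gland) and four timepoints (6, 8, 10, 12 weeks: hyperplasia →
adenoma → carcinoma), with 3 tumor and 2 tumor-free replicates per
genotype–timepoint. The questions the pipeline answers:

1. Which genes are differentially expressed between tumors and age-matched
   tumor-free glands at each stage, per genotype?
2. How do the hyperplasia-stage DEGs evolve over tumor progression — which
   temporal archetypes do they follow, and which genes are exclusive to one
   genotype?
3. Which differentially expressed lncRNAs sit within ±500 kb of a
   differentially expressed protein-coding gene and co-express with it —
   the operational signature of cis-regulation?

## The model

**Differential expression.** Counts are modelled as negative binomial with
variance μ + αμ². Samples are normalised by median-of-ratios size factors
(for sample *j*, the median over genes of count/geometric-mean). Per gene,
condition means are estimated with size-factor offsets, the dispersion α by
method of moments pooled over all replicate groups of the design, and the
Wald statistic is log2FC/SE with the delta-method standard error, two-sided
normal p-values and Benjamini–Hochberg FDR. DEGs pass strict fold-change
and FDR thresholds (stagewise: FC > 1.5, FDR < 0.1; time-course input:
FC > 2, FDR < 0.1).

**Temporal clustering.** Hyperplasia-stage DEGs of both genotypes are
summarised as mean normalized expression per tumor stage (stage-aligned:
the knockout's onset is one timepoint later), prefixed by the tumor-free
baseline, z-scored per gene and clustered with k-means (k-means++, best of
25 restarts; the within-cluster-SS elbow supports K = 3). Clusters map to
three archetypes: early spike then decay, sustained rise, early drop.

**Enrichment.** Preranked GSEA with the weighted Kolmogorov–Smirnov
running-sum statistic and gene-set permutation (the 3-vs-2 design is too
small for phenotype permutation), plus hypergeometric over-representation
for cluster gene lists.

**Cis screen.** Every DE lncRNA is paired with DE protein-coding genes
whose span gap is ≤ 500 kb on the same chromosome; each pair's Pearson
correlation of log2(normalized + 1) expression across tumor samples is
tested (two-sided t, n − 2 df). Reported pairs satisfy r ≥ 0.80 and
p < 0.01.

A synthetic-data module generates the full study design — NB counts,
reporter spike-ins (GFP high, membrane-tdTomato near zero in sorted cells),
a floxed-exon feature absent in knockout samples, three planted temporal
archetypes, and cis-linked pairs with a shared latent factor — so every
stage is testable against a known answer key.

## Worked example

Generate the default synthetic study and run the whole pipeline:

```sh
lnctrace simulate --seed 7 --out study
cat > config.yaml <<EOF
counts: study/counts.tsv
samples: study/samples.tsv
annotation: study/annotation.gtf
gmt: study/sets.gmt
exon_counts: study/exon_counts.tsv
out_dir: out
seed: 7
EOF
lnctrace run-all --config config.yaml
```

Selected lines of the printed run summary:

```
qc.n_samples              40
qc.n_recombination_ok     40
diffexpr.degs_WT_wk6      298
temporal.n_hyperplasia_wt 291
temporal.cluster1         104
temporal.cluster2         182
temporal.cluster3         120
cis_screen.n_evaluated    223
cis_screen.n_reported     15
```

All 40 samples pass the GFP/mTd reporter check; 298 genes are DE in
wild-type tumors at week 6 (FC > 1.5, FDR < 0.1), of which 291 pass the
stricter time-course threshold and feed the clustering together with the
knockout's week-8 DEGs; the joint profiles split into the three archetypes;
and 15 of 223 evaluated lncRNA–PCG pairs pass the window + correlation
screen. The head of `out/pairs.tsv`:

```
lncRNA    protein_coding_gene  PCC           p_value          distance_bp  n_samples
CISLNC04  CISPCG04             0.9875658947  2.292460133e-09  8742         12
CISLNC01  CISPCG01             0.982330763   1.31676087e-08   14954        12
CISLNC05  CISPCG05             0.9775992602  4.278373037e-08  7490         12
```

The five `CIS*` pairs are the generator's planted cis-regulated pairs —
all recovered at the top of the report, analogous to the screen that singles
out a lncRNA adjacent to a fatty-acid-metabolism gene in the real study.

Each stage is also available on its own (`lnctrace de`, `cluster`, `gsea`,
`ora`, `cispairs`, `qc`), and as library functions
(`lnctrace.nb_wald_test`, `lnctrace.screen_pairs`, ...).

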