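# Methods

This note documents the statistical model, the synthetic study the tests
run against, the numerical conventions, and the design choices that were
genuinely open.

## Study design and data model

The design is a 2 × 2 × 4 layout: genotypes WT and KO (conditional
knockout with delayed tumor onset), conditions tumor and tumor-free, and
timepoints 6/8/10/12 weeks, with 3 tumor and 2 tumor-free replicates per
genotype–timepoint (40 libraries). Counts are gene × sample non-negative
integers; the pipeline starts at the count matrix (alignment and counting
are upstream). Genomic coordinates are 0-based half-open internally; GTF
I/O converts at the boundary (GTF is 1-based inclusive), which keeps the
±500 kb window arithmetic unambiguous. Gene biotype comes from
`gene_biotype` (fallback `gene_type`); values other than
`protein_coding`/`lncRNA` map to `other`, and the two fluorescent-reporter
rows are ordinary count rows flagged `spike_in`.

## Quality control

Sorted GFP+ epithelial cells must show reporter recombination: a sample
passes when (GFP + 1)/(mTd + 1) ≥ `min_ratio` (default 10; pseudocount 1
avoids division by zero — a sample with no reads on either reporter scores
ratio 1, fails, and is flagged `no_signal`). Knockout concordance uses the
floxed-exon count: a KO sample is concordant when exon/(gene + 1) ≤
`max_exon_fraction` (default 0.01); discordant KO samples are
recombination escapees. The source material states these criteria only
qualitatively ("GFP expressed at higher levels", "no reads at the floxed
exon"), so both numeric defaults are package choices; both checks are
monotone in their threshold by construction. Exon-level counts arrive as a
separate small table (`feature_id = gene:exonN`) because the pipeline does
not return to read level.

## Differential expression

Counts K_gj ~ NB(s_j · μ_gc, α_g) with variance μ + α μ². Choices, in the
order they bind:

- **Size factors** — median-of-ratios: factor_j = median over genes of
  K_gj / geomean_g, restricted to genes with all-positive counts. A single
  sample gets factor 1 by convention.
- **Prefilter** — genes with total count < 10 across all samples are
  dropped (boundary inclusive: a total of exactly 10 is kept).
- **Condition means** — μ̂_c = Σ_j K_gj / Σ_j s_j over the contrast's
  samples (tumor vs age-matched tumor-free within one genotype and
  timepoint; ≥ 2 replicates per condition required).
- **Dispersion** — per-gene method of moments pooled over *all* replicate
  groups of the supplied matrix: with SS_c the normalized-count residual
  sum of squares in group c, α̂ = (Σ SS_c − Σ(n_c−1)μ̂_c) / Σ(n_c−1)μ̂_c²,
  clipped to [1e-8, 10]. Pooling over the full design (24 residual df here)
  rather than a single contrast's five samples is what keeps the
  normal-quantile Wald test near its nominal level; with 3 df the null
  rejection rate at 0.05 would be ~0.14 (t₃-like). No shrinkage, no
  independent filtering, no LFC moderation — the test is deliberately a
  transparent NB Wald test, not a reimplementation of any particular
  package's estimator.
- **Effect and test** — log2FC = log2((μ̂_T + ε)/(μ̂_F + ε)) with ε = 0.5
  normalized counts (bounds the fold change for all-zero conditions);
  SE from the delta method with Var(μ̂_c) = (Σs·μ̂ + α̂ (Σs²) μ̂²)/(Σs)².
  The variance carries a first-order plug-in correction (1 + 2/m), m the
  dispersion's residual df, compensating the anticonservative bias of
  treating an estimated dispersion as known; it vanishes as m grows.
  Two-sided p from the standard normal; BH step-up FDR over tested genes.
  All-zero genes report log2FC 0, p 1.
- **Thresholds** — strict inequalities; fold-change thresholds are linear
  by default (FC > 1.5 ⇔ |log2FC| > log2 1.5). A `fc_scale="log2"` option
  reads the threshold directly on the log2 scale, since the two
  conventions both appear in practice; linear is the default because it is
  the internally consistent reading of the stated thresholds.

PCA operates on log2(normalized + 1), restricted to the 500 most variable
genes, gene-centred, samples projected on the top right-singular vectors
(the transform is a package choice; the variance-top-K restriction is
standard practice).

Measured behaviour (the acceptance suite recomputes these): on a null
simulation (2000 genes, 3 vs 2, dispersion 0.1) the raw p < 0.05 fraction
is ≈ 0.06; 100 planted log2FC = 2 genes at base mean 100 are called at
FC > 1.5/FDR < 0.1 in ≥ 90% of cases, with the mean estimate slightly
attenuated (≈ 1.9) by the ε pseudocount.

## Temporal clustering

Input: the union of hyperplasia-stage DEGs (FC > 2, FDR < 0.1) from WT
(week 6) and KO (week 8). Each gene's trajectory is its mean normalized
expression at the genotype's 1st/2nd/3rd tumor timepoint (WT 6/8/10, KO
8/10/12) — stage alignment is the only way a joint WT+KO clustering is
well-posed — *prefixed by the pooled tumor-free baseline* of the same
weeks. The baseline column matters: after per-row z-scoring, a
"drops at hyperplasia and stays low" gene is near-constant across tumor
stages alone, and its z-scored profile would be amplified noise; with the
baseline in front all three archetypes have distinct, stable shapes.
Constant rows are flagged and dropped before z-scoring.

K-means uses k-means++ seeding, Lloyd iterations (max 300, tol 1e-6), best
of n_init = 25 restarts, deterministic under the configured seed. The
elbow curve (total within-cluster SS vs K) is returned for plotting; K = 3
is the pipeline default. Because k-means labels are arbitrary, centroids
are matched to the three canonical archetype shapes by correlation with
Hungarian assignment, so cluster "1/2/3" always means early-spike /
sustained-rise / early-drop regardless of label permutation. Exclusivity
partitions (WT-only / KO-only / shared membership of a cluster) compare
the two genotypes' assignments against each other's clustering input.

## Enrichment

Preranked GSEA: genes ranked by Wald statistic (variance-aware; the
ranking metric is a package choice, `signed_log2fc` is available), ties
broken lexicographically. The enrichment score is the weighted KS running
sum — hits add |metric|^w / Σ_hits |metric|^w (w = 1 default; w = 0
recovers the classic unweighted KS statistic), misses subtract 1/(N − m) —
and ES is the signed extremum. Significance by gene-set permutation
(random equal-size member sets from the ranked universe): NES = ES
divided by the mean |null ES| of matching sign; the empirical two-sided p
carries an add-one correction (floor 2/(n_perm + 1), so p is never 0);
BH FDR across sets. Gene-set permutation is used because 3-vs-2 groups
cannot support phenotype permutation. Size bounds 5–500.

Over-representation: upper-tail hypergeometric P(X ≥ overlap) with
population = universe (tested genes), successes = set ∩ universe, draws =
query; query genes outside the universe are trimmed with a warning.

## Cis-regulation screen

Operational definition of a cis pair: same chromosome, span gap ≤ 500 kb
(inclusive; 0 when the spans overlap; strand ignored), Pearson r ≥ 0.80
(signed — the screen targets co-upregulated pairs; absolute mode is
available) and correlation p < 0.01 (two-sided t on n − 2 df) on
log2(normalized + 1) across the sample scope. Distance defaults to the
span gap (the most permissive faithful reading of "within a 500 kb
window"); start-to-start and strand-aware TSS-to-TSS anchors are options.
The default scope is all tumor samples of one genotype pooled over
timepoints (n = 12 in the default design); pooling stages is what gives
the correlation its power, and stage-driven co-variation is exactly the
signal a cis pair shares. Both members must be differentially expressed;
the pipeline feeds WT *up-regulated* hyperplasia DEGs and reports, per
pair, whether both members are additionally WT-exclusive (not DE-up in KO)
— exclusivity is an annotation rather than a hard pre-filter because a
single false-positive KO call would otherwise silently delete a true pair.
Every evaluated pair is written with its three pass flags; the report is
the subset passing all three, sorted by descending r.

## The synthetic study

The generator's defaults are the emulated conditions, not tuning knobs:

- 2000 genes (15% lncRNA) placed uniformly without overlap on 5 × 10 Mb
  chromosomes; baseline log2 expression ~ N(5, 2²); NB dispersion 0.1
  (variance = μ + 0.1 μ², i.e. ~32% biological CV — typical for bulk
  RNA-seq of sorted cells); log-normal library-size factors (σ = 0.15).
- The full 40-sample design above; GFP mean 5000, mTd mean 0.2 in every
  sample (sorted GFP+ cells); a 5-exon Pthlh-like gene (mean 500) whose
  exon-4 feature is Binomial(gene count, 0.25) in WT and exactly 0 in
  non-escapee KO samples. Escapee modelling (KO samples with WT-like
  exon-4 counts) is off by default and switchable for QC tests.
- 60 planted DE genes per archetype (40% WT-only, 20% KO-only, 40%
  shared), base log2 mean ~ N(7, 1). Trajectories, as log2FC vs
  tumor-free at the genotype's four tumor timepoints, are `planted_lfc`
  (default 2) times the shapes (1.5, 0.75, 0.25, 0.1) for the early
  spike, (1.25, 1.65, 2.0, 2.15) for the sustained rise and
  (−1.65, −1.7, −1.75, −1.8) for the early drop. KO trajectories start
  one timepoint later (week-6 KO tumors are pre-onset), reproducing the
  delayed-initiation phenotype.
- 5 cis pairs (lncRNA + PCG, span gap uniform on [0, 500 kb], both
  planted WT-only sustained-rise) and 50 decoy pairs whose members are DE
  with *flat* tumor trajectories — flat means their expression is i.i.d.
  across the screen's tumor-sample scope, making them an exact null for
  the correlation filter.
- Pair co-expression is planted through a Gaussian copula: a shared
  standard-normal latent factor (loading √ρ, ρ = `cis_pair_r_target`,
  default 0.9) drives both genes' NB quantiles. The copula keeps each
  gene's marginal distribution exactly NB — so differential-expression
  behaviour is untouched — while the pair's log-scale correlation is ≈ ρ
  at fixed mean and higher across tumor stages (the shared trajectory adds
  co-variation). A mean-shift latent factor sized for r = 0.9 at
  dispersion 0.1 would instead inflate per-sample variance ~9-fold and
  destroy the pair members' own DE calls at n = 3 vs 2, which is why the
  copula construction was chosen.

What the generator does *not* emulate: batch effects beyond library size,
gene-length or GC bias, isoform structure, read-level artifacts,
inter-gene correlation outside planted pairs, and real mouse annotation.
Passing tests therefore demonstrate that the algorithms recover known
structure under the stated noise model — not that any biological claim
about real data is reproduced; the published dataset's DEG counts and
specific pair list depend on the deposited data and its upstream stack and
are out of scope.

## Problem sizes and determinism

All tests and the acceptance script run at the default study size (2000
genes × 40 samples; the whole pipeline takes ~2 s, 1000-permutation GSEA
included), with brute-force oracles on 20–500-element instances and
exhaustive k-means optima on ≤ 8 points. A single global seed fans out to
per-stage seeds by fixed offsets; reruns at a fixed seed are byte-identical
(result tables use a fixed float format; the run report stores inputs by
content digest and outputs by basename).

## Known limitations

- The Wald test's plug-in correction is first-order; with very few
  replicate groups the test remains slightly anticonservative (≈ 0.06 at
  nominal 0.05 in the default design).
- Method-of-moments dispersion is noisy per gene; the design trades
  efficiency for transparency (no shrinkage), so per-gene power is below
  what empirical-Bayes estimators achieve.
- The exclusivity partition inherits the DEG calls' error rates: a
  false-positive call in one genotype moves a gene out of the other's
  exclusive set. The screen therefore treats exclusivity as an annotation.
- The cis screen nominates correlated neighbours; it cannot distinguish
  cis-regulation from co-regulation by a shared enhancer or from
  coincidental co-expression, and trans-acting pairs are out of scope.
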