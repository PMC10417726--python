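"""Synthetic genomes, annotations and NB count matrices with planted truth.

The generator emulates the lineage-traced mammary-tumor study design:
2 genotypes (WT, KO) x 2 conditions (tumor, tumor-free) x 4 timepoints
(6, 8, 10, 12 weeks) with 3 tumor and 2 tumor-free replicates per
genotype-timepoint; NB-distributed counts with per-sample library-size
multipliers; GFP/mTd reporter spike-ins (sorted GFP+ cells are modelled as
GFP-high / mTd-near-zero); a Pthlh-like gene whose floxed fourth exon has
zero counts in KO samples; three planted temporal differential-expression
archetypes; and cis-linked lncRNA/protein-coding pairs placed within 500 kb
whose counts share a latent factor.

Every planted feature is returned in a :class:`GroundTruth` answer key so
downstream stages can be tested for recovery without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CapacityError, ValidationError
from .io import (
    CountMatrix,
    GeneAnnotation,
    GeneAnnotations,
    GeneSet,
    GeneSetCollection,
    SampleRecord,
    write_counts,
    write_gmt,
    write_gtf,
    write_samplesheet,
    write_table,
)

CIS_WINDOW_BP = 500_000

GFP_ID = "GFP"
MTD_ID = "MTD"
PTHLH_LIKE_ID = "PTHLH_LIKE"
FLOXED_EXON = 4  # 1-based index of the loxP-flanked exon

#: log2 fold-change trajectories (tumor vs tumor-free) per archetype, as
#: multiples of ``planted_lfc``, indexed by tumor stage (1st..4th timepoint
#: with tumors for the genotype).  Shapes follow the three temporal
#: archetypes: 1 = early spike then decay, 2 = sustained rise,
#: 3 = early drop staying low.
ARCHETYPE_SHAPES: dict[int, tuple[float, ...]] = {
    1: (1.5, 0.75, 0.25, 0.1),
    2: (1.25, 1.65, 2.0, 2.15),
    3: (-1.65, -1.7, -1.75, -1.8),
}

SCOPES = ("WT", "KO", "both")


def _default_design() -> tuple[tuple[str, str, int, int], ...]:
    design = []
    for genotype in ("WT", "KO"):
        for week in (6, 8, 10, 12):
            design.append((genotype, "tumor", week, 3))
            design.append((genotype, "tumor_free", week, 2))
    return tuple(design)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    n_genes: int = 2000
    lncrna_fraction: float = 0.15
    n_chromosomes: int = 5
    chrom_length_bp: int = 10_000_000
    design: tuple[tuple[str, str, int, int], ...] = field(default_factory=_default_design)
    mean_log2_expression: float = 5.0
    sd_log2_expression: float = 2.0
    dispersion: float = 0.1
    n_planted_per_cluster: Mapping[int, int] = field(
        default_factory=lambda: {1: 60, 2: 60, 3: 60}
    )
    scope_fractions: tuple[float, float, float] = (0.4, 0.2, 0.4)  # WT, KO, both
    planted_lfc: float = 2.0
    planted_base_log2_mean: float = 7.0
    planted_base_log2_sd: float = 1.0
    n_cis_pairs: int = 5
    cis_pair_r_target: float = 0.9
    n_decoy_lnc: int = 50
    decoy_lfc: float = 2.0
    gfp_mean: float = 5000.0
    mtd_mean: float = 0.2
    pthlh_mean: float = 500.0
    libsize_sigma: float = 0.15
    pthlh_exon_fraction: float = 0.25
    n_escapees: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lncrna_fraction <= 1:
            raise ValidationError("lncrna_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if not self.design:
            raise ValidationError("design must be non-empty")
        if not 0 < self.cis_pair_r_target <= 1:
            raise ValidationError("cis_pair_r_target must be in (0, 1]")
        if self.n_cis_pairs < 0 or self.n_decoy_lnc < 0:
            raise ValidationError("pair counts must be non-negative")


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one differentially expressed gene.

    ``cluster`` is 1..3 for archetype genes and ``None`` for decoys, which
    carry a flat (stage-independent) tumor log2FC instead.
    """

    cluster: int | None
    scope: str  # WT, KO or both
    flat_lfc: float | None = None


@dataclass
class GroundTruth:
    de_genes: dict[str, PlantedGene]
    cis_pairs: list[tuple[str, str]]
    decoy_pairs: list[tuple[str, str]]
    ko_escapee_samples: list[str]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _place_genes(rng, config: SimulationConfig, lengths: np.ndarray):
    """Place genes uniformly at random without overlap; bounded retries."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    spans = []
    for length in lengths:
        ok = False
        for _ in range(200):
            chrom = chroms[rng.integers(0, len(chroms))]
            start = int(rng.integers(0, max(1, config.chrom_length_bp - length)))
            end = start + int(length)
            if end > config.chrom_length_bp:
                continue
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                spans.append((chrom, start, end))
                ok = True
                break
        if not ok:
            raise CapacityError(
                "could not place all genes without overlap; "
                "increase chrom_length_bp or n_chromosomes"
            )
    return spans, placed


def generate_annotation(config: SimulationConfig) -> GeneAnnotations:
    """Generate a toy annotation matching the configured design.

    Includes one Pthlh-like gene with >= 4 exons, GFP and mTd spike-in
    records, and for each requested cis pair a lncRNA placed so its span gap
    to its partner protein-coding gene is uniform on [0, 500 kb].
    """
    rng = np.random.default_rng(config.seed)
    n_special = 3 + 2 * config.n_cis_pairs + 2 * config.n_decoy_lnc
    if config.n_genes < n_special:
        raise ValidationError(
            f"n_genes={config.n_genes} too small for {n_special} special genes"
        )
    footprint = config.n_genes * 6_000
    if footprint > 0.5 * config.n_chromosomes * config.chrom_length_bp:
        raise CapacityError(
            f"~{footprint} bp of gene footprint does not fit on "
            f"{config.n_chromosomes} x {config.chrom_length_bp} bp chromosomes"
        )
    n_regular = config.n_genes - n_special
    lengths = rng.integers(1_000, 10_000, size=n_regular + 3)
    spans, placed = _place_genes(rng, config, lengths)

    genes: list[GeneAnnotation] = []
    width = len(str(config.n_genes))

    def regular_id(i: int) -> str:
        return f"GENE{i:0{width}d}"

    n_lnc = int(round(config.lncrna_fraction * n_regular))
    biotypes = np.array(["lncRNA"] * n_lnc + ["protein_coding"] * (n_regular - n_lnc))
    rng.shuffle(biotypes)
    for i in range(n_regular):
        chrom, start, end = spans[i]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(regular_id(i + 1), regular_id(i + 1), chrom, start, end,
                           strand, str(biotypes[i]))
        )

    # Pthlh-like gene with >= 4 exons (the 4th is the floxed one).
    chrom, start, end = spans[n_regular]
    n_ex = 5
    bounds = np.linspace(start, end, 2 * n_ex + 1).astype(int)
    exons = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex))
    genes.append(
        GeneAnnotation(PTHLH_LIKE_ID, PTHLH_LIKE_ID, chrom, start, end, "+",
                       "protein_coding", exons=exons)
    )
    # Reporter spike-ins: ordinary count-matrix rows flagged biotype=spike_in.
    for sid, span in ((GFP_ID, spans[n_regular + 1]), (MTD_ID, spans[n_regular + 2])):
        chrom, start, end = span
        genes.append(GeneAnnotation(sid, sid, chrom, start, end, "+", "spike_in"))

    def place_pair(tag: str, k: int) -> tuple[GeneAnnotation, GeneAnnotation]:
        """A lncRNA and a PCG with span gap uniform on [0, window]."""
        for _ in range(500):
            chrom = f"chr{int(rng.integers(0, config.n_chromosomes)) + 1}"
            pcg_len = int(rng.integers(1_000, 10_000))
            lnc_len = int(rng.integers(500, 5_000))
            gap = int(rng.integers(0, CIS_WINDOW_BP + 1))
            pcg_start = int(rng.integers(0, config.chrom_length_bp - pcg_len
                                         - gap - lnc_len - 1))
            pcg_end = pcg_start + pcg_len
            lnc_start = pcg_end + gap
            lnc_end = lnc_start + lnc_len
            occupied = placed[chrom]
            if all(e <= pcg_start or s >= lnc_end for s, e in occupied):
                placed[chrom].extend([(pcg_start, pcg_end), (lnc_start, lnc_end)])
                lnc = GeneAnnotation(f"{tag}LNC{k:02d}", f"{tag}LNC{k:02d}", chrom,
                                     lnc_start, lnc_end, "+", "lncRNA")
                pcg = GeneAnnotation(f"{tag}PCG{k:02d}", f"{tag}PCG{k:02d}", chrom,
                                     pcg_start, pcg_end, "+", "protein_coding")
                return lnc, pcg
        raise CapacityError("could not place a cis pair; enlarge the genome")

    for k in range(1, config.n_cis_pairs + 1):
        lnc, pcg = place_pair("CIS", k)
        genes.extend([lnc, pcg])
    for k in range(1, config.n_decoy_lnc + 1):
        lnc, pcg = place_pair("DECOY", k)
        genes.extend([lnc, pcg])
    return GeneAnnotations(genes)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def design_truth(config: SimulationConfig, annotation: GeneAnnotations) -> GroundTruth:
    """Assign planted clusters/scopes and pair roles over the annotation."""
    rng = np.random.default_rng(config.seed + 1)
    regular = [g.gene_id for g in annotation
               if g.biotype in ("protein_coding", "lncRNA")
               and not g.gene_id.startswith(("CIS", "DECOY"))
               and g.gene_id != PTHLH_LIKE_ID]
    n_needed = sum(config.n_planted_per_cluster.values())
    if n_needed > len(regular):
        raise ValidationError("not enough regular genes to plant the clusters")
    chosen = list(rng.choice(regular, size=n_needed, replace=False))

    de_genes: dict[str, PlantedGene] = {}
    pos = 0
    f_wt, f_ko, _ = config.scope_fractions
    for cluster in sorted(config.n_planted_per_cluster):
        n = config.n_planted_per_cluster[cluster]
        n_wt = int(round(f_wt * n))
        n_ko = int(round(f_ko * n))
        scopes = ["WT"] * n_wt + ["KO"] * n_ko + ["both"] * (n - n_wt - n_ko)
        for scope in scopes:
            de_genes[chosen[pos]] = PlantedGene(cluster=cluster, scope=scope)
            pos += 1

    cis_pairs, decoy_pairs = [], []
    for k in range(1, config.n_cis_pairs + 1):
        lnc, pcg = f"CISLNC{k:02d}", f"CISPCG{k:02d}"
        # Pairs mirror the flagship finding: WT-exclusive, sustained-rise genes.
        de_genes[lnc] = PlantedGene(cluster=2, scope="WT")
        de_genes[pcg] = PlantedGene(cluster=2, scope="WT")
        cis_pairs.append((lnc, pcg))
    for k in range(1, config.n_decoy_lnc + 1):
        lnc, pcg = f"DECOYLNC{k:02d}", f"DECOYPCG{k:02d}"
        # Decoys are DE but flat across tumor stages, hence mutually
        # independent across the screen's sample scope (a correlation null).
        de_genes[lnc] = PlantedGene(cluster=None, scope="WT",
                                    flat_lfc=config.decoy_lfc)
        de_genes[pcg] = PlantedGene(cluster=None, scope="WT",
                                    flat_lfc=config.decoy_lfc)
        decoy_pairs.append((lnc, pcg))

    escapees: list[str] = []
    if config.n_escapees:
        ko_tumor = [f"{g}_{c}_wk{w}_r{r + 1}"
                    for g, c, w, n in config.design if g == "KO" and c == "tumor"
                    for r in range(n)]
        if config.n_escapees > len(ko_tumor):
            raise ValidationError("more escapees requested than KO tumor samples")
        escapees = sorted(rng.choice(ko_tumor, size=config.n_escapees, replace=False))
    return GroundTruth(de_genes, cis_pairs, decoy_pairs, escapees)


def tumor_stage_weeks(genotype: str) -> tuple[int, ...]:
    """Stage-aligned tumor timepoints: KO onset is delayed by one timepoint."""
    return (6, 8, 10) if genotype == "WT" else (8, 10, 12)


def planted_log2fc(config: SimulationConfig, planted: PlantedGene,
                   genotype: str, week: int) -> float:
    """Tumor-vs-tumor-free log2FC of a planted gene at one timepoint.

    KO trajectories start one timepoint later than WT ("delayed onset"):
    the archetype is indexed by stage order, not absolute weeks.
    """
    if planted.scope != "both" and planted.scope != genotype:
        return 0.0
    onset = {"WT": 6, "KO": 8}[genotype]
    stage = (week - onset) // 2
    if stage < 0:
        return 0.0
    if planted.flat_lfc is not None:
        return planted.flat_lfc
    shape = ARCHETYPE_SHAPES[planted.cluster]
    return config.planted_lfc * shape[min(stage, len(shape) - 1)]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def make_samples(config: SimulationConfig) -> list[SampleRecord]:
    samples = []
    for genotype, condition, week, n_reps in config.design:
        for r in range(1, n_reps + 1):
            samples.append(
                SampleRecord(f"{genotype}_{condition}_wk{week}_r{r}", genotype,
                             condition, week, r)
            )
    return samples


def nb_draws(rng, mean, dispersion: float, size=None) -> np.ndarray:
    """NB draws under variance = mu + alpha * mu^2 (alpha = dispersion)."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p, size=size if size is not None else mean.shape)


def correlated_nb_pair(rng, mean1, mean2, dispersion: float, rho: float):
    """Two NB count vectors coupled by a shared latent Gaussian factor.

    A bivariate-normal latent (correlation ``rho``) drives the NB quantiles
    of both genes (Gaussian copula), so marginal counts stay exactly NB while
    the pair's log-scale expression correlates at ~``rho``.
    """
    mean1 = np.asarray(mean1, dtype=float)
    mean2 = np.asarray(mean2, dtype=float)
    n = mean1.shape[0]
    shared = rng.standard_normal(n)
    own1 = rng.standard_normal(n)
    own2 = rng.standard_normal(n)
    a = math.sqrt(rho)
    b = math.sqrt(1.0 - rho)
    u1 = stats.norm.cdf(a * shared + b * own1)
    u2 = stats.norm.cdf(a * shared + b * own2)
    r = 1.0 / dispersion
    c1 = stats.nbinom.ppf(u1, r, r / (r + np.maximum(mean1, 1e-12)))
    c2 = stats.nbinom.ppf(u2, r, r / (r + np.maximum(mean2, 1e-12)))
    return c1.astype(np.int64), c2.astype(np.int64)


def expected_means(config: SimulationConfig, annotation: GeneAnnotations,
                   truth: GroundTruth, samples: Sequence[SampleRecord],
                   base_means: Mapping[str, float],
                   libsize: np.ndarray) -> pd.DataFrame:
    """Per-gene, per-sample NB means implied by the planted trajectories."""
    values = np.empty((len(annotation), len(samples)))
    for i, gene in enumerate(annotation):
        base = base_means[gene.gene_id]
        planted = truth.de_genes.get(gene.gene_id)
        for j, s in enumerate(samples):
            lfc = 0.0
            if planted is not None and s.condition == "tumor":
                lfc = planted_log2fc(config, planted, s.genotype, s.timepoint_weeks)
            values[i, j] = base * 2.0 ** lfc * libsize[j]
    return pd.DataFrame(values, index=annotation.ids,
                        columns=[s.sample_id for s in samples])


def _base_means(config: SimulationConfig, annotation: GeneAnnotations,
                truth: GroundTruth, rng) -> dict[str, float]:
    base: dict[str, float] = {}
    for gene in annotation:
        if gene.gene_id == GFP_ID:
            base[gene.gene_id] = config.gfp_mean
        elif gene.gene_id == MTD_ID:
            base[gene.gene_id] = config.mtd_mean
        elif gene.gene_id == PTHLH_LIKE_ID:
            base[gene.gene_id] = config.pthlh_mean
        elif gene.gene_id in truth.de_genes:
            base[gene.gene_id] = float(2.0 ** rng.normal(
                config.planted_base_log2_mean, config.planted_base_log2_sd))
        else:
            base[gene.gene_id] = float(2.0 ** rng.normal(
                config.mean_log2_expression, config.sd_log2_expression))
    return base


def simulate_counts(config: SimulationConfig, annotation: GeneAnnotations,
                    truth: GroundTruth) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the count matrix and the exon-level QC table.

    Returns the gene-level :class:`CountMatrix` and a small exon-count table
    (one row, ``PTHLH_LIKE:exon4``) modelling the floxed exon: zero in
    (non-escapee) KO samples, ~``pthlh_exon_fraction`` of the gene count in
    WT samples and escapees.
    """
    for gene_id in truth.de_genes:
        if gene_id not in annotation:
            raise ValidationError(f"truth references unknown gene {gene_id!r}")
    rng = np.random.default_rng(config.seed + 2)
    samples = make_samples(config)
    libsize = np.exp(rng.normal(0.0, config.libsize_sigma, size=len(samples)))
    base = _base_means(config, annotation, truth, rng)
    means = expected_means(config, annotation, truth, samples, base, libsize)

    counts = nb_draws(rng, means.to_numpy(), config.dispersion)
    gene_pos = {g: i for i, g in enumerate(annotation.ids)}
    for lnc, pcg in truth.cis_pairs:
        c_lnc, c_pcg = correlated_nb_pair(
            rng, means.loc[lnc].to_numpy(), means.loc[pcg].to_numpy(),
            config.dispersion, config.cis_pair_r_target)
        counts[gene_pos[lnc]] = c_lnc
        counts[gene_pos[pcg]] = c_pcg

    cm = CountMatrix(annotation.ids, samples, counts)

    exon_rows = []
    pthlh = cm.gene_counts(PTHLH_LIKE_ID)
    escapees = set(truth.ko_escapee_samples)
    for j, s in enumerate(samples):
        recombined = s.genotype == "KO" and s.sample_id not in escapees
        if recombined:
            exon_rows.append(0)
        else:
            exon_rows.append(int(rng.binomial(pthlh[j], config.pthlh_exon_fraction)))
    exon_counts = pd.DataFrame(
        [exon_rows], index=[f"{PTHLH_LIKE_ID}:exon{FLOXED_EXON}"],
        columns=[s.sample_id for s in samples])
    return cm, exon_counts


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def _build_gmt(config: SimulationConfig, annotation: GeneAnnotations,
               truth: GroundTruth, rng) -> GeneSetCollection:
    """Sets from planted cluster members plus random decoy sets."""
    sets = []
    for cluster in sorted({p.cluster for p in truth.de_genes.values()
                           if p.cluster is not None}):
        members = tuple(sorted(g for g, p in truth.de_genes.items()
                               if p.cluster == cluster))
        sets.append(GeneSet(f"PLANTED_CLUSTER{cluster}",
                            f"planted archetype-{cluster} genes", members))
    symbols = [g.symbol for g in annotation if g.biotype != "spike_in"]
    for k in range(1, 9):
        members = tuple(sorted(rng.choice(symbols, size=30, replace=False)))
        sets.append(GeneSet(f"RANDOM_SET_{k:02d}", "random decoy set", members))
    return GeneSetCollection(sets)


def export_fixture(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write the full fixture directory; byte-identical for a fixed config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(config)
    truth = design_truth(config, annotation)
    cm, exon_counts = simulate_counts(config, annotation, truth)

    paths = {
        "annotation": out_dir / "annotation.gtf",
        "counts": out_dir / "counts.tsv",
        "samples": out_dir / "samples.tsv",
        "gmt": out_dir / "sets.gmt",
        "truth": out_dir / "truth.tsv",
        "exon_counts": out_dir / "exon_counts.tsv",
    }
    write_gtf(annotation, paths["annotation"])
    write_counts(cm, paths["counts"], paths["samples"])
    rng = np.random.default_rng(config.seed + 3)
    write_gmt(_build_gmt(config, annotation, truth, rng), paths["gmt"])

    partner = {}
    role = {}
    for lnc, pcg in truth.cis_pairs:
        partner[lnc], partner[pcg] = pcg, lnc
        role[lnc], role[pcg] = "cis_lnc", "cis_pcg"
    for lnc, pcg in truth.decoy_pairs:
        partner[lnc], partner[pcg] = pcg, lnc
        role[lnc], role[pcg] = "decoy_lnc", "decoy_pcg"
    rows = [
        dict(gene_id=g,
             cluster="" if p.cluster is None else p.cluster,
             scope=p.scope,
             role=role.get(g, "cluster"),
             partner_id=partner.get(g, ""))
        for g, p in sorted(truth.de_genes.items())
    ]
    write_table(pd.DataFrame(rows), paths["truth"],
                params={"ko_escapee_samples": ",".join(truth.ko_escapee_samples),
                        "seed": config.seed})
    exon_counts.rename_axis("feature_id").to_csv(paths["exon_counts"], sep="\t")
    return paths


def read_ground_truth(path) -> GroundTruth:
    from .io import read_table

    df, params = read_table(path)
    df = df.fillna("")
    de_genes: dict[str, PlantedGene] = {}
    cis, decoy = {}, {}
    for r in df.itertuples():
        cluster = int(r.cluster) if r.cluster != "" else None
        flat = None if cluster is not None else 0.0  # magnitude not round-tripped
        de_genes[r.gene_id] = PlantedGene(cluster=cluster, scope=r.scope,
                                          flat_lfc=flat)
        if r.role == "cis_lnc":
            cis[r.gene_id] = r.partner_id
        elif r.role == "decoy_lnc":
            decoy[r.gene_id] = r.partner_id
    escapees = [s for s in params.get("ko_escapee_samples", "").split(",") if s]
    return GroundTruth(de_genes, sorted(cis.items()), sorted(decoy.items()), escapees)
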