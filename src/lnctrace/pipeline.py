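"""End-to-end orchestration: QC -> prefilter -> normalization ->
stage-matched differential expression -> DEG set algebra -> temporal
clustering -> enrichment -> cis-pair screen, with a machine-readable run
report and plain-text logging.

Every stage writes its table to ``out_dir`` with a ``# key=value`` header
recording the parameters, and the whole run is deterministic (byte-identical
outputs) for a fixed seed: the global seed is fanned out to per-stage seeds
by fixed offsets so stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import cispair, diffexpr, enrichment, qc, temporal
from .cispair import ScreenConfig
from .errors import ConfigError, ValidationError
from .io import read_counts, read_gmt, read_gtf, write_table
from .simulate import GFP_ID, MTD_ID, PTHLH_LIKE_ID, tumor_stage_weeks

logger = logging.getLogger("lnctrace")

# fixed per-stage seed offsets (global seed fan-out)
SEED_OFFSETS = {"kmeans": 101, "gsea": 202}


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    counts: Path
    samples: Path
    annotation: Path
    gmt: Path
    out_dir: Path
    exon_counts: Path | None = None
    gfp_id: str = GFP_ID
    mtd_id: str = MTD_ID
    pthlh_gene: str = PTHLH_LIKE_ID
    min_total: int = 10
    stagewise_fc: float = 1.5
    stagewise_fdr: float = 0.1
    timecourse_fc: float = 2.0
    timecourse_fdr: float = 0.1
    fc_scale: str = "linear"
    K: int = 3
    n_init: int = 25
    gsea_permutations: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    min_ratio: float = 10.0
    max_exon_fraction: float = 0.01
    wt_stage_weeks: tuple[int, ...] = tumor_stage_weeks("WT")
    ko_stage_weeks: tuple[int, ...] = tumor_stage_weeks("KO")
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    seed: int = 0

    def validate(self) -> None:
        for name in ("counts", "samples", "annotation", "gmt"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise ConfigError(f"{name} file does not exist: {path}")
        if self.exon_counts is not None and not Path(self.exon_counts).is_file():
            raise ConfigError(f"exon_counts file does not exist: {self.exon_counts}")
        inputs = {Path(getattr(self, n)).resolve()
                  for n in ("counts", "samples", "annotation", "gmt")}
        if Path(self.out_dir).resolve() in {p.parent for p in inputs}:
            raise ConfigError("out_dir must be distinct from the input directories")
        for fc in (self.stagewise_fc, self.timecourse_fc):
            if self.fc_scale == "linear" and fc <= 1:
                raise ConfigError(f"fold-change threshold must be > 1, got {fc}")
        for fdr in (self.stagewise_fdr, self.timecourse_fdr):
            if not 0 < fdr < 1:
                raise ConfigError(f"FDR threshold must be in (0, 1), got {fdr}")
        if self.K < 1:
            raise ConfigError("K must be >= 1")


class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys."""


def _no_dupes(loader, node, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ConfigError(f"duplicate key {key!r} in config")
        seen.add(key)
    return yaml.SafeLoader.construct_mapping(loader, node, deep)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_dupes)

_PATH_KEYS = ("counts", "samples", "annotation", "gmt", "out_dir", "exon_counts")


def validate_config(path) -> PipelineConfig:
    """Parse and type-check a YAML config file; unknown keys are errors."""
    path = Path(path)
    with open(path) as fh:
        try:
            raw = yaml.load(fh, Loader=_StrictLoader)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    screen_raw = raw.pop("screen", {}) or {}
    known = set(PipelineConfig.__dataclass_fields__) - {"screen"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    unknown_screen = sorted(set(screen_raw) - set(ScreenConfig.__dataclass_fields__))
    if unknown_screen:
        raise ConfigError(f"unknown screen keys: {unknown_screen}")
    missing = [k for k in ("counts", "samples", "annotation", "gmt", "out_dir")
               if k not in raw]
    if missing:
        raise ConfigError(f"missing required config keys: {missing}")
    for key in _PATH_KEYS:
        if key in raw and raw[key] is not None:
            raw[key] = (path.parent / raw[key]).resolve() \
                if not Path(raw[key]).is_absolute() else Path(raw[key])
    for key in ("wt_stage_weeks", "ko_stage_weeks"):
        if key in raw:
            raw[key] = tuple(int(w) for w in raw[key])
    config = PipelineConfig(screen=ScreenConfig(**screen_raw), **raw)
    config.validate()
    logger.info("resolved config: %s", config)
    return config


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------

@dataclass
class StageRecord:
    name: str
    params: dict
    outputs: list[str]
    numbers: dict


@dataclass
class RunReport:
    seed: int
    version: str
    input_digests: dict[str, str]
    stages: list[StageRecord] = field(default_factory=list)

    def add(self, name: str, params: Mapping, outputs: list, numbers: Mapping
            ) -> None:
        self.stages.append(StageRecord(name, dict(params),
                                       [Path(p).name for p in outputs],
                                       dict(numbers)))
        logger.info("stage %s: %s", name, dict(numbers))

    def headline(self) -> dict:
        out: dict = {}
        for s in self.stages:
            out.update({f"{s.name}.{k}": v for k, v in s.numbers.items()})
        return out

    def write(self, path) -> None:
        payload = dict(seed=self.seed, version=self.version,
                       input_digests=self.input_digests,
                       stages=[asdict(s) for s in self.stages])
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                         default=str) + "\n")


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig) -> RunReport:
    """Execute every stage on the configured inputs; idempotent given seed."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        seed=config.seed, version=__version__,
        input_digests={n: _digest(getattr(config, n))
                       for n in ("counts", "samples", "annotation", "gmt")})

    annotation = read_gtf(config.annotation)
    counts = read_counts(config.counts, config.samples)
    collection = read_gmt(config.gmt)

    # ---- QC -------------------------------------------------------------
    exon_vec = None
    if config.exon_counts is not None:
        exon_df = pd.read_csv(config.exon_counts, sep="\t", index_col=0)
        feature = f"{config.pthlh_gene}:exon4"
        if feature in exon_df.index:
            exon_vec = exon_df.loc[feature, counts.sample_ids].to_numpy()
    qc_table = qc.qc_report(counts, config.gfp_id, config.mtd_id,
                            exon_counts=exon_vec,
                            pthlh_gene=config.pthlh_gene if exon_vec is not None
                            else None,
                            min_ratio=config.min_ratio,
                            max_exon_fraction=config.max_exon_fraction)
    qc_path = out / "qc_report.tsv"
    write_table(qc_table.reset_index(), qc_path,
                params=dict(min_ratio=config.min_ratio,
                            max_exon_fraction=config.max_exon_fraction))
    numbers = dict(n_samples=len(counts.samples),
                   n_recombination_ok=int(qc_table["recombination_ok"].sum()))
    if "escapee" in qc_table:
        numbers["n_escapees"] = int(qc_table["escapee"].sum())
    report.add("qc", dict(min_ratio=config.min_ratio), [qc_path], numbers)

    # ---- prefilter + normalization ---------------------------------------
    filtered = diffexpr.prefilter(counts, config.min_total)
    factors = diffexpr.size_factors(filtered)
    norm = diffexpr.normalize(filtered, factors)
    sf_path = out / "size_factors.tsv"
    write_table(pd.DataFrame({"sample_id": filtered.sample_ids,
                              "size_factor": factors}), sf_path,
                params=dict(min_total=config.min_total))
    report.add("normalize", dict(min_total=config.min_total), [sf_path],
               dict(n_genes_kept=len(filtered.gene_ids),
                    n_genes_dropped=len(counts.gene_ids) - len(filtered.gene_ids)))

    # ---- PCA --------------------------------------------------------------
    coords, evr = diffexpr.pca(norm.normalized)
    pca_path = out / "pca.tsv"
    write_table(coords.reset_index(names="sample_id"), pca_path,
                params=dict(explained_variance=",".join(f"{v:.6g}" for v in evr)))
    report.add("pca", dict(n_top_genes=500), [pca_path],
               dict(pc1_explained=round(float(evr[0]), 4)))

    # ---- stage-matched DE -------------------------------------------------
    dispersions = diffexpr.estimate_dispersions(filtered, factors)
    stage_weeks = {"WT": tuple(config.wt_stage_weeks),
                   "KO": tuple(config.ko_stage_weeks)}
    de_results: dict[tuple[str, int], diffexpr.DEResult] = {}
    deg_sets: dict[str, dict[int, frozenset]] = {"WT": {}, "KO": {}}
    de_paths = []
    de_numbers = {}
    for genotype, weeks in stage_weeks.items():
        for week in weeks:
            res = diffexpr.nb_wald_test(filtered, (genotype, week), factors,
                                        dispersions)
            de_results[(genotype, week)] = res
            degs = diffexpr.call_degs(res, config.stagewise_fc,
                                      config.stagewise_fdr, "both",
                                      config.fc_scale)
            deg_sets[genotype][week] = degs.gene_ids
            path = out / f"de_{genotype}_wk{week}.tsv"
            write_table(res.table, path,
                        params=dict(genotype=genotype, timepoint_weeks=week,
                                    fc=config.stagewise_fc,
                                    fdr=config.stagewise_fdr))
            de_paths.append(path)
            de_numbers[f"degs_{genotype}_wk{week}"] = len(degs.gene_ids)
    report.add("diffexpr", dict(fc=config.stagewise_fc, fdr=config.stagewise_fdr),
               de_paths, de_numbers)

    # ---- DEG Venn partition ------------------------------------------------
    venn_paths = []
    venn_numbers = {}
    for genotype in ("WT", "KO"):
        venn = diffexpr.deg_set_algebra(deg_sets[genotype])
        rows = [dict(region="+".join(str(k) for k in sorted(key)),
                     n=len(members), genes=",".join(sorted(members)))
                for key, members in sorted(venn.regions.items(),
                                           key=lambda kv: sorted(map(str, kv[0])))]
        path = out / f"venn_{genotype}.tsv"
        write_table(pd.DataFrame(rows), path, params=dict(genotype=genotype))
        venn_paths.append(path)
        venn_numbers[f"union_{genotype}"] = len(venn.union)
        all_region = frozenset(deg_sets[genotype])
        venn_numbers[f"all_timepoints_{genotype}"] = len(venn.regions[all_region])
    report.add("deg_venn", {}, venn_paths, venn_numbers)

    # ---- hyperplasia DEGs and temporal clustering ---------------------------
    hyper: dict[str, frozenset] = {}
    for genotype, weeks in stage_weeks.items():
        res = de_results[(genotype, weeks[0])]
        degs = diffexpr.call_degs(res, config.timecourse_fc,
                                  config.timecourse_fdr, "both", config.fc_scale)
        hyper[genotype] = degs.gene_ids
    profiles = temporal.build_trajectories(
        norm.normalized, filtered.samples,
        {g: sorted(hyper[g]) for g in ("WT", "KO")}, stage_weeks)
    zprofiles = temporal.zscore_profiles(profiles)
    fit = temporal.kmeans_cluster(zprofiles, config.K,
                                  seed=config.seed + SEED_OFFSETS["kmeans"],
                                  n_init=config.n_init)
    archetype_of = temporal.match_archetypes(fit.centroids)
    clusters = fit.assignments.map(archetype_of)
    cluster_df = clusters.rename("cluster").reset_index()
    clusters_path = out / "clusters.tsv"
    write_table(cluster_df, clusters_path,
                params=dict(K=config.K, n_init=config.n_init,
                            seed=config.seed + SEED_OFFSETS["kmeans"],
                            fc=config.timecourse_fc, fdr=config.timecourse_fdr))
    centroid_df = pd.DataFrame(fit.centroids,
                               columns=zprofiles.values.columns)
    centroid_df.insert(0, "cluster",
                       [archetype_of[i + 1] for i in range(config.K)])
    centroids_path = out / "centroids.tsv"
    write_table(centroid_df.sort_values("cluster"), centroids_path,
                params=dict(total_within_ss=f"{fit.total_within_ss:.10g}"))
    cluster_sizes = {f"cluster{c}": int((clusters == c).sum())
                     for c in sorted(set(clusters))}
    report.add("temporal", dict(K=config.K),
               [clusters_path, centroids_path],
               dict(n_hyperplasia_wt=len(hyper["WT"]),
                    n_hyperplasia_ko=len(hyper["KO"]), **cluster_sizes))

    # ---- exclusivity partition ----------------------------------------------
    wt_assign = {g: c for (gt, g), c in clusters.items() if gt == "WT"}
    ko_assign = {g: c for (gt, g), c in clusters.items() if gt == "KO"}
    excl_rows = []
    excl_numbers = {}
    wt_exclusive_all: set[str] = set()
    for cluster_id in sorted(set(clusters)):
        wt_only, ko_only, shared = temporal.exclusivity_partition(
            wt_assign, ko_assign, cluster_id)
        wt_exclusive_all |= wt_only
        for label, genes in (("wt_only", wt_only), ("ko_only", ko_only),
                             ("shared", shared)):
            excl_rows.append(dict(cluster=cluster_id, region=label,
                                  n=len(genes), genes=",".join(sorted(genes))))
        excl_numbers[f"cluster{cluster_id}_wt_only"] = len(wt_only)
        excl_numbers[f"cluster{cluster_id}_ko_only"] = len(ko_only)
        excl_numbers[f"cluster{cluster_id}_shared"] = len(shared)
    excl_path = out / "exclusivity.tsv"
    write_table(pd.DataFrame(excl_rows), excl_path, params={})
    report.add("exclusivity", {}, [excl_path], excl_numbers)

    # ---- enrichment -----------------------------------------------------------
    gsea_paths = []
    gsea_numbers = {}
    for genotype, weeks in stage_weeks.items():
        ranked = enrichment.rank_genes(de_results[(genotype, weeks[0])])
        gsea_df = enrichment.gsea_preranked(
            ranked, collection, config.gsea_permutations,
            seed=config.seed + SEED_OFFSETS["gsea"],
            min_size=config.gsea_min_size, max_size=config.gsea_max_size)
        path = out / f"gsea_{genotype}_wk{weeks[0]}.tsv"
        write_table(gsea_df, path,
                    params=dict(genotype=genotype, timepoint_weeks=weeks[0],
                                permutations=config.gsea_permutations,
                                seed=config.seed + SEED_OFFSETS["gsea"]))
        gsea_paths.append(path)
        gsea_numbers[f"gsea_sets_{genotype}"] = len(gsea_df)
        gsea_numbers[f"gsea_sig_{genotype}"] = int((gsea_df["fdr"] < 0.1).sum()) \
            if len(gsea_df) else 0
    universe = set(de_results[("WT", stage_weeks["WT"][0])].table["gene_id"])
    ora_df = enrichment.ora_hypergeometric(wt_exclusive_all & universe,
                                           collection, universe)
    ora_path = out / "ora_wt_exclusive.tsv"
    write_table(ora_df, ora_path, params=dict(query="wt_exclusive_all_clusters"))
    report.add("enrichment", dict(permutations=config.gsea_permutations),
               [*gsea_paths, ora_path],
               dict(**gsea_numbers, ora_sig=int((ora_df["fdr"] < 0.1).sum())
                    if len(ora_df) else 0))

    # ---- cis screen ------------------------------------------------------------
    # The screen targets co-upregulated pairs: both members must be DE-up in
    # WT at hyperplasia.  WT-exclusivity (not also DE-up in KO) is reported
    # per pair rather than imposed as a hard pre-filter.
    wt_up = diffexpr.call_degs(de_results[("WT", stage_weeks["WT"][0])],
                               config.timecourse_fc, config.timecourse_fdr,
                               "up", config.fc_scale).gene_ids
    ko_up = diffexpr.call_degs(de_results[("KO", stage_weeks["KO"][0])],
                               config.timecourse_fc, config.timecourse_fdr,
                               "up", config.fc_scale).gene_ids
    lnc_ids, pcg_ids, _ = cispair.classify_biotypes(wt_up, annotation)
    scope_ids = [s.sample_id for s in filtered.samples
                 if s.genotype == "WT" and s.condition == "tumor"]
    log_expr = np.log2(norm.normalized[scope_ids] + 1.0)
    screenable_lnc = [g for g in lnc_ids if g in log_expr.index]
    screenable_pcg = [g for g in pcg_ids if g in log_expr.index]
    pairs = cispair.screen_pairs(log_expr, screenable_lnc, screenable_pcg,
                                 annotation, config.screen)
    evaluated = cispair.pairs_frame(pairs)
    evaluated["wt_exclusive"] = [
        p.lncRNA_id not in ko_up and p.pcg_id not in ko_up for p in pairs]
    evaluated_path = out / "pairs_evaluated.tsv"
    write_table(evaluated, evaluated_path,
                params=dict(window_bp=config.screen.window_bp,
                            r_min=config.screen.r_min,
                            p_max=config.screen.p_max,
                            n_samples=len(scope_ids)))
    pairs_path = out / "pairs.tsv"
    cispair.write_pair_table(pairs, pairs_path,
                             params=dict(window_bp=config.screen.window_bp,
                                         r_min=config.screen.r_min,
                                         p_max=config.screen.p_max))
    report.add("cis_screen",
               dict(window_bp=config.screen.window_bp, r_min=config.screen.r_min,
                    p_max=config.screen.p_max),
               [evaluated_path, pairs_path],
               dict(n_de_lncrna=len(lnc_ids), n_de_pcg=len(pcg_ids),
                    n_evaluated=len(pairs),
                    n_reported=len(cispair.reported_pairs(pairs)),
                    n_reported_wt_exclusive=int(
                        sum(1 for p, excl in zip(pairs, evaluated["wt_exclusive"])
                            if p.reported and excl))))

    report.write(out / "run_report.json")
    return report
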