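"""The cis-regulation screen: differentially expressed lncRNAs are paired
with differentially expressed protein-coding genes lying within a +/-500 kb
genomic window, and each pair's expression correlation is tested.

A pair is reported when it passes all three filters: same chromosome within
the window (span gap <= 500 kb, inclusive, 0 when the spans overlap), a
Pearson correlation of at least ``r_min`` (signed by default: the screen
targets co-upregulated pairs), and a correlation p-value below ``p_max``
(two-sided t test on n-2 degrees of freedom).  Correlations are computed on
log2(normalized + 1) expression across the configured sample scope — by
default all tumor samples of one genotype pooled over timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .io import GeneAnnotation, GeneAnnotations, write_table

DEFAULT_WINDOW_BP = 500_000

PAIR_TABLE_COLUMNS = ["lncRNA", "protein_coding_gene", "PCC", "p_value",
                      "distance_bp", "n_samples"]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and conventions of the windowed correlation screen."""

    window_bp: int = DEFAULT_WINDOW_BP
    r_min: float = 0.80
    p_max: float = 0.01
    r_mode: str = "signed"  # signed | absolute
    distance_anchor: str = "span_gap"  # span_gap | start_to_start | tss_to_tss

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= 1:
            raise ConfigError("r_min must be in (0, 1]")
        if not 0 < self.p_max < 1:
            raise ConfigError("p_max must be in (0, 1)")
        if self.r_mode not in ("signed", "absolute"):
            raise ConfigError(f"bad r_mode {self.r_mode!r}")
        if self.distance_anchor not in ("span_gap", "start_to_start", "tss_to_tss"):
            raise ConfigError(f"bad distance_anchor {self.distance_anchor!r}")
        if self.window_bp <= 0:
            raise ConfigError("window_bp must be positive")


@dataclass(frozen=True)
class CisPair:
    """One evaluated lncRNA / protein-coding-gene candidate pair."""

    lncRNA_id: str
    pcg_id: str
    chrom: str
    genomic_distance_bp: int
    pearson_r: float
    pvalue: float
    n_samples: int
    passes_window: bool
    passes_r: bool
    passes_p: bool

    @property
    def reported(self) -> bool:
        return self.passes_window and self.passes_r and self.passes_p


# ---------------------------------------------------------------------------
# biotypes and windows
# ---------------------------------------------------------------------------

def classify_biotypes(gene_ids: Iterable[str], annotation: GeneAnnotations
                      ) -> tuple[list[str], list[str], list[str]]:
    """Partition a DEG set into (lncRNA, protein-coding, other) id lists.

    Genes missing from the annotation are reported as "other" with a warning.
    """
    lnc, pcg, other = [], [], []
    missing = []
    for g in sorted(set(gene_ids)):
        ann = annotation.get(g)
        if ann is None:
            missing.append(g)
            other.append(g)
        elif ann.biotype == "lncRNA":
            lnc.append(g)
        elif ann.biotype == "protein_coding":
            pcg.append(g)
        else:
            other.append(g)
    if missing:
        warnings.warn(f"genes missing from annotation treated as 'other': "
                      f"{missing}", stacklevel=2)
    return lnc, pcg, other


def span_gap(a: GeneAnnotation, b: GeneAnnotation) -> int:
    """Gap between two gene spans on the same chromosome (0 if overlapping)."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def genomic_distance(a: GeneAnnotation, b: GeneAnnotation,
                     anchor: str = "span_gap") -> int:
    if anchor == "span_gap":
        return span_gap(a, b)
    if anchor == "start_to_start":
        return abs(a.start - b.start)
    if anchor == "tss_to_tss":
        return abs(a.tss - b.tss)
    raise ConfigError(f"bad distance_anchor {anchor!r}")


def window_candidates(lnc: GeneAnnotation,
                      pcg_pool: Iterable[GeneAnnotation],
                      window_bp: int = DEFAULT_WINDOW_BP,
                      anchor: str = "span_gap"
                      ) -> list[tuple[GeneAnnotation, int]]:
    """Protein-coding genes within the window of a lncRNA, with distances.

    Same chromosome only; the window boundary is inclusive ("within 500 kb");
    strand is ignored.  The empty list is a valid result.
    """
    out = []
    for pcg in pcg_pool:
        if pcg.chrom != lnc.chrom or pcg.gene_id == lnc.gene_id:
            continue
        d = genomic_distance(lnc, pcg, anchor)
        if d <= window_bp:
            out.append((pcg, d))
    out.sort(key=lambda cd: (cd[1], cd[0].gene_id))
    return out


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p (t on n-2 df); r = +/-1 -> p = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("correlation needs n >= 3 samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def screen_pairs(log_expr: pd.DataFrame, lnc_degs: Iterable[str],
                 pcg_degs: Iterable[str], annotation: GeneAnnotations,
                 config: ScreenConfig = ScreenConfig()) -> list[CisPair]:
    """Evaluate every DE-lncRNA x in-window DE-PCG pair.

    ``log_expr`` is the log2(normalized + 1) matrix already restricted to the
    sample scope of the screen (genes x samples).  Every evaluated pair is
    returned with its three pass flags; the report is the subset passing all
    flags (see :func:`reported_pairs`).
    """
    n_samples = log_expr.shape[1]
    if n_samples < 3:
        raise ConfigError(f"sample scope selects only {n_samples} samples (< 3)")
    lnc_degs = sorted(set(lnc_degs))
    pcg_degs = sorted(set(pcg_degs))
    missing = [g for g in (*lnc_degs, *pcg_degs)
               if g not in log_expr.index or g not in annotation]
    if missing:
        raise ValidationError(
            f"DEG ids absent from expression matrix or annotation: {missing}")
    pcg_pool = [annotation[g] for g in pcg_degs]
    pairs: list[CisPair] = []
    for lnc_id in lnc_degs:
        lnc = annotation[lnc_id]
        x = log_expr.loc[lnc_id].to_numpy()
        for pcg, dist in window_candidates(lnc, pcg_pool, config.window_bp,
                                           config.distance_anchor):
            y = log_expr.loc[pcg.gene_id].to_numpy()
            try:
                r, p = pearson_with_p(x, y)
            except ValidationError:
                warnings.warn(
                    f"pair ({lnc_id}, {pcg.gene_id}) skipped: constant "
                    "expression vector", stacklevel=2)
                continue
            r_stat = abs(r) if config.r_mode == "absolute" else r
            pairs.append(CisPair(
                lncRNA_id=lnc_id, pcg_id=pcg.gene_id, chrom=lnc.chrom,
                genomic_distance_bp=int(dist), pearson_r=r, pvalue=p,
                n_samples=n_samples,
                passes_window=dist <= config.window_bp,
                passes_r=r_stat >= config.r_min,
                passes_p=p < config.p_max,
            ))
    return pairs


def reported_pairs(pairs: Iterable[CisPair]) -> list[CisPair]:
    """Pairs passing all three filters, sorted by descending correlation."""
    return sorted((p for p in pairs if p.reported),
                  key=lambda p: (-p.pearson_r, p.lncRNA_id, p.pcg_id))


def pairs_frame(pairs: Iterable[CisPair]) -> pd.DataFrame:
    """Full evaluated-pair table including the pass flags."""
    return pd.DataFrame([
        dict(lncRNA=p.lncRNA_id, protein_coding_gene=p.pcg_id, chrom=p.chrom,
             distance_bp=p.genomic_distance_bp, PCC=p.pearson_r,
             p_value=p.pvalue, n_samples=p.n_samples,
             passes_window=p.passes_window, passes_r=p.passes_r,
             passes_p=p.passes_p)
        for p in pairs
    ], columns=["lncRNA", "protein_coding_gene", "chrom", "distance_bp", "PCC",
                "p_value", "n_samples", "passes_window", "passes_r", "passes_p"])


def write_pair_table(pairs: Iterable[CisPair], path,
                     params: dict | None = None) -> None:
    """Write the report (pairs passing all filters) as a TSV."""
    rep = reported_pairs(pairs)
    df = pd.DataFrame([
        dict(lncRNA=p.lncRNA_id, protein_coding_gene=p.pcg_id,
             PCC=p.pearson_r, p_value=p.pvalue,
             distance_bp=p.genomic_distance_bp, n_samples=p.n_samples)
        for p in rep
    ], columns=PAIR_TABLE_COLUMNS)
    write_table(df, path, params=params)


def read_pair_table(path) -> pd.DataFrame:
    from .io import read_table

    df, _ = read_table(path)
    return df
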