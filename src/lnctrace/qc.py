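"""Count-level sample QC for the lineage-traced knockout design.

Three checks run before any analysis: the Cre reporter check (GFP spike-in
reads must dominate mTd reads in sorted GFP+ cells), the floxed-exon check
(KO samples must have essentially no reads on the loxP-flanked exon — a
sample with reads there is a recombination "escapee"), and a per-sample
detected-gene count.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import CountMatrix, SampleRecord

DEFAULT_MIN_RATIO = 10.0
DEFAULT_MAX_EXON_FRACTION = 0.01


def recombination_check(counts: CountMatrix, gfp_id: str, mtd_id: str,
                        min_ratio: float = DEFAULT_MIN_RATIO) -> pd.DataFrame:
    """Per-sample GFP/mTd reporter check.

    A sample passes iff ``(gfp + 1) / (mtd + 1) >= min_ratio`` (pseudocount 1
    avoids division by zero).  Samples with no reads on either spike-in are
    additionally flagged ``no_signal``.
    """
    for sid in (gfp_id, mtd_id):
        if sid not in counts.gene_ids:
            raise ConfigError(f"spike-in row {sid!r} absent from count matrix")
    gfp = counts.gene_counts(gfp_id).astype(float)
    mtd = counts.gene_counts(mtd_id).astype(float)
    ratio = (gfp + 1.0) / (mtd + 1.0)
    return pd.DataFrame(
        {
            "gfp_count": gfp.astype(int),
            "mtd_count": mtd.astype(int),
            "ratio": ratio,
            "recombination_ok": ratio >= min_ratio,
            "no_signal": (gfp == 0) & (mtd == 0),
        },
        index=pd.Index(counts.sample_ids, name="sample_id"),
    )


def floxed_exon_check(exon_counts: Sequence[int], gene_counts: Sequence[int],
                      samples: Sequence[SampleRecord],
                      max_exon_fraction: float = DEFAULT_MAX_EXON_FRACTION,
                      ) -> pd.DataFrame:
    """Knockout concordance from floxed-exon coverage.

    A KO sample is concordant iff ``exon / (gene + 1) <= max_exon_fraction``;
    discordant KO samples are escapees (cells that evaded Cre excision).
    WT samples are reported not-applicable (``ko_concordant`` is NA).
    """
    exon = np.asarray(exon_counts, dtype=float)
    gene = np.asarray(gene_counts, dtype=float)
    if not (len(exon) == len(gene) == len(samples)):
        raise ValidationError(
            f"length mismatch: {len(exon)} exon counts, {len(gene)} gene "
            f"counts, {len(samples)} samples"
        )
    if (exon < 0).any() or (gene < 0).any():
        raise ValidationError("counts must be non-negative")
    fraction = exon / (gene + 1.0)
    is_ko = np.array([s.genotype == "KO" for s in samples])
    concordant = pd.array(fraction <= max_exon_fraction, dtype="boolean")
    concordant[~is_ko] = pd.NA
    return pd.DataFrame(
        {
            "exon4_count": exon.astype(int),
            "gene_count": gene.astype(int),
            "exon_fraction": fraction,
            "ko_concordant": concordant,
            "escapee": pd.array(is_ko & (fraction > max_exon_fraction)),
        },
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )


def genes_detected(counts: CountMatrix, min_count: int = 1) -> pd.Series:
    """Number of genes with count >= ``min_count`` in each sample."""
    detected = (counts.counts >= min_count).sum(axis=0)
    return pd.Series(detected, index=pd.Index(counts.sample_ids, name="sample_id"),
                     name="genes_detected")


def qc_report(counts: CountMatrix, gfp_id: str, mtd_id: str,
              exon_counts: Sequence[int] | None = None,
              pthlh_gene: str | None = None,
              min_ratio: float = DEFAULT_MIN_RATIO,
              max_exon_fraction: float = DEFAULT_MAX_EXON_FRACTION,
              min_count: int = 1) -> pd.DataFrame:
    """Combined per-sample QC table (reporter, knockout and detection checks)."""
    report = recombination_check(counts, gfp_id, mtd_id, min_ratio)
    report["genes_detected"] = genes_detected(counts, min_count)
    if exon_counts is not None and pthlh_gene is not None:
        flox = floxed_exon_check(exon_counts, counts.gene_counts(pthlh_gene),
                                 counts.samples, max_exon_fraction)
        report = report.join(flox[["exon4_count", "gene_count", "exon_fraction",
                                   "ko_concordant", "escapee"]])
    return report
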