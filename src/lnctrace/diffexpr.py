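"""Normalization, per-gene NB Wald differential expression, DEG set algebra
and PCA for the tumor vs age-matched tumor-free contrasts.

The model
---------
Counts :math:`K_{gj}` are treated as negative binomial with mean
:math:`s_j \\mu_{gc(j)}` and variance :math:`\\mu + \\alpha_g \\mu^2`
(:math:`s_j` = median-of-ratios size factor, :math:`c(j)` = the sample's
condition).  Per condition the mean is estimated as
:math:`\\hat\\mu_c = \\sum_j K_{gj} / \\sum_j s_j`; the per-gene dispersion
:math:`\\alpha_g` by method of moments on normalized counts, pooling
residuals within every replicate group of the matrix.  The Wald statistic is
``log2fc / se`` with the standard error from the NB delta method, two-sided
p-values from the standard normal, and Benjamini-Hochberg adjustment across
tested genes.  This is a deliberately transparent reimplementation of the
"NB test + FC/FDR thresholds" contract: no dispersion shrinkage, no
independent filtering, no LFC moderation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContrastError, ValidationError
from .io import CountMatrix, SampleRecord

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
DISPERSION_CEILING = 10.0
FC_EPSILON = 0.5  # pseudo normalized count taming log2FC at zeros

DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "se", "wald_stat", "pvalue", "padj"]


# ---------------------------------------------------------------------------
# prefilter and normalization
# ---------------------------------------------------------------------------

def prefilter(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Keep genes with total count across all samples >= ``min_total``."""
    totals = counts.counts.sum(axis=1)
    keep = [g for g, t in zip(counts.gene_ids, totals) if t >= min_total]
    if not keep:
        warnings.warn("prefilter removed every gene", stacklevel=2)
        return CountMatrix([], counts.samples,
                           np.empty((0, len(counts.samples)), dtype=np.int64))
    return counts.select_genes(keep)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    For sample j, the factor is the median over genes of
    ``counts[g, j] / geomean_g`` where the geometric mean is taken across
    samples, restricted to genes with all-positive counts (positive geomean).
    """
    k = counts.counts.astype(float)
    if k.shape[1] == 1:
        return np.ones(1)
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene with positive counts in every sample; "
            "size factors are undefined"
        )
    logk = np.log(k[positive])
    log_geomean = logk.mean(axis=1)
    ratios = np.exp(logk - log_geomean[:, None])
    sf = np.median(ratios, axis=0)
    if (sf <= 0).any():
        raise ValidationError("non-positive size factor")
    return sf


@dataclass(frozen=True)
class NormalizationResult:
    size_factors: np.ndarray
    normalized: pd.DataFrame  # gene x sample, counts / size_factor


def normalize(counts: CountMatrix, factors: np.ndarray | None = None
              ) -> NormalizationResult:
    if factors is None:
        factors = size_factors(counts)
    factors = np.asarray(factors, dtype=float)
    norm = pd.DataFrame(counts.counts / factors[None, :], index=counts.gene_ids,
                        columns=counts.sample_ids)
    return NormalizationResult(factors, norm)


# ---------------------------------------------------------------------------
# dispersion and the Wald test
# ---------------------------------------------------------------------------

def _replicate_groups(samples: Sequence[SampleRecord]) -> list[np.ndarray]:
    groups: dict[tuple, list[int]] = {}
    for j, s in enumerate(samples):
        groups.setdefault(s.group, []).append(j)
    return [np.asarray(idx) for idx in groups.values()]


def estimate_dispersions(counts: CountMatrix, factors: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments dispersion, pooled over replicate groups.

    Within every (genotype, condition, timepoint) group the NB law gives
    ``E[SS_c] = (n_c - 1)(mu_c + alpha * mu_c^2)`` for the normalized-count
    residual sum of squares, so ``alpha`` is estimated as
    ``(sum_c SS_c - sum_c (n_c-1) mu_c) / sum_c (n_c-1) mu_c^2`` and clipped
    to [1e-8, 10].  Pooling over all groups of the supplied matrix (rather
    than only a single contrast's five samples) is what keeps the Wald
    statistic close to its nominal normal null.
    """
    q = counts.counts / np.asarray(factors, dtype=float)[None, :]
    ss = np.zeros(q.shape[0])
    lin = np.zeros(q.shape[0])
    quad = np.zeros(q.shape[0])
    for idx in _replicate_groups(counts.samples):
        if len(idx) < 2:
            continue
        sub = q[:, idx]
        m = sub.mean(axis=1)
        ss += ((sub - m[:, None]) ** 2).sum(axis=1)
        lin += (len(idx) - 1) * m
        quad += (len(idx) - 1) * m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (ss - lin) / quad
    alpha[~np.isfinite(alpha)] = DISPERSION_FLOOR
    return np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEILING)


@dataclass(frozen=True)
class DEResult:
    """Per-gene Wald-test results for one tumor vs tumor-free contrast."""

    table: pd.DataFrame  # columns DE_COLUMNS
    contrast: tuple[str, int]  # (genotype, timepoint_weeks)


def nb_wald_test(counts: CountMatrix, contrast: tuple[str, int],
                 factors: np.ndarray | None = None,
                 dispersions: np.ndarray | None = None,
                 epsilon: float = FC_EPSILON) -> DEResult:
    """NB Wald test of tumor vs age-matched tumor-free for one genotype.

    ``contrast`` is (genotype, timepoint_weeks).  Size factors and
    dispersions default to estimates from the full supplied matrix.
    """
    genotype, week = contrast
    tumor = np.array([s.genotype == genotype and s.timepoint_weeks == week
                      and s.condition == "tumor" for s in counts.samples])
    free = np.array([s.genotype == genotype and s.timepoint_weeks == week
                     and s.condition == "tumor_free" for s in counts.samples])
    if tumor.sum() < 2 or free.sum() < 2:
        raise ContrastError(
            f"contrast {contrast} needs >= 2 replicates per condition "
            f"(found {int(tumor.sum())} tumor, {int(free.sum())} tumor-free)"
        )
    if factors is None:
        factors = size_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, factors)
    alpha = np.asarray(dispersions, dtype=float)

    k = counts.counts.astype(float)
    s_t, s_f = factors[tumor], factors[free]
    mu_t = k[:, tumor].sum(axis=1) / s_t.sum()
    mu_f = k[:, free].sum(axis=1) / s_f.sum()

    log2fc = np.log2((mu_t + epsilon) / (mu_f + epsilon))

    # Var(mu_hat_c) with mu_hat_c = sum K / sum s and Var(K_j) = s_j mu + a s_j^2 mu^2
    var_mu_t = (s_t.sum() * mu_t + alpha * (s_t ** 2).sum() * mu_t ** 2) / s_t.sum() ** 2
    var_mu_f = (s_f.sum() * mu_f + alpha * (s_f ** 2).sum() * mu_f ** 2) / s_f.sum() ** 2
    var_log2 = (var_mu_t / (mu_t + epsilon) ** 2
                + var_mu_f / (mu_f + epsilon) ** 2) / LN2 ** 2
    # First-order plug-in correction: the dispersion entering the variance is
    # itself estimated on m residual df, which biases the nominal-normal Wald
    # test anticonservative; inflating by (1 + 2/m) restores calibration and
    # vanishes as m grows.
    m_df = sum(max(0, len(idx) - 1) for idx in _replicate_groups(counts.samples))
    var_log2 = var_log2 * (1.0 + 2.0 / max(m_df, 2))
    se = np.sqrt(var_log2)

    degenerate = se == 0  # both conditions all-zero
    se_safe = np.where(degenerate, np.inf, se)
    wald = np.where(degenerate, 0.0, log2fc / se_safe)
    pvalue = np.where(degenerate, 1.0, 2.0 * stats.norm.sf(np.abs(wald)))
    log2fc = np.where(degenerate, 0.0, log2fc)

    both = tumor | free
    base_mean = (k[:, both] / factors[both][None, :]).mean(axis=1)

    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": np.where(degenerate, np.inf, se),
            "wald_stat": wald,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue) if len(pvalue) else pvalue,
        }
    )
    return DEResult(table=table, contrast=(genotype, week))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DEG sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEGSet:
    """Genes passing fold-change and FDR thresholds for one contrast."""

    label: str
    direction: str  # up, down or both
    gene_ids: frozenset[str]
    fold_change_min: float
    fdr_max: float


def call_degs(result: DEResult, fold_change_min: float = 1.5,
              fdr_max: float = 0.1, direction: str = "both",
              fc_scale: str = "linear") -> DEGSet:
    """Threshold a DE table into a DEG set (strict inequalities).

    ``fc_scale="linear"`` reads the threshold as a fold change
    (|log2FC| > log2 fc); ``"log2"`` reads it directly on the log2 scale.
    """
    if direction not in ("up", "down", "both"):
        raise ValidationError(f"bad direction {direction!r}")
    if fc_scale not in ("linear", "log2"):
        raise ValidationError(f"bad fc_scale {fc_scale!r}")
    lfc_min = np.log2(fold_change_min) if fc_scale == "linear" else fold_change_min
    t = result.table
    sig = t["padj"].to_numpy() < fdr_max
    lfc = t["log2fc"].to_numpy()
    if direction == "up":
        hit = lfc > lfc_min
    elif direction == "down":
        hit = lfc < -lfc_min
    else:
        hit = np.abs(lfc) > lfc_min
    genes = frozenset(t.loc[sig & hit, "gene_id"])
    label = f"{result.contrast[0]}_wk{result.contrast[1]}_{direction}"
    return DEGSet(label, direction, genes, fold_change_min, fdr_max)


@dataclass(frozen=True)
class VennPartition:
    """Exclusive-region partition of up to three gene sets."""

    regions: dict[frozenset, frozenset]  # keys: frozenset of set labels
    union: frozenset


def deg_set_algebra(sets: Mapping[object, Iterable[str]]) -> VennPartition:
    """Venn partition of up to 3 sets keyed by timepoint (or any label)."""
    if len(sets) > 3:
        raise ValidationError("Venn partition supports at most 3 sets")
    as_sets = {k: frozenset(v) for k, v in sets.items()}
    union = frozenset().union(*as_sets.values()) if as_sets else frozenset()
    regions: dict[frozenset, frozenset] = {}
    keys = list(as_sets)
    for r in range(1, len(keys) + 1):
        for combo in combinations(keys, r):
            inside = frozenset(combo)
            members = frozenset.intersection(*(as_sets[k] for k in combo))
            for k in keys:
                if k not in inside:
                    members -= as_sets[k]
            regions[inside] = members
    return VennPartition(regions=regions, union=union)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(normalized: pd.DataFrame, n_top_genes: int = 500, n_components: int = 2
        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA on log2(normalized + 1), restricted to high-variance genes.

    Returns sample coordinates (samples x PCs) and explained-variance
    fractions.  ``n_components`` is clamped to what the data supports.
    """
    from sklearn.decomposition import PCA

    x = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    n_genes, n_samples = x.shape
    if n_top_genes < n_genes:
        order = np.argsort(x.var(axis=1))[::-1][:n_top_genes]
        x = x[np.sort(order)]
    max_comp = min(n_samples - 1 if n_samples > 1 else 1, x.shape[0])
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} clamped to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(x.T)
    frame = pd.DataFrame(coords, index=normalized.columns,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    return frame, model.explained_variance_ratio_
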