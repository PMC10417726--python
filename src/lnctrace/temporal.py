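"""Temporal expression trajectories of hyperplasia-stage DEGs and their
k-means archetypes.

DEGs called at the first tumor timepoint (hyperplasia: week 6 for WT, week 8
for KO — knockout onset is delayed one timepoint) are summarised as mean
normalized expression per tumor stage, z-scored per gene, and clustered with
k-means.  WT and KO genes are clustered jointly with their timepoint axes
aligned by stage order (1st/2nd/3rd tumor timepoint), which is the only way
a joint clustering of the two genotypes is well-posed.  A pooled tumor-free
baseline is prepended as a leading profile column so that the "drops at
hyperplasia and stays low" archetype keeps a well-defined shape after
z-scoring (without the baseline such rows are near-constant and their
z-scores are pure noise).

Cluster labels from k-means are arbitrary; :func:`match_archetypes` maps
them onto the three canonical shapes (1 = early spike then decay,
2 = sustained rise, 3 = early drop staying low) by centroid correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import SampleRecord

BASELINE_LABEL = "baseline"


@dataclass(frozen=True)
class TemporalProfiles:
    """Gene x timepoint profile matrix (optionally z-scored per row)."""

    values: pd.DataFrame  # rows: genes (or (genotype, gene)), cols: stage labels
    scaling: str = "none"  # none | zscore

    def __post_init__(self) -> None:
        if self.scaling not in ("none", "zscore"):
            raise ValidationError(f"bad scaling {self.scaling!r}")


def stage_means(normalized: pd.DataFrame, samples: Sequence[SampleRecord],
                gene_ids: Sequence[str], group: tuple[str, str],
                timepoints: Sequence[int] | None = None) -> TemporalProfiles:
    """Mean normalized expression per timepoint for one (genotype, condition).

    ``value[g, t]`` is the arithmetic mean over the group's samples at
    timepoint ``t``.
    """
    genotype, condition = group
    missing = [g for g in gene_ids if g not in normalized.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    by_id = {s.sample_id: s for s in samples}
    cols = [c for c in normalized.columns
            if by_id[c].genotype == genotype and by_id[c].condition == condition]
    if timepoints is None:
        timepoints = sorted({by_id[c].timepoint_weeks for c in cols})
    values = {}
    for week in timepoints:
        week_cols = [c for c in cols if by_id[c].timepoint_weeks == week]
        if not week_cols:
            raise ValidationError(f"no {genotype}/{condition} samples at week {week}")
        values[week] = normalized.loc[list(gene_ids), week_cols].mean(axis=1)
    return TemporalProfiles(pd.DataFrame(values), scaling="none")


def build_trajectories(normalized: pd.DataFrame, samples: Sequence[SampleRecord],
                       genes_by_genotype: Mapping[str, Sequence[str]],
                       stage_weeks: Mapping[str, Sequence[int]],
                       include_baseline: bool = True) -> TemporalProfiles:
    """Joint stage-aligned trajectory matrix for WT and KO DEGs.

    Rows are (genotype, gene) pairs; columns are ``baseline`` (mean tumor-free
    expression over the genotype's stage weeks) followed by ``stage1..K``
    (mean tumor expression at the genotype's 1st..Kth tumor timepoint).
    """
    blocks = []
    for genotype in sorted(genes_by_genotype):
        gene_ids = list(genes_by_genotype[genotype])
        if not gene_ids:
            continue
        weeks = list(stage_weeks[genotype])
        tumor = stage_means(normalized, samples, gene_ids,
                            (genotype, "tumor"), weeks)
        block = tumor.values.to_numpy()
        labels = [f"stage{i + 1}" for i in range(len(weeks))]
        if include_baseline:
            free = stage_means(normalized, samples, gene_ids,
                               (genotype, "tumor_free"), weeks)
            baseline = free.values.to_numpy().mean(axis=1, keepdims=True)
            block = np.hstack([baseline, block])
            labels = [BASELINE_LABEL] + labels
        idx = pd.MultiIndex.from_product([[genotype], gene_ids],
                                         names=["genotype", "gene_id"])
        blocks.append(pd.DataFrame(block, index=idx, columns=labels))
    if not blocks:
        raise ValidationError("no genes to build trajectories for")
    return TemporalProfiles(pd.concat(blocks), scaling="none")


def zscore_profiles(profiles: TemporalProfiles) -> TemporalProfiles:
    """Z-score each row; constant rows are flagged (warning) and dropped."""
    v = profiles.values
    sd = v.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant profile rows before "
            "z-scoring", stacklevel=2
        )
    kept = v.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return TemporalProfiles(z, scaling="zscore")


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterFit:
    """A k-means fit: assignments in 1..K, centroids and total within SS."""

    K: int
    assignments: pd.Series  # index: profile rows, values: 1..K
    centroids: np.ndarray  # K x timepoints
    total_within_ss: float
    seed: int
    n_init: int

    def recompute_within_ss(self, profiles: TemporalProfiles) -> float:
        x = profiles.values.to_numpy()
        labels = self.assignments.to_numpy() - 1
        return float(((x - self.centroids[labels]) ** 2).sum())


def kmeans_cluster(profiles: TemporalProfiles, K: int, seed: int = 0,
                   n_init: int = 25) -> ClusterFit:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts."""
    from sklearn.cluster import KMeans

    x = profiles.values.to_numpy()
    if K < 1 or K > x.shape[0]:
        raise ConfigError(f"K={K} out of range for {x.shape[0]} profiles")
    model = KMeans(n_clusters=K, init="k-means++", n_init=n_init,
                   max_iter=300, tol=1e-6, algorithm="lloyd",
                   random_state=seed)
    labels = model.fit_predict(x)
    assignments = pd.Series(labels + 1, index=profiles.values.index,
                            name="cluster")
    return ClusterFit(K=K, assignments=assignments,
                      centroids=model.cluster_centers_,
                      total_within_ss=float(model.inertia_),
                      seed=seed, n_init=n_init)


def elbow_curve(profiles: TemporalProfiles, k_range: Sequence[int],
                seed: int = 0, n_init: int = 25) -> dict[int, float]:
    """Total within-cluster SS per K — the curve one plots to pick K."""
    return {int(k): kmeans_cluster(profiles, int(k), seed, n_init).total_within_ss
            for k in k_range}


# ---------------------------------------------------------------------------
# archetype matching and exclusivity
# ---------------------------------------------------------------------------

def _canonical_shapes(n_cols: int, with_baseline: bool) -> np.ndarray:
    """Idealised archetype profiles on the clustering axis, z-scored."""
    stages = n_cols - 1 if with_baseline else n_cols
    ramp = np.linspace(0.0, 1.0, max(stages, 2))[:stages]
    spike = np.concatenate([[1.0], (0.4 * ramp[::-1] + 0.1)[1:]])  # peak at stage 1
    rise = 0.2 + 0.8 * ramp
    drop = np.full(stages, 0.05)

    def with_base(traj: np.ndarray, base: float) -> np.ndarray:
        return np.concatenate([[base], traj]) if with_baseline else traj

    rows = [
        with_base(spike, 0.1),  # 1: early spike then decay
        with_base(rise, 0.1),   # 2: sustained rise
        with_base(drop, 1.0),   # 3: early drop staying low
    ]
    z = [(r - r.mean()) / (r.std() if r.std() > 0 else 1.0) for r in rows]
    return np.asarray(z)


def match_archetypes(centroids: np.ndarray, with_baseline: bool = True
                     ) -> dict[int, int]:
    """Map k-means cluster labels (1..K) to archetypes 1..3 by shape.

    Uses the assignment of centroids to canonical shapes that maximises the
    total correlation (Hungarian matching), so label permutations of the
    k-means fit never change the outcome.  Extra clusters beyond three keep
    their own number.
    """
    from scipy.optimize import linear_sum_assignment

    canon = _canonical_shapes(centroids.shape[1], with_baseline)
    k = centroids.shape[0]
    cz = centroids - centroids.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(cz, axis=1, keepdims=True)
    cz = cz / np.where(norms == 0, 1.0, norms)
    kz = canon / np.linalg.norm(canon, axis=1, keepdims=True)
    corr = cz @ kz.T  # k x 3
    rows, cols = linear_sum_assignment(-corr[:, : min(3, k)])
    mapping = {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}
    for label in range(1, k + 1):
        mapping.setdefault(label, label)
    return mapping


def exclusivity_partition(wt_assignments: Mapping[str, int],
                          ko_assignments: Mapping[str, int],
                          cluster_id: int) -> tuple[set, set, set]:
    """Split one cluster's members into WT-only / KO-only / shared genes.

    ``wt_only`` = in WT's cluster but absent from KO's DEG input (and
    symmetrically); ``shared`` = assigned to the cluster in both genotypes.
    """
    wt_in = {g for g, c in wt_assignments.items() if c == cluster_id}
    ko_in = {g for g, c in ko_assignments.items() if c == cluster_id}
    wt_only = {g for g in wt_in if g not in ko_assignments}
    ko_only = {g for g in ko_in if g not in wt_assignments}
    shared = wt_in & ko_in
    return wt_only, ko_only, shared
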