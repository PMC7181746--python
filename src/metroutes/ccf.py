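"""CCF merging, per-cluster matrices, clonality calling, cluster filtering.

Multi-region lesions (primary tumors, liver metastases) are analyzed as a
single sample: each mutation's per-region CCFs are first combined with a
depth-weighted mean capped at 1,

    CCF = min(1, sum_i CCF_i * d_i / sum_i d_i),

then the cluster's mean CCF per lesion is the arithmetic mean over its
member mutations. Clonality is called per cluster and lesion: mean CCF
strictly above ``clonal_ccf`` (default 0.85) is clonal, at or below
``absent_ccf`` (default 0.05) is absent, anything between is subclonal.
"""

from __future__ import annotations

import logging
import statistics
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import (
    ABSENT,
    CLONAL,
    SUBCLONAL,
    ClonalityMatrix,
    ClusterCCFMatrix,
    ContractError,
    PatientDataset,
    ThresholdConfig,
)

log = logging.getLogger("metroutes")

__all__ = [
    "ccf_from_counts",
    "merge_ccf",
    "cluster_lesion_ccf",
    "call_clonality",
    "filter_clusters",
    "ClonalityCaller",
    "ClusterFilter",
]


def ccf_from_counts(
    alt_count: int,
    ref_count: int,
    purity: float,
    total_cn: int = 2,
    multiplicity: int = 1,
) -> float:
    """Convert read counts to a CCF via the standard purity/copy-number model.

    CCF = VAF * (purity * total_cn + (1 - purity) * 2) / (purity * multiplicity),
    clipped to [0, 1.5]; downstream merging applies the final cap at 1.
    """
    total = alt_count + ref_count
    if total < 1:
        raise ContractError("ccf_from_counts: zero total reads")
    if not (0 < purity <= 1):
        raise ContractError("ccf_from_counts: purity must be in (0, 1]")
    if total_cn < 1 or multiplicity < 1:
        raise ContractError("ccf_from_counts: total_cn and multiplicity must be >= 1")
    vaf = alt_count / total
    ccf = vaf * (purity * total_cn + (1.0 - purity) * 2.0) / (purity * multiplicity)
    return float(min(max(ccf, 0.0), 1.5))


def merge_ccf(
    per_region_ccfs: Sequence[float], per_region_depths: Sequence[int]
) -> float:
    """Depth-weighted merged CCF across the regions of one lesion, capped at 1."""
    if len(per_region_ccfs) == 0 or len(per_region_ccfs) != len(per_region_depths):
        raise ContractError("merge_ccf: need equal-length non-empty lists")
    if any(d < 1 for d in per_region_depths):
        raise ContractError("merge_ccf: depths must be >= 1")
    num = sum(c * d for c, d in zip(per_region_ccfs, per_region_depths))
    den = sum(per_region_depths)
    return float(min(1.0, num / den))


def cluster_lesion_ccf(dataset: PatientDataset) -> ClusterCCFMatrix:
    """Build the per-cluster, per-lesion mean CCF matrix for one patient.

    For each mutation and lesion, CCFs are merged across the lesion's
    regions (depth-weighted, capped at 1); a mutation not observed in some
    region is imputed as CCF 0 at that region's median depth — with the
    study's coverage requirements, the absence of a call in a covered
    region is evidence of absence. The cluster's mean CCF per lesion is
    the arithmetic mean over its member mutations.
    """
    by_cluster: dict = {}
    obs: dict = {}
    for m in dataset.mutations:
        by_cluster.setdefault(m.cluster_id, set()).add(m.mutation_id)
        obs[(m.mutation_id, m.sample_id)] = m
    if not by_cluster:
        raise ContractError("cluster_lesion_ccf: dataset has no mutations")
    for cid, muts in by_cluster.items():
        if not muts:
            raise ContractError(f"cluster {cid} has no member mutations")

    depths_by_sample: dict = {}
    for m in dataset.mutations:
        depths_by_sample.setdefault(m.sample_id, []).append(m.depth)
    overall_median = statistics.median(d for ds in depths_by_sample.values() for d in ds)
    median_depth = {
        sid: statistics.median(ds) for sid, ds in depths_by_sample.items()
    }

    cluster_ids = sorted(by_cluster)
    lesion_ids = [l.lesion_id for l in dataset.lesions]
    mat = np.zeros((len(cluster_ids), len(lesion_ids)))
    for j, lesion in enumerate(dataset.lesions):
        regions = lesion.region_sample_ids
        for i, cid in enumerate(cluster_ids):
            merged = []
            for mid in sorted(by_cluster[cid]):
                ccfs, depths = [], []
                for sid in regions:
                    rec = obs.get((mid, sid))
                    if rec is not None:
                        ccfs.append(rec.ccf)
                        depths.append(rec.depth)
                    else:
                        ccfs.append(0.0)
                        depths.append(int(median_depth.get(sid, overall_median)))
                merged.append(merge_ccf(ccfs, depths))
            mat[i, j] = float(np.mean(merged))

    chrom_sets = {}
    for cid in cluster_ids:
        chroms = set()
        for mid in by_cluster[cid]:
            parts = mid.split(":")
            if len(parts) == 4:
                chroms.add(parts[0])
        chrom_sets[cid] = frozenset(chroms)
    has_chroms = any(chrom_sets.values())

    return ClusterCCFMatrix(
        ccf=pd.DataFrame(mat, index=cluster_ids, columns=lesion_ids),
        n_mutations=pd.Series(
            {cid: len(by_cluster[cid]) for cid in cluster_ids}, name="n_mutations"
        ),
        chromosomes=chrom_sets if has_chroms else None,
    )


def call_clonality(
    matrix: ClusterCCFMatrix, thresholds: Optional[ThresholdConfig] = None
) -> ClonalityMatrix:
    """Call per-cluster, per-lesion clonality status from mean CCFs.

    Boundaries follow the strict inequalities: exactly ``clonal_ccf`` is
    subclonal, exactly ``absent_ccf`` is absent.
    """
    thresholds = thresholds or ThresholdConfig()
    vals = matrix.ccf.to_numpy()
    status = np.where(
        vals > thresholds.clonal_ccf,
        CLONAL,
        np.where(vals <= thresholds.absent_ccf, ABSENT, SUBCLONAL),
    )
    return ClonalityMatrix(
        status=pd.DataFrame(status, index=matrix.ccf.index, columns=matrix.ccf.columns)
    )


def filter_clusters(
    matrix: ClusterCCFMatrix, thresholds: Optional[ThresholdConfig] = None
) -> ClusterCCFMatrix:
    """Drop likely false-positive clusters; pure selection, values untouched.

    Clusters with fewer than ``min_cluster_size`` substitutions are removed;
    if ``min_chromosomes`` is set and chromosome annotations exist, clusters
    spanning fewer chromosomes are removed as well.
    """
    thresholds = thresholds or ThresholdConfig()
    keep = []
    for cid in matrix.cluster_ids:
        n = int(matrix.n_mutations[cid])
        if n < thresholds.min_cluster_size:
            log.info(
                "filter_clusters: dropping cluster %s (%d < %d substitutions)",
                cid, n, thresholds.min_cluster_size,
            )
            continue
        if (
            thresholds.min_chromosomes is not None
            and matrix.chromosomes is not None
            and len(matrix.chromosomes.get(cid, frozenset()))
            < thresholds.min_chromosomes
        ):
            log.info(
                "filter_clusters: dropping cluster %s (mutations on %d < %d chromosomes)",
                cid, len(matrix.chromosomes.get(cid, frozenset())),
                thresholds.min_chromosomes,
            )
            continue
        keep.append(cid)
    if not keep:
        raise ContractError("filter_clusters: all clusters were dropped")
    return ClusterCCFMatrix(
        ccf=matrix.ccf.loc[keep],
        n_mutations=matrix.n_mutations.loc[keep],
        chromosomes=(
            {c: matrix.chromosomes[c] for c in keep} if matrix.chromosomes else None
        ),
    )


class ClonalityCaller(TransformerMixin, BaseEstimator):
    """Threshold transformer mapping mean CCFs to clonality statuses.

    Parameters
    ----------
    clonal_ccf : float, default 0.85
        Strictly-greater threshold for the clonal call.
    absent_ccf : float, default 0.05
        At-or-below threshold for statistical absence.
    """

    def __init__(self, clonal_ccf: float = 0.85, absent_ccf: float = 0.05):
        self.clonal_ccf = clonal_ccf
        self.absent_ccf = absent_ccf

    def fit(self, X, y=None):
        self.thresholds_ = ThresholdConfig(
            clonal_ccf=self.clonal_ccf, absent_ccf=self.absent_ccf
        )
        return self

    def transform(self, X: ClusterCCFMatrix) -> ClonalityMatrix:
        if not hasattr(self, "thresholds_"):
            self.fit(X)
        return call_clonality(X, self.thresholds_)


class ClusterFilter(TransformerMixin, BaseEstimator):
    """Selector dropping clusters too small (or chromosomally too narrow)
    to be trusted as real subclones."""

    def __init__(self, min_cluster_size: int = 5, min_chromosomes=None):
        self.min_cluster_size = min_cluster_size
        self.min_chromosomes = min_chromosomes

    def fit(self, X, y=None):
        self.thresholds_ = ThresholdConfig(
            min_cluster_size=self.min_cluster_size,
            min_chromosomes=self.min_chromosomes,
        )
        return self

    def transform(self, X: ClusterCCFMatrix) -> ClusterCCFMatrix:
        if not hasattr(self, "thresholds_"):
            self.fit(X)
        return filter_clusters(X, self.thresholds_)
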