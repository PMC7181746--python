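"""End-to-end per-patient analysis: CCF matrix -> clonality -> clone tree ->
metastatic map -> route summary."""

from __future__ import annotations

import logging
from typing import Optional

from sklearn.base import BaseEstimator

from .ccf import call_clonality, cluster_lesion_ccf, filter_clusters
from .model import (
    ClonalityMatrix,
    ClusterCCFMatrix,
    ContractError,
    PatientDataset,
    ThresholdConfig,
)
from .routes import infer_metastatic_map
from .summary import summarize_routes
from .tree import build_clone_tree, classify_cluster_roles

log = logging.getLogger("metroutes")

__all__ = ["RouteAnalyzer", "analyze_patient"]


class RouteAnalyzer(BaseEstimator):
    """Full inference pipeline for one multi-region sequenced patient.

    Parameters mirror the analysis thresholds: ``clonal_ccf`` / ``absent_ccf``
    for clonality calling, ``min_cluster_size`` (and optionally
    ``min_chromosomes``) for the false-positive cluster filter, and
    ``epsilon`` for CCF comparisons in the pigeonhole rules.

    Attributes (after ``fit``)
    --------------------------
    ccf_matrix_ : ClusterCCFMatrix
        Filtered per-cluster per-lesion merged mean CCFs.
    clonality_ : ClonalityMatrix
    roles_ : list of ClusterRole
    tree_ : CloneTree
    map_ : MetastaticMap
    summary_ : RouteSummary
    """

    def __init__(
        self,
        clonal_ccf: float = 0.85,
        absent_ccf: float = 0.05,
        min_cluster_size: int = 5,
        min_chromosomes: Optional[int] = None,
        epsilon: float = 0.05,
    ):
        self.clonal_ccf = clonal_ccf
        self.absent_ccf = absent_ccf
        self.min_cluster_size = min_cluster_size
        self.min_chromosomes = min_chromosomes
        self.epsilon = epsilon

    def _thresholds(self) -> ThresholdConfig:
        return ThresholdConfig(
            clonal_ccf=self.clonal_ccf,
            absent_ccf=self.absent_ccf,
            min_cluster_size=self.min_cluster_size,
            min_chromosomes=self.min_chromosomes,
            ccf_epsilon=self.epsilon,
        )

    def fit(self, X: PatientDataset, y=None):
        thresholds = self._thresholds()
        matrix = cluster_lesion_ccf(X)
        matrix = filter_clusters(matrix, thresholds)
        status = call_clonality(matrix, thresholds)
        # clusters statistically absent in every lesion carry no placement
        # information; drop them before tree building
        keep = [
            c
            for c in matrix.cluster_ids
            if (status.status.loc[c] != "absent").any()
        ]
        if not keep:
            raise ContractError("all clusters are absent in every lesion")
        dropped = sorted(set(matrix.cluster_ids) - set(keep))
        if dropped:
            log.info(
                "RouteAnalyzer: dropping clusters absent everywhere: %s", dropped
            )
            matrix = ClusterCCFMatrix(
                ccf=matrix.ccf.loc[keep],
                n_mutations=matrix.n_mutations.loc[keep],
                chromosomes=(
                    {c: matrix.chromosomes[c] for c in keep}
                    if matrix.chromosomes
                    else None
                ),
            )
            status = ClonalityMatrix(status=status.status.loc[keep])

        self.thresholds_ = thresholds
        self.ccf_matrix_ = matrix
        self.clonality_ = status
        self.roles_ = classify_cluster_roles(status)
        self.tree_ = build_clone_tree(
            matrix, status, self.roles_, epsilon=self.epsilon
        )
        self.map_ = infer_metastatic_map(
            X.lesions,
            self.tree_,
            status,
            matrix,
            patient_id=X.patient_id,
            absent_ccf=self.absent_ccf,
        )
        self.summary_ = summarize_routes(
            self.map_.routes, {l.lesion_id: l.layer for l in X.lesions}
        )
        self.lesions_ = list(X.lesions)
        return self


def analyze_patient(dataset: PatientDataset, **params) -> RouteAnalyzer:
    """Run the full pipeline on one patient dataset; returns the fitted
    :class:`RouteAnalyzer`."""
    return RouteAnalyzer(**params).fit(dataset)
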