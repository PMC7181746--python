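"""Domain model for multi-region tumor clonality and metastatic-route inference.

The objects here mirror the stages of the analysis: per-mutation CCF calls
grouped into PyClone-style clusters (:class:`MutationCall`), anatomical
lesions arranged in the five-layer lymphatic/liver network
(:class:`Lesion`), per-cluster-per-lesion CCF and clonality matrices, the
rooted clone tree, and the inferred metastatic map.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "LAYERS",
    "LAYER_RANK",
    "CLONAL",
    "SUBCLONAL",
    "ABSENT",
    "MetroutesError",
    "FormatError",
    "ValidationError",
    "ContractError",
    "InconsistencyError",
    "InfeasibilityError",
    "MutationCall",
    "Lesion",
    "ThresholdConfig",
    "PatientDataset",
    "ClusterCCFMatrix",
    "ClonalityMatrix",
    "Role",
    "ClusterRole",
    "PairRelation",
    "CloneTree",
    "SeedingCloneSet",
    "Route",
    "MetastaticMap",
]

#: Layers of the metastatic network, ordered by lymphatic drainage distance:
#: primary tumor, paracolic / intermediate / central lymph-node metastases,
#: liver metastases.
LAYERS = ("T", "P", "I", "C", "LM")
LAYER_RANK = {layer: rank for rank, layer in enumerate(LAYERS)}

CLONAL = "clonal"
SUBCLONAL = "subclonal"
ABSENT = "absent"


class MetroutesError(Exception):
    """Base class for all package errors."""


class FormatError(MetroutesError):
    """A tabular input does not match the expected schema."""


class ValidationError(MetroutesError):
    """An input violates a domain invariant."""


class ContractError(MetroutesError):
    """An operation was called with arguments outside its contract."""


class InconsistencyError(MetroutesError):
    """CCF constraints admit no consistent clone tree / nesting."""


class InfeasibilityError(MetroutesError):
    """No metastatic map satisfies the model assumptions."""


@dataclass(frozen=True)
class MutationCall:
    """One mutation observed in one tumor region.

    ``ccf`` is the PyClone-style cancer cell fraction estimate for this
    region; values slightly above 1 are permitted on input and are capped
    downstream by the depth-weighted merge. ``depth`` is the per-region
    sequencing depth used as the merge weight.
    """

    mutation_id: str
    sample_id: str
    ccf: float
    depth: int
    cluster_id: str
    ref_count: Optional[int] = None
    alt_count: Optional[int] = None
    major_cn: Optional[int] = None
    minor_cn: Optional[int] = None
    purity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValidationError(
                f"mutation {self.mutation_id} in {self.sample_id}: depth must be >= 1"
            )
        if self.ccf < 0:
            raise ValidationError(
                f"mutation {self.mutation_id} in {self.sample_id}: ccf must be >= 0"
            )
        if self.ref_count is not None and self.ref_count < 0:
            raise ValidationError("ref_count must be non-negative")
        if self.alt_count is not None and self.alt_count < 0:
            raise ValidationError("alt_count must be non-negative")

    @property
    def chromosome(self) -> Optional[str]:
        """Chromosome label if the mutation ID is ``chrom:pos:ref:alt``-shaped."""
        parts = self.mutation_id.split(":")
        return parts[0] if len(parts) == 4 else None


@dataclass(frozen=True)
class Lesion:
    """An anatomical lesion (primary tumor or metastasis) with its regions."""

    lesion_id: str
    layer: str
    region_sample_ids: tuple

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(
                f"lesion {self.lesion_id}: layer {self.layer!r} not in {LAYERS}"
            )
        if not self.region_sample_ids:
            raise ValidationError(f"lesion {self.lesion_id}: needs >= 1 region")
        object.__setattr__(self, "region_sample_ids", tuple(self.region_sample_ids))

    @property
    def rank(self) -> int:
        return LAYER_RANK[self.layer]

    @property
    def is_primary(self) -> bool:
        return self.layer == "T"


@dataclass(frozen=True)
class ThresholdConfig:
    """Analysis thresholds.

    clonal_ccf
        Mean CCF strictly above this is called clonal (default 0.85).
    absent_ccf
        Mean CCF at or below this is statistically absent (default 0.05).
    min_cluster_size
        Clusters with fewer substitutions are discarded as likely
        false-positive calls (default 5).
    ccf_epsilon
        Tolerance for CCF comparisons in the pigeonhole rules.
    min_chromosomes
        Optional: discard clusters whose mutations span fewer chromosomes
        (disabled by default; the appropriate cutoff is data-dependent).
    """

    clonal_ccf: float = 0.85
    absent_ccf: float = 0.05
    min_cluster_size: int = 5
    ccf_epsilon: float = 0.05
    min_chromosomes: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.absent_ccf < self.clonal_ccf <= 1):
            raise ValidationError("require 0 <= absent_ccf < clonal_ccf <= 1")
        if self.min_cluster_size < 1:
            raise ValidationError("min_cluster_size must be >= 1")
        if self.ccf_epsilon < 0:
            raise ValidationError("ccf_epsilon must be >= 0")


@dataclass
class PatientDataset:
    """All inputs for one patient: lesions, mutation calls, thresholds."""

    patient_id: str
    lesions: list
    mutations: list
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    def __post_init__(self) -> None:
        primaries = [l for l in self.lesions if l.is_primary]
        if len(primaries) != 1:
            raise ValidationError(
                f"patient {self.patient_id}: exactly one primary (layer T) lesion "
                f"required, found {len(primaries)}"
            )
        sample_map: dict = {}
        for lesion in self.lesions:
            for sid in lesion.region_sample_ids:
                if sid in sample_map:
                    raise ValidationError(
                        f"sample {sid} assigned to lesions "
                        f"{sample_map[sid]} and {lesion.lesion_id}"
                    )
                sample_map[sid] = lesion.lesion_id
        seen = set()
        for m in self.mutations:
            if m.sample_id not in sample_map:
                raise ValidationError(
                    f"mutation {m.mutation_id}: sample {m.sample_id} not assigned "
                    "to any lesion"
                )
            key = (m.mutation_id, m.sample_id)
            if key in seen:
                raise ValidationError(
                    f"mutation {m.mutation_id} appears twice in sample {m.sample_id}"
                )
            seen.add(key)
        self._sample_to_lesion = sample_map

    @property
    def sample_to_lesion(self) -> Mapping[str, str]:
        return self._sample_to_lesion

    @property
    def primary(self) -> Lesion:
        return next(l for l in self.lesions if l.is_primary)

    def lesion(self, lesion_id: str) -> Lesion:
        for l in self.lesions:
            if l.lesion_id == lesion_id:
                return l
        raise KeyError(lesion_id)


@dataclass
class ClusterCCFMatrix:
    """Per-cluster, per-lesion mean CCF with cluster mutation counts.

    ``ccf`` is a clusters x lesions DataFrame of merged mean CCFs in [0, 1];
    ``n_mutations`` is indexed by cluster. ``chromosomes`` optionally maps
    each cluster to the set of chromosomes its mutations fall on.
    """

    ccf: pd.DataFrame
    n_mutations: pd.Series
    chromosomes: Optional[Mapping[str, frozenset]] = None

    def __post_init__(self) -> None:
        vals = self.ccf.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("mean CCF values must lie in [0, 1]")
        missing = set(self.ccf.index) - set(self.n_mutations.index)
        if missing:
            raise ValidationError(f"clusters without mutation counts: {sorted(missing)}")
        if (self.n_mutations.loc[list(self.ccf.index)] < 1).any():
            raise ValidationError("every retained cluster needs n_mutations >= 1")

    @property
    def cluster_ids(self) -> list:
        return list(self.ccf.index)

    @property
    def lesion_ids(self) -> list:
        return list(self.ccf.columns)


@dataclass
class ClonalityMatrix:
    """Per-cluster, per-lesion status in {clonal, subclonal, absent}."""

    status: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.status.to_numpy().ravel()) - {CLONAL, SUBCLONAL, ABSENT}
        if bad:
            raise ValidationError(f"invalid status values: {sorted(bad)}")

    @property
    def cluster_ids(self) -> list:
        return list(self.status.index)

    @property
    def lesion_ids(self) -> list:
        return list(self.status.columns)

    def present(self, cluster_id: str, lesion_id: str) -> bool:
        return self.status.at[cluster_id, lesion_id] != ABSENT

    def present_clusters(self, lesion_id: str) -> list:
        col = self.status[lesion_id]
        return [c for c in self.status.index if col[c] != ABSENT]


class Role(str, Enum):
    """Cluster role: trunk (clonal in every lesion, the MRCA), branch
    (shared by >= 2 lesions), leaf (present in exactly one lesion)."""

    TRUNK = "trunk"
    BRANCH = "branch"
    LEAF = "leaf"


@dataclass(frozen=True)
class ClusterRole:
    cluster_id: str
    role: Role


class PairRelation(str, Enum):
    """Pigeonhole relationship between two mutation clusters."""

    LINEAR_A_OVER_B = "linear_a_over_b"
    LINEAR_B_OVER_A = "linear_b_over_a"
    BRANCHING = "branching"
    UNDETERMINED = "undetermined"

    def mirror(self) -> "PairRelation":
        if self is PairRelation.LINEAR_A_OVER_B:
            return PairRelation.LINEAR_B_OVER_A
        if self is PairRelation.LINEAR_B_OVER_A:
            return PairRelation.LINEAR_A_OVER_B
        return self


@dataclass
class CloneTree:
    """Rooted tree of mutation clusters; the root is the trunk/MRCA cluster."""

    parent: dict
    root: str
    n_mutations: dict = field(default_factory=dict)
    roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.root in self.parent:
            raise ValidationError("the root/trunk cluster must not have a parent")
        for child in self.parent:
            node, hops = child, 0
            while node in self.parent:
                node = self.parent[node]
                hops += 1
                if hops > len(self.parent) + 1:
                    raise ValidationError("cycle in clone-tree parent map")
            if node != self.root:
                raise ValidationError(f"cluster {child} is not connected to the root")

    @property
    def nodes(self) -> list:
        return [self.root] + sorted(self.parent)

    def children(self, node: str) -> list:
        return sorted(c for c, p in self.parent.items() if p == node)

    def ancestors(self, node: str) -> list:
        """Ancestors of ``node`` from its parent up to the root."""
        out = []
        while node in self.parent:
            node = self.parent[node]
            out.append(node)
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` is a (strict) ancestor of ``b``."""
        return a in self.ancestors(b)

    def depth(self, node: str) -> int:
        return len(self.ancestors(node))

    def descendants(self, node: str) -> set:
        return {c for c in self.parent if self.is_ancestor(node, c)}

    def subtree_size(self, node: str) -> int:
        return 1 + len(self.descendants(node))


@dataclass(frozen=True)
class SeedingCloneSet:
    """The subclones that jointly founded one metastatic lesion."""

    lesion_id: str
    clones: tuple
    classification: str  # "monoclonal" | "multiclonal"

    def __post_init__(self) -> None:
        if not self.clones:
            raise ContractError(f"lesion {self.lesion_id}: empty seeding clone set")
        object.__setattr__(self, "clones", tuple(sorted(self.clones)))


@dataclass
class Route:
    """One seeding event: source lesion -> target lesion."""

    source_lesion_id: str
    target_lesion_id: str
    seeding_clones: tuple
    classification: str
    color_cluster: Optional[str] = None
    mode: Optional[str] = None  # "sequential" | "skip" | "intra"

    def __post_init__(self) -> None:
        if self.source_lesion_id == self.target_lesion_id:
            raise ValidationError("route source and target must differ")
        self.seeding_clones = tuple(sorted(self.seeding_clones))


@dataclass
class MetastaticMap:
    """Parsimonious metastatic map: one route per metastasis.

    ``ambiguity_groups`` lists sets of lesions with identical clonal
    composition whose internal seeding order is conventional, not inferred.
    """

    patient_id: str
    routes: list
    ambiguity_groups: list = field(default_factory=list)

    def route_to(self, lesion_id: str) -> Route:
        for r in self.routes:
            if r.target_lesion_id == lesion_id:
                return r
        raise KeyError(lesion_id)

    def validate(self, lesions: Sequence[Lesion]) -> None:
        """Check the route graph is a directed tree rooted at the primary."""
        primary = next(l.lesion_id for l in lesions if l.is_primary)
        targets = [r.target_lesion_id for r in self.routes]
        metastases = [l.lesion_id for l in lesions if not l.is_primary]
        if sorted(targets) != sorted(metastases):
            raise ValidationError(
                "routes must target every metastasis exactly once; "
                f"got {sorted(targets)} vs {sorted(metastases)}"
            )
        if primary in targets:
            raise ValidationError("the primary lesion cannot be a seeding target")
        parent = {r.target_lesion_id: r.source_lesion_id for r in self.routes}
        for start in parent:
            node, hops = start, 0
            while node in parent:
                node = parent[node]
                hops += 1
                if hops > len(parent):
                    raise ValidationError("cycle in the metastatic route graph")
            if node != primary:
                raise ValidationError(f"lesion {start} is not rooted at the primary")
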