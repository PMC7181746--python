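"""Synthetic patient generator with known clone trees and seeding histories.

The generator emulates PyClone-style output from a multi-region study of
colorectal cancer with lymphatic and liver metastases: a random clone tree,
a primary tumor carrying all clones with nested fractions, metastases
created layer by layer (paracolic, intermediate, central lymph nodes, then
liver), each founded by one seeding event from an eligible earlier lesion
under the proximal-to-distal rule, and per-mutation read counts drawn
binomially at a configurable depth (default 264X).

Identifiability is an explicit configuration axis: with
``private_marker_probability`` = 1 every reseeding source acquires a fresh
private marker cluster that it transmits to the new metastasis, making the
reseeding edge recoverable; without markers, reseeding is provably
indistinguishable from primary seeding and the parsimony objective will
(correctly) prefer the primary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .ccf import ccf_from_counts
from .model import (
    CloneTree,
    ContractError,
    LAYER_RANK,
    Lesion,
    MetastaticMap,
    MutationCall,
    PatientDataset,
    Route,
    ValidationError,
)

log = logging.getLogger("metroutes")

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_clone_tree",
    "simulate_metastatic_history",
    "simulate_observations",
    "simulate_patient",
    "validate_ground_truth",
    "evaluate_recovery",
]

#: clones need at least this exclusive fraction in a lesion to seed from it
_SEEDABLE_MIN = 0.10
#: multiclonal founder fractions are kept inside this band so every founding
#: subclone stays unambiguously present-but-subclonal
_FOUNDER_BAND = (0.15, 0.80)
#: cap on any non-trunk cluster CCF in the primary so the trunk stays the
#: unique cluster clonal in every lesion
_PRIMARY_NON_TRUNK_CAP = 0.75


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated patient."""

    n_clusters: int = 7
    mutations_per_cluster: Tuple[int, int] = (5, 40)
    n_lesions_per_layer: Dict[str, int] = field(
        default_factory=lambda: {"P": 3, "I": 2, "C": 1, "LM": 1}
    )
    n_regions_primary: int = 3
    n_regions_lm: int = 2
    depth: int = 264
    purity: float = 0.7
    fraction_metastasis_seeded: float = 0.35
    private_marker_probability: float = 1.0
    monoclonal_probability: float = 0.3
    region_concentration: float = 10.0
    noise: str = "binomial"  # "none" | "binomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        for name in (
            "fraction_metastasis_seeded",
            "private_marker_probability",
            "monoclonal_probability",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.noise not in ("none", "binomial"):
            raise ValidationError("noise must be 'none' or 'binomial'")


@dataclass
class GroundTruth:
    """The simulator's true tree, lesion compositions and seeding history."""

    tree: CloneTree
    lesions: List[Lesion]
    compositions: Dict[str, Dict[str, float]]  # lesion -> clone -> fraction
    routes: List[Route]
    seeding_class: Dict[str, str]
    config: SimulationConfig


def simulate_clone_tree(
    config: SimulationConfig, rng: np.random.Generator
) -> CloneTree:
    """Random recursive clone tree: cluster "1" is the trunk, each further
    cluster attaches to a uniformly chosen existing node; mutation counts
    are uniform over ``mutations_per_cluster`` (all at least the cluster
    filter's minimum, so simulated clusters are never filtered)."""
    lo, hi = config.mutations_per_cluster
    parent: Dict[str, str] = {}
    nodes = ["1"]
    for i in range(2, config.n_clusters + 1):
        parent[str(i)] = nodes[int(rng.integers(0, len(nodes)))]
        nodes.append(str(i))
    n_mut = {c: int(rng.integers(lo, hi + 1)) for c in nodes}
    return CloneTree(parent=parent, root="1", n_mutations=n_mut)


def _closure(tree: CloneTree, clone: str) -> frozenset:
    return frozenset([clone, *tree.ancestors(clone)])


def _cluster_ccfs(tree: CloneTree, comp: Dict[str, float]) -> Dict[str, float]:
    """Per-cluster CCF implied by exclusive clone fractions: a cluster is
    carried by every clone at or below it in the tree."""
    ccf = {c: 0.0 for c in tree.nodes}
    for clone, frac in comp.items():
        for c in _closure(tree, clone):
            ccf[c] += frac
    return ccf


def _seedable(comp: Dict[str, float]) -> List[str]:
    return sorted(c for c, f in comp.items() if f >= _SEEDABLE_MIN)


def _founder_fractions(k: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = _FOUNDER_BAND
    for _ in range(1000):
        f = rng.dirichlet(np.ones(k))
        if np.all((f >= lo) & (f <= hi)):
            return f
    return np.full(k, 1.0 / k)


def simulate_metastatic_history(
    tree: CloneTree, config: SimulationConfig, rng: np.random.Generator
) -> GroundTruth:
    """Generate lesions, clone compositions, and the true seeding history.

    The primary carries every cluster with Dirichlet exclusive fractions
    (trunk clone floored so no other cluster reaches the clonal range in the
    primary); metastases are created in layer order and founded by a random
    non-empty subset of an eligible source's clones (joint migration, one
    event per metastasis). Reseeding sources gain a fresh private marker
    cluster, transmitted to the new metastasis, when
    ``private_marker_probability`` fires.
    """
    tree = CloneTree(
        parent=dict(tree.parent), root=tree.root, n_mutations=dict(tree.n_mutations)
    )
    n = len(tree.nodes)
    nodes = tree.nodes
    # primary composition: trunk clone floored at 0.25 so no other cluster
    # reaches the clonal range in the primary; internal clusters floored at
    # a detectable exclusive fraction — a clone whose mutations sit at the
    # same CCF as its child's in every sample would have been merged into
    # one cluster by the upstream clustering and is not generated
    internal = [c for c in nodes if c != tree.root and tree.children(c)]
    f_min = min(0.08, 0.5 / max(1, len(internal)))
    base = {tree.root: 1.0 - _PRIMARY_NON_TRUNK_CAP}
    for c in internal:
        base[c] = f_min
    rem = 1.0 - sum(base.values())
    x = rng.dirichlet(np.ones(n))
    comp_T = {
        c: base.get(c, 0.0) + rem * float(x[i]) for i, c in enumerate(nodes)
    }

    lesions: List[Lesion] = [
        Lesion("T", "T", tuple(f"T_R{i+1}" for i in range(config.n_regions_primary)))
    ]
    compositions = {"T": comp_T}
    routes: List[Route] = []
    seeding_class: Dict[str, str] = {}
    lo, hi = config.mutations_per_cluster
    # marker clusters are event-private: a marker is spawned on the source,
    # transmitted once to the new metastasis, and never re-transmitted or
    # used as the host of a later marker. Clones whose mutation content
    # includes an earlier marker are therefore never migrated again, which
    # keeps every reseeding edge tagged by a clone shared only by its two
    # endpoints (the premise of the identifiable regime).
    marker_clusters: set = set()

    def transmissible(clone: str) -> bool:
        return not (_closure(tree, clone) & marker_clusters)

    met_ids: List[Tuple[str, str]] = []  # (lesion_id, layer)
    for layer in ("P", "I", "C", "LM"):
        for i in range(config.n_lesions_per_layer.get(layer, 0)):
            met_ids.append((f"{layer}{i+1}", layer))

    def _reseeding_capable(comp: Dict[str, float]) -> bool:
        # a metastasis can source a new seeding only if it can host a fresh
        # marker (one ample marker-free clone) AND withhold a marker-free
        # clone from the migrating subset — withholding keeps the source's
        # clone content strictly richer than the recipient's, which is what
        # makes the edge's direction identifiable downstream
        trans = [c for c, f in comp.items() if f >= _SEEDABLE_MIN and transmissible(c)]
        ample = [c for c in trans if comp[c] >= 2 * _SEEDABLE_MIN]
        return len(ample) >= 1 and len(trans) >= 2

    for lesion_id, layer in met_ids:
        eligible = ["T"]
        for l in lesions[1:]:
            if layer == "LM" or (
                l.layer != "LM" and LAYER_RANK[l.layer] <= LAYER_RANK[layer]
            ):
                if _reseeding_capable(compositions[l.lesion_id]):
                    eligible.append(l.lesion_id)
        source = "T"
        if rng.random() < config.fraction_metastasis_seeded:
            mets = [e for e in eligible if e != "T"]
            if mets:
                source = mets[int(rng.integers(0, len(mets)))]
            else:
                log.info(
                    "simulate: %s requested metastasis seeding but none "
                    "eligible yet; falling back to the primary", lesion_id,
                )
        src_comp = compositions[source]

        marker: Optional[str] = None
        host: Optional[str] = None
        if source != "T" and rng.random() < config.private_marker_probability:
            marker = str(len(tree.nodes) + 1)
            ample = [
                c
                for c in src_comp
                if transmissible(c) and src_comp[c] >= 2 * _SEEDABLE_MIN
            ]
            host = max(ample, key=lambda c: (src_comp[c], tree.depth(c), c))
            tree.parent[marker] = host
            tree.n_mutations[marker] = int(rng.integers(lo, hi + 1))
            half = src_comp[host] / 2.0
            src_comp[host] = half
            src_comp[marker] = half
            marker_clusters.add(marker)

        pool = [
            c for c in _seedable(src_comp) if c != marker and transmissible(c)
        ]
        k = 1 if rng.random() < config.monoclonal_probability else int(
            rng.integers(2, 4)
        )
        if marker:
            # the marker rides on its host clone: both migrate (otherwise
            # "the marker arose in the recipient" would implicitly grant
            # the recipient the host's cells and blur the edge direction);
            # at least one other marker-free clone is withheld so the
            # recipient's content never mirrors the source's
            clones = [marker, host]
            others = [c for c in pool if c != host]
            n_extra = max(0, min(k - 2, len(others) - 1))
            if n_extra:
                clones += [
                    others[i]
                    for i in sorted(
                        rng.choice(
                            len(others), size=n_extra, replace=False
                        ).tolist()
                    )
                ]
        else:
            clones = []
            n_extra = max(1, min(k, len(pool)))
            clones += [
                pool[i]
                for i in sorted(
                    rng.choice(len(pool), size=n_extra, replace=False).tolist()
                )
            ]
        if len(clones) == 1:
            comp = {clones[0]: 1.0}
        else:
            fracs = _founder_fractions(len(clones), rng)
            comp = {c: float(f) for c, f in zip(sorted(clones), fracs)}
        compositions[lesion_id] = comp

        n_regions = config.n_regions_lm if layer == "LM" else 1
        region_ids = (
            tuple(f"{lesion_id}_R{i+1}" for i in range(n_regions))
            if n_regions > 1
            else (f"{lesion_id}_s",)
        )
        lesions.append(Lesion(lesion_id, layer, region_ids))
        routes.append(
            Route(
                source_lesion_id=source,
                target_lesion_id=lesion_id,
                seeding_clones=tuple(sorted(clones)),
                classification="monoclonal" if len(clones) == 1 else "multiclonal",
            )
        )
    # seeding class as a composition reader assigns it: a lesion whose cells
    # all belong to one clone is monoclonal. A monoclonally seeded source
    # that later gained a private marker subclone reads (correctly, from its
    # final composition) as multiclonal — the founding-event class is not
    # identifiable from present-day data.
    for lesion_id, _ in met_ids:
        seeding_class[lesion_id] = (
            "monoclonal" if len(compositions[lesion_id]) == 1 else "multiclonal"
        )
        for r in routes:
            if r.target_lesion_id == lesion_id:
                r.classification = seeding_class[lesion_id]
    truth = GroundTruth(
        tree=tree,
        lesions=lesions,
        compositions=compositions,
        routes=routes,
        seeding_class=seeding_class,
        config=config,
    )
    validate_ground_truth(truth)
    return truth


def validate_ground_truth(truth: GroundTruth) -> None:
    """Independent check that a generated history obeys the model
    assumptions: every metastasis has exactly one inbound route, no route
    violates the layer order, and each lesion's clone fractions sum to 1
    with nested cluster CCFs (child never above parent)."""
    layer = {l.lesion_id: l.layer for l in truth.lesions}
    targets = [r.target_lesion_id for r in truth.routes]
    mets = [l.lesion_id for l in truth.lesions if not l.is_primary]
    if sorted(targets) != sorted(mets):
        raise ValidationError("each metastasis needs exactly one inbound route")
    for r in truth.routes:
        src, tgt = layer[r.source_lesion_id], layer[r.target_lesion_id]
        if tgt != "LM" and (
            src == "LM" or LAYER_RANK[src] > LAYER_RANK[tgt]
        ):
            raise ValidationError(
                f"route {r.source_lesion_id}->{r.target_lesion_id} violates the "
                "proximal-to-distal layer order"
            )
    for lesion_id, comp in truth.compositions.items():
        total = sum(comp.values())
        if not np.isclose(total, 1.0):
            raise ValidationError(f"{lesion_id}: clone fractions sum to {total}")
        ccf = _cluster_ccfs(truth.tree, comp)
        for child, parent in truth.tree.parent.items():
            if ccf[child] > ccf[parent] + 1e-9:
                raise ValidationError(
                    f"{lesion_id}: cluster {child} CCF exceeds its parent's"
                )


def _mutation_ids(
    tree: CloneTree, rng: np.random.Generator
) -> Dict[str, List[str]]:
    bases = "ACGT"
    out: Dict[str, List[str]] = {}
    used = set()
    for cluster in tree.nodes:
        ids = []
        for _ in range(tree.n_mutations[cluster]):
            while True:
                chrom = f"chr{int(rng.integers(1, 23))}"
                pos = int(rng.integers(1, 200_000_000))
                ref = bases[int(rng.integers(0, 4))]
                alt = bases[int(rng.integers(0, 4))]
                if ref == alt:
                    continue
                mid = f"{chrom}:{pos}:{ref}:{alt}"
                if mid not in used:
                    used.add(mid)
                    break
            ids.append(mid)
        out[cluster] = ids
    return out


def simulate_observations(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> PatientDataset:
    """Emit the PyClone-style per-region mutation table for a truth.

    Per mutation and region the true CCF is the carrying clones' total
    fraction; under binomial noise the expected VAF is purity * CCF / 2
    (diploid, multiplicity 1), the alt count is binomial at the configured
    depth, and the emitted CCF is back-converted from the counts. Regions of
    multi-region lesions receive Dirichlet-perturbed clone fractions to
    emulate spatial heterogeneity; with ``noise='none'`` the true lesion
    CCFs are emitted exactly in every region.
    """
    muts = _mutation_ids(truth.tree, rng)
    records: List[MutationCall] = []
    for lesion in truth.lesions:
        comp = truth.compositions[lesion.lesion_id]
        for sid in lesion.region_sample_ids:
            region_comp = comp
            if config.noise == "binomial" and len(lesion.region_sample_ids) > 1:
                clones = sorted(c for c, f in comp.items() if f > 0)
                alpha = np.array(
                    [config.region_concentration * comp[c] for c in clones]
                )
                fracs = rng.dirichlet(np.maximum(alpha, 1e-3))
                region_comp = {c: float(f) for c, f in zip(clones, fracs)}
            ccfs = _cluster_ccfs(truth.tree, region_comp)
            for cluster in truth.tree.nodes:
                true_ccf = min(1.0, ccfs[cluster])
                for mid in muts[cluster]:
                    if config.noise == "none":
                        records.append(
                            MutationCall(
                                mutation_id=mid,
                                sample_id=sid,
                                ccf=true_ccf,
                                depth=config.depth,
                                cluster_id=cluster,
                                purity=config.purity,
                            )
                        )
                    else:
                        vaf = config.purity * true_ccf / 2.0
                        alt = int(rng.binomial(config.depth, vaf))
                        records.append(
                            MutationCall(
                                mutation_id=mid,
                                sample_id=sid,
                                ccf=ccf_from_counts(
                                    alt, config.depth - alt, config.purity, 2, 1
                                ),
                                depth=config.depth,
                                cluster_id=cluster,
                                ref_count=config.depth - alt,
                                alt_count=alt,
                                purity=config.purity,
                            )
                        )
    return PatientDataset(
        patient_id=f"SIM_{config.seed}",
        lesions=list(truth.lesions),
        mutations=records,
    )


def simulate_patient(
    config: Optional[SimulationConfig] = None,
) -> Tuple[PatientDataset, GroundTruth]:
    """Full simulation: clone tree, seeding history, observed mutation table.

    All randomness flows from one generator seeded with ``config.seed``;
    the draw order is tree, history, observations, so identical seeds give
    byte-identical datasets.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    tree = simulate_clone_tree(config, rng)
    truth = simulate_metastatic_history(tree, config, rng)
    dataset = simulate_observations(truth, config, rng)
    return dataset, truth


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


def _collapse(lesion: str, groups) -> str:
    for g in groups:
        if lesion in g:
            return min(g)
    return lesion


def evaluate_recovery(
    inferred: MetastaticMap,
    truth: GroundTruth,
    inferred_tree: Optional[CloneTree] = None,
) -> dict:
    """Compare an inferred map (and optionally tree) against the truth.

    Route precision/recall/F1 are computed over (source, target) pairs
    after collapsing each of the inferred map's ambiguity groups to a
    single lesion — within such a group the seeding direction is not
    identifiable and any admissible ordering counts as correct.
    """
    true_lesions = {l.lesion_id for l in truth.lesions}
    inf_lesions = {r.target_lesion_id for r in inferred.routes} | {
        r.source_lesion_id for r in inferred.routes
    }
    if not inf_lesions <= true_lesions:
        raise ContractError("inferred map references unknown lesions")

    groups = inferred.ambiguity_groups

    def pairs(routes) -> set:
        out = set()
        for r in routes:
            s = _collapse(r.source_lesion_id, groups)
            t = _collapse(r.target_lesion_id, groups)
            if s != t:
                out.add((s, t))
        return out

    true_pairs = pairs(truth.routes)
    inf_pairs = pairs(inferred.routes)
    tp = len(true_pairs & inf_pairs)
    precision = tp / len(inf_pairs) if inf_pairs else 0.0
    recall = tp / len(true_pairs) if true_pairs else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )

    classes = [
        truth.seeding_class[r.target_lesion_id] == r.classification
        for r in inferred.routes
    ]
    class_accuracy = float(np.mean(classes)) if classes else 0.0

    out = {
        "route_precision": precision,
        "route_recall": recall,
        "route_f1": f1,
        "seeding_class_accuracy": class_accuracy,
    }
    if inferred_tree is not None:
        shared = [
            c
            for c in inferred_tree.parent
            if c in truth.tree.parent
            and inferred_tree.roles.get(c) != "leaf"
        ]
        if shared:
            out["parent_accuracy"] = float(
                np.mean(
                    [truth.tree.parent[c] == inferred_tree.parent[c] for c in shared]
                )
            )
        else:
            out["parent_accuracy"] = 1.0
    return out
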