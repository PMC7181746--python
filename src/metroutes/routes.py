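"""Parsimonious metastatic-map inference.

Model assumptions: (1) lymphatic spread is proximal-to-distal — a source's
layer rank never exceeds a lymphatic target's, and liver metastases never
seed lymphatic layers (any layer may seed a liver metastasis); (2) clones
do not vanish — a lesion's present-day clone content stands in for its
history; (3) migration is rare — each metastasis arises from exactly one
seeding event, and subclones shared by two lesions migrated jointly.

The inference assigns each metastasis one source lesion so that the number
of metastasis-to-metastasis routes is minimal (the primary tumor is always
preferred when it carries the full seeding clone set), the route graph is a
tree rooted at the primary, and ties are broken toward the candidate
sharing the most-derived clone with the target, then by lesion ID.

A metastasis can carry subclones found nowhere a source could have provided
them (they arose in situ after seeding, like a group of lesions linked by a
private marker clone). Such dependency groups are resolved by electing a
group head whose reduced clone set — group-private clusters masked — is
sourceable from outside the group; the rest of the group chains below the
head. When several eligible heads have identical clonal composition the
choice is conventional (the lexicographically largest lesion ID seeds the
smaller ones) and the group is reported as an ambiguity group.
"""

from __future__ import annotations

import logging
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx

from sklearn.base import BaseEstimator

from .model import (
    ABSENT,
    CLONAL,
    SUBCLONAL,
    ClonalityMatrix,
    CloneTree,
    ClusterCCFMatrix,
    ContractError,
    InfeasibilityError,
    LAYER_RANK,
    Lesion,
    MetastaticMap,
    Route,
    SeedingCloneSet,
)

log = logging.getLogger("metroutes")

__all__ = [
    "seeding_clone_set",
    "candidate_sources",
    "infer_metastatic_map",
    "color_route",
    "MetastaticMapBuilder",
]

MONOCLONAL = "monoclonal"
MULTICLONAL = "multiclonal"


def _nonleaf_clusters(tree: CloneTree) -> List[str]:
    return [c for c in tree.nodes if tree.roles.get(c) != "leaf"]


class _CloneCalculus:
    """Interval reading of which clones exist as cell populations.

    The CCF of a cluster counts every cell carrying it, including cells of
    its descendant subclones, so the cluster's own clone has cells only
    where its CCF exceeds the joint CCF of the sub-subclones nested inside
    it. Which clusters are nested inside which is not fully identified by
    the pairwise pigeonhole rules, so two bounds are computed per cluster
    and lesion:

    * the *certain* residual subtracts the maximum-CCF set of clusters that
      could consistently sit disjointly inside the cluster (dominated,
      never reversed, and no pair jointly exceeding 1) — if even that
      leaves more than ``absent_ccf``, the clone certainly has cells and is
      part of the lesion's founding requirement;
    * the *possible* residual subtracts only clusters provably nested
      inside (their joint CCF with the cluster exceeds 1 somewhere) and
      provably pairwise disjoint (reversed CCFs) — if that already removes
      everything, the clone certainly has no cells and cannot be supplied
      by the lesion.

    Requirements use the certain reading and availability the possible one,
    so a lesion's true source always qualifies as a candidate.
    """

    def __init__(
        self,
        tree: CloneTree,
        status: ClonalityMatrix,
        matrix: Optional[ClusterCCFMatrix],
        absent_ccf: float = 0.05,
        epsilon: float = 0.05,
    ):
        self.tree = tree
        self.status = status
        self.matrix = matrix
        self.thr = absent_ccf
        self.eps = epsilon
        self.clusters = _nonleaf_clusters(tree)
        if matrix is not None:
            import numpy as np

            self.vec = {
                c: matrix.ccf.loc[c].to_numpy(dtype=float) for c in self.clusters
            }
            eps = epsilon
            self.dominates = {}
            self.branching = {}
            self.overlap = {}  # joint CCF above 1 somewhere -> must be nested
            for a in self.clusters:
                for b in self.clusters:
                    if a == b:
                        continue
                    va, vb = self.vec[a], self.vec[b]
                    a_strict = bool(np.any(va > vb + eps))
                    b_strict = bool(np.any(vb > va + eps))
                    self.dominates[(a, b)] = bool(np.all(va >= vb - eps)) and a_strict
                    self.branching[(a, b)] = a_strict and b_strict
                    self.overlap[(a, b)] = bool(np.any(va + vb > 1.0 + eps))
        self._cache: Dict = {}

    def _max_weight_disjoint(
        self, pool: List[str], weights: Dict[str, float], compatible
    ) -> float:
        """Maximum total CCF over subsets of ``pool`` that are pairwise
        ``compatible`` (i.e. could or must be disjoint subclones)."""
        pool = [c for c in pool if weights[c] > 0]
        pool.sort(key=lambda c: -weights[c])
        best = 0.0

        def rec(i: int, chosen: List[str], total: float) -> None:
            nonlocal best
            if total > best:
                best = total
            if i == len(pool):
                return
            remaining = sum(weights[c] for c in pool[i:])
            if total + remaining <= best:
                return
            c = pool[i]
            if all(compatible(c, d) for d in chosen):
                chosen.append(c)
                rec(i + 1, chosen, total + weights[c])
                chosen.pop()
            rec(i + 1, chosen, total)

        rec(0, [], 0.0)
        return best

    def _clone_set(
        self, lesion_id: str, masked: FrozenSet[str], certain: bool
    ) -> FrozenSet[str]:
        key = (lesion_id, masked, certain)
        if key in self._cache:
            return self._cache[key]
        col = self.status.status[lesion_id]
        present = [
            c for c in self.clusters if c not in masked and col[c] != ABSENT
        ]
        if self.matrix is None:
            subclonal = [c for c in present if col[c] == SUBCLONAL]
            clonal = [c for c in present if col[c] == CLONAL]
            out: FrozenSet[str] = frozenset()
            if clonal:
                deepest = max(clonal, key=lambda c: (self.tree.depth(c), c))
                out = frozenset(subclonal) | {deepest}
            self._cache[key] = out
            return out
        lesion_idx = list(self.matrix.ccf.columns).index(lesion_id)
        weights = {c: float(self.vec[c][lesion_idx]) for c in present}
        out_set = set()
        for c in present:
            if certain:
                pool = [
                    d
                    for d in present
                    if d != c
                    and self.dominates[(c, d)]
                    and not self.branching[(c, d)]
                ]
                compatible = lambda a, b: not (
                    self.overlap[(a, b)] or self.overlap[(b, a)]
                )
            else:
                pool = [
                    d
                    for d in present
                    if d != c
                    and self.dominates[(c, d)]
                    and not self.branching[(c, d)]
                    and self.overlap[(c, d)]
                ]
                compatible = lambda a, b: self.branching[(a, b)]
            sub = self._max_weight_disjoint(pool, weights, compatible)
            if weights[c] - sub > self.thr + 1e-9:
                out_set.add(c)
        out = frozenset(out_set)
        self._cache[key] = out
        return out

    def plausible(
        self, lesion_id: str, masked: FrozenSet[str] = frozenset()
    ) -> FrozenSet[str]:
        """Most-plausible clone populations under a single nesting forest.

        Each dominated, never-reversed cluster is assigned to its tightest
        dominator — the one whose CCF margin over it (across the lesions
        where it is present) is smallest; a near-zero margin means the
        subclone saturates that host somewhere, strong evidence of
        containment. Unlike the certain/possible bounds, every cluster is
        subtracted exactly once, so marker-rich lesions keep their real
        residual clones. Used to rank contested seeding directions."""
        key = (lesion_id, masked, "plausible")
        if key in self._cache:
            return self._cache[key]
        col = self.status.status[lesion_id]
        present = [
            c for c in self.clusters if c not in masked and col[c] != ABSENT
        ]
        if self.matrix is None:
            out = self._clone_set(lesion_id, masked, certain=True)
            self._cache[key] = out
            return out
        lesion_idx = list(self.matrix.ccf.columns).index(lesion_id)
        weights = {c: float(self.vec[c][lesion_idx]) for c in present}
        child_sum = {c: 0.0 for c in present}
        for d in present:
            doms = [
                a
                for a in present
                if a != d
                and self.dominates[(a, d)]
                and not self.branching[(a, d)]
            ]
            if not doms:
                continue

            def margin(a: str) -> float:
                vd = self.vec[d]
                mask_l = vd > self.thr
                diffs = (self.vec[a] - vd)[mask_l]
                return float(diffs.min()) if diffs.size else float(
                    (self.vec[a] - vd).min()
                )

            host = min(
                doms, key=lambda a: (margin(a), float(self.vec[a].max()), a)
            )
            child_sum[host] += weights[d]
        out = frozenset(
            c
            for c in present
            if weights[c] - child_sum[c] > self.thr + 1e-9
        )
        self._cache[key] = out
        return out

    def requirement(
        self, lesion_id: str, masked: FrozenSet[str] = frozenset()
    ) -> FrozenSet[str]:
        """Clones that certainly founded the lesion."""
        out = self._clone_set(lesion_id, masked, certain=True)
        if out:
            return out
        # degenerate fall-back: the deepest clonal cluster founds the lesion
        col = self.status.status[lesion_id]
        clonal = [
            c
            for c in self.clusters
            if c not in masked and col[c] == CLONAL
        ]
        if clonal:
            return frozenset({max(clonal, key=lambda c: (self.tree.depth(c), c))})
        return frozenset()

    def available(
        self, lesion_id: str, masked: FrozenSet[str] = frozenset()
    ) -> FrozenSet[str]:
        """Clones that possibly exist as cell populations in the lesion."""
        return self._clone_set(lesion_id, masked, certain=False)


def _seeding_set(
    lesion_id: str,
    tree: CloneTree,
    status: ClonalityMatrix,
    matrix: Optional[ClusterCCFMatrix] = None,
    absent_ccf: float = 0.05,
    masked: FrozenSet[str] = frozenset(),
    calculus: Optional[_CloneCalculus] = None,
) -> Optional[SeedingCloneSet]:
    col = status.status[lesion_id]
    clusters = [c for c in _nonleaf_clusters(tree) if c not in masked]
    present = [c for c in clusters if col[c] != ABSENT]
    if not present:
        return None
    subclonal = [c for c in present if col[c] == SUBCLONAL]
    clonal = [c for c in present if col[c] == CLONAL]
    if not clonal:
        return None
    if calculus is None:
        calculus = _CloneCalculus(tree, status, matrix, absent_ccf)
    clones = calculus.requirement(lesion_id, masked)
    if not clones:
        return None
    return SeedingCloneSet(
        lesion_id=lesion_id,
        clones=tuple(sorted(clones)),
        classification=MONOCLONAL if not subclonal else MULTICLONAL,
    )


def seeding_clone_set(
    lesion: Lesion,
    tree: CloneTree,
    status: ClonalityMatrix,
    matrix: Optional[ClusterCCFMatrix] = None,
    absent_ccf: float = 0.05,
) -> SeedingCloneSet:
    """The subclones that founded a lesion, read from its clonal composition.

    With CCFs available (``matrix``), a cluster marks a founding clone when
    its CCF exceeds the summed CCFs of its present children by more than
    ``absent_ccf`` — cells carrying that cluster as their most-derived one
    actually exist. Without CCFs the status-level reading is used: every
    present subclonal (non-leaf) cluster plus the deepest clonal cluster.
    A lesion whose present clusters are all clonal was seeded monoclonally.
    """
    lesion_id = lesion.lesion_id if isinstance(lesion, Lesion) else lesion
    out = _seeding_set(lesion_id, tree, status, matrix, absent_ccf)
    if out is None:
        raise ContractError(
            f"lesion {lesion_id}: no present (non-leaf) clusters — cannot derive "
            "a seeding clone set"
        )
    return out


def _layer_allows(source: Lesion, target: Lesion) -> bool:
    if target.layer == "LM":
        return True
    if source.layer == "LM":
        return False
    return LAYER_RANK[source.layer] <= LAYER_RANK[target.layer]


def _available_clones(
    lesion_id: str,
    tree: CloneTree,
    status: ClonalityMatrix,
    matrix: Optional[ClusterCCFMatrix] = None,
    absent_ccf: float = 0.05,
    calculus: Optional[_CloneCalculus] = None,
) -> FrozenSet[str]:
    """Clones possibly existing as cell populations in a lesion (the
    optimistic side of the interval reading); without CCFs this falls back
    to the status-level seeding-set reading."""
    if calculus is None:
        calculus = _CloneCalculus(tree, status, matrix, absent_ccf)
    if calculus.matrix is None:
        s = _seeding_set(lesion_id, tree, status, calculus=calculus)
        return frozenset(s.clones) if s is not None else frozenset()
    return calculus.available(lesion_id)


def _candidates(
    target: SeedingCloneSet,
    lesions: Sequence[Lesion],
    avail: Dict[str, FrozenSet[str]],
    exclude: FrozenSet[str] = frozenset(),
) -> List[str]:
    target_lesion = next(l for l in lesions if l.lesion_id == target.lesion_id)
    need = set(target.clones)
    out = []
    for s in lesions:
        if s.lesion_id == target.lesion_id or s.lesion_id in exclude:
            continue
        if not _layer_allows(s, target_lesion):
            continue
        if need <= avail[s.lesion_id]:
            out.append(s.lesion_id)
    return out


def candidate_sources(
    target: SeedingCloneSet,
    all_lesions: Sequence[Lesion],
    status: ClonalityMatrix,
    tree: CloneTree,
    matrix: Optional[ClusterCCFMatrix] = None,
    absent_ccf: float = 0.05,
) -> List[str]:
    """Lesions that could have supplied the target's full seeding clone set.

    A source qualifies when every seeding clone of the target exists as a
    cell population in it (present subclonal cluster, or its deepest clonal
    cluster) and the layer constraint holds: lymphatic targets accept only
    sources at the same or a more proximal lymphatic layer (or the
    primary), liver metastases accept any source. Raises when no lesion
    qualifies.
    """
    avail = {
        l.lesion_id: _available_clones(l.lesion_id, tree, status, matrix, absent_ccf)
        for l in all_lesions
    }
    out = _candidates(target, all_lesions, avail)
    if not out:
        missing = {
            c
            for c in target.clones
            if all(
                c not in avail[l.lesion_id]
                for l in all_lesions
                if l.lesion_id != target.lesion_id
            )
        }
        raise InfeasibilityError(
            f"no candidate source for {target.lesion_id}; clones available "
            f"nowhere else: "
            f"{sorted(missing) or '(layer constraints exclude all carriers)'}"
        )
    return out


def color_route(route: Route, tree: CloneTree) -> str:
    """The smallest involved subclone: the deepest seeding clone in the
    clone tree (ties: fewer descendants, then lower cluster ID)."""
    return min(
        route.seeding_clones,
        key=lambda c: (-tree.depth(c), tree.subtree_size(c), c),
    )


class _Inference:
    def __init__(
        self,
        lesions: Sequence[Lesion],
        tree: CloneTree,
        status: ClonalityMatrix,
        matrix: Optional[ClusterCCFMatrix] = None,
        absent_ccf: float = 0.05,
    ):
        self.lesions = list(lesions)
        self.by_id = {l.lesion_id: l for l in lesions}
        self.tree = tree
        self.status = status
        self.matrix = matrix
        self.absent_ccf = absent_ccf
        self.primary = next(l.lesion_id for l in lesions if l.is_primary)
        self.metastases = sorted(
            l.lesion_id for l in lesions if not l.is_primary
        )
        self.calculus = _CloneCalculus(tree, status, matrix, absent_ccf)
        self.seed_sets: Dict[str, SeedingCloneSet] = {}
        for m in self.metastases:
            out = _seeding_set(
                m, tree, status, matrix, absent_ccf, calculus=self.calculus
            )
            if out is None:
                raise ContractError(
                    f"lesion {m}: no present (non-leaf) clusters — cannot "
                    "derive a seeding clone set"
                )
            self.seed_sets[m] = out
        nonleaf = _nonleaf_clusters(tree)
        self.present: Dict[str, FrozenSet[str]] = {
            l.lesion_id: frozenset(
                c for c in nonleaf
                if status.status.at[c, l.lesion_id] != ABSENT
            )
            for l in lesions
        }
        self.avail: Dict[str, FrozenSet[str]] = {
            l.lesion_id: _available_clones(
                l.lesion_id, tree, status, matrix, absent_ccf,
                calculus=self.calculus,
            )
            for l in lesions
        }
        self.cands: Dict[str, List[str]] = {
            m: _candidates(self.seed_sets[m], self.lesions, self.avail)
            for m in self.metastases
        }
        self.route_clones: Dict[str, Tuple[str, ...]] = {
            m: self.seed_sets[m].clones for m in self.metastases
        }
        self.ambiguity_groups: List[Tuple[str, ...]] = []

    # ---- preference orders -------------------------------------------------

    def _shared_depth(self, a: str, b: str) -> int:
        shared = self.present[a] & self.present[b]
        return max((self.tree.depth(c) for c in shared), default=-1)

    def _pref_key(self, target: str, source: str):
        return (
            0 if source == self.primary else 1,
            -self._shared_depth(target, source),
            source,
        )

    # ---- acyclic assignment ------------------------------------------------

    def _creates_cycle(self, sigma: Dict[str, str], target: str, source: str) -> bool:
        node = source
        while node in sigma:
            node = sigma[node]
            if node == target:
                return True
        return node == target

    def _backtrack(
        self, remaining: List[str], sigma: Dict[str, str]
    ) -> Optional[Dict[str, str]]:
        if not remaining:
            return dict(sigma)
        m = remaining[0]
        for s in sorted(self.cands[m], key=lambda s: self._pref_key(m, s)):
            if self._creates_cycle(sigma, m, s):
                continue
            sigma[m] = s
            out = self._backtrack(remaining[1:], sigma)
            if out is not None:
                return out
            del sigma[m]
        return None

    # ---- dependency groups -------------------------------------------------

    def _build_group(self, start: str) -> Set[str]:
        """Closure of lesions linked by clusters absent from the primary."""
        group = {start}
        frontier = [start]
        while frontier:
            m = frontier.pop()
            blocked = [
                c
                for c in self.seed_sets[m].clones
                if c not in self.avail[self.primary]
            ]
            for c in blocked:
                for l in self.metastases:
                    if l not in group and c in self.present[l]:
                        group.add(l)
                        frontier.append(l)
        return group

    def _masked_clusters(self, group: Set[str]) -> FrozenSet[str]:
        outside = [
            l.lesion_id for l in self.lesions if l.lesion_id not in group
        ]
        masked = set()
        for c in _nonleaf_clusters(self.tree):
            carried_in_group = any(c in self.present[m] for m in group)
            carried_outside = any(
                self.status.status.at[c, l] != ABSENT for l in outside
            )
            if carried_in_group and not carried_outside:
                masked.add(c)
        return frozenset(masked)

    def _composition(self, lesion_id: str) -> Tuple[Tuple[str, str], ...]:
        col = self.status.status[lesion_id]
        return tuple((c, col[c]) for c in sorted(_nonleaf_clusters(self.tree)))

    def _head_order(self, group: Set[str], masked: FrozenSet[str]) -> List[str]:
        """Group members in head-preference order.

        The founder of a dependency group must be able to (transitively)
        supply every other member, and no member may be able to supply it:
        heads are taken from the root strongly-connected components of the
        within-group "can-source" digraph. Members of one root component
        are mutually sourceable (identical-composition case); there the
        choice is conventional — group-private clusters held subclonally
        (arisen in situ) are preferred over clonally (founding event), then
        the richer clone content, then the lexicographically largest ID.
        """
        # the digraph compares each member's REDUCED requirement (its
        # group-private clusters masked — they may have arisen in situ)
        # against the others' availability: a member nobody else can supply
        # even in that weakened sense must be the founder of its component
        reduced_req: Dict[str, Set[str]] = {}
        certain: Dict[str, FrozenSet[str]] = {}
        for m in group:
            red = _seeding_set(
                m, self.tree, self.status, self.matrix, self.absent_ccf,
                masked=masked, calculus=self.calculus,
            )
            reduced_req[m] = set(red.clones) if red is not None else set(
                self.seed_sets[m].clones
            )
            certain[m] = self.calculus.plausible(m)
        dig = nx.DiGraph()
        dig.add_nodes_from(group)

        def cost(s: str, m: str) -> int:
            # clones the edge borrows beyond the source's most-plausible
            # clone populations
            return len(reduced_req[m] - certain[s])

        for s in group:
            for m in group:
                if s != m and reduced_req[m] <= self.avail[s]:
                    dig.add_edge(s, m)
        # orient contested pairs toward the direction needing fewer
        # optimistically assumed clones; equal-cost pairs stay mutual
        # (identical compositions resolve by convention further down)
        for s, m in list(dig.edges):
            if dig.has_edge(m, s) and cost(s, m) < cost(m, s):
                dig.remove_edge(m, s)
        cond = nx.condensation(dig)
        roots: Set[str] = set()
        for n in cond.nodes:
            if cond.in_degree(n) == 0:
                roots |= set(cond.nodes[n]["members"])

        def key(h: str):
            col = self.status.status[h]
            n_clonal = sum(1 for c in masked if col[c] == CLONAL)
            return (0 if h in roots else 1, n_clonal, -len(self.present[h]))

        return sorted(sorted(group, reverse=True), key=key)

    # ---- main solve --------------------------------------------------------

    #: cap on dependency-group resolution attempts; legitimate instances
    #: need at most a few dozen, so exceeding this means the constraints are
    #: mutually inconsistent (noisy clonality calls) and we fail loudly
    MAX_SOLVE_CALLS = 2000

    def solve(self, remaining: List[str], sigma: Dict[str, str]) -> Dict[str, str]:
        self._solve_calls = getattr(self, "_solve_calls", 0) + 1
        if self._solve_calls > self.MAX_SOLVE_CALLS:
            raise InfeasibilityError(
                "metastatic-map search budget exceeded; source constraints "
                "appear mutually inconsistent"
            )
        out = self._backtrack(sorted(remaining), dict(sigma))
        if out is not None:
            return out
        for start in sorted(remaining):
            group = self._build_group(start) & set(remaining)
            if not group:
                continue
            masked = self._masked_clusters(group)
            for h in self._head_order(group, masked):
                reduced = _seeding_set(
                    h, self.tree, self.status, self.matrix, self.absent_ccf,
                    masked=masked, calculus=self.calculus,
                )
                if reduced is None:
                    continue
                ext = _candidates(
                    reduced, self.lesions, self.avail, exclude=frozenset(group)
                )
                if not ext:
                    continue
                src = min(ext, key=lambda s: self._pref_key(h, s))
                trial = dict(sigma)
                trial[h] = src
                if self._creates_cycle(sigma, h, src):
                    continue
                try:
                    solved = self.solve(
                        [m for m in remaining if m != h], trial
                    )
                except InfeasibilityError:
                    continue
                # commit: remember the transported clone set and ambiguity
                self.route_clones[h] = reduced.clones
                eligible_same = []
                for h2 in group:
                    if self._composition(h2) != self._composition(h):
                        continue
                    red2 = _seeding_set(
                        h2, self.tree, self.status, self.matrix,
                        self.absent_ccf, masked=masked, calculus=self.calculus,
                    )
                    if red2 is not None and _candidates(
                        red2, self.lesions, self.avail, exclude=frozenset(group)
                    ):
                        eligible_same.append(h2)
                if len(eligible_same) >= 2:
                    self.ambiguity_groups.append(tuple(sorted(eligible_same)))
                    log.info(
                        "infer_metastatic_map: lesions %s have identical clonal "
                        "composition; %s designated the externally seeded one "
                        "by convention",
                        sorted(eligible_same), h,
                    )
                log.info(
                    "infer_metastatic_map: dependency group %s resolved with "
                    "head %s seeded by %s (group-private clusters %s treated "
                    "as arisen in situ)",
                    sorted(group), h, src, sorted(masked),
                )
                return solved
        raise InfeasibilityError(
            f"no acyclic source assignment exists for lesions {sorted(remaining)}"
        )


def infer_metastatic_map(
    lesions: Sequence[Lesion],
    tree: CloneTree,
    status: ClonalityMatrix,
    matrix: Optional[ClusterCCFMatrix] = None,
    patient_id: str = "",
    absent_ccf: float = 0.05,
) -> MetastaticMap:
    """Assign exactly one source lesion to every metastasis.

    Minimizes the number of metastasis-to-metastasis routes (the primary is
    chosen whenever it carries the target's full seeding clone set), then
    prefers the candidate sharing the deepest clone with the target, then
    the smallest lesion ID; the result is verified to be a directed tree
    rooted at the primary.
    """
    from .summary import classify_mode  # local import avoids a module cycle

    inf = _Inference(lesions, tree, status, matrix, absent_ccf)
    sigma: Dict[str, str] = {}
    remaining = []
    for m in inf.metastases:
        if inf.primary in inf.cands[m]:
            sigma[m] = inf.primary
            log.info(
                "infer_metastatic_map: %s seeded by the primary (%s); seeding "
                "clones %s", m, inf.primary, list(inf.seed_sets[m].clones),
            )
        else:
            remaining.append(m)
    sigma = inf.solve(remaining, sigma)

    routes = []
    for m in inf.metastases:
        r = Route(
            source_lesion_id=sigma[m],
            target_lesion_id=m,
            seeding_clones=inf.route_clones[m],
            classification=inf.seed_sets[m].classification,
        )
        r.color_cluster = color_route(r, tree)
        r.mode = classify_mode(r, {l.lesion_id: l.layer for l in lesions})
        routes.append(r)
    mmap = MetastaticMap(
        patient_id=patient_id,
        routes=routes,
        ambiguity_groups=[tuple(g) for g in inf.ambiguity_groups],
    )
    mmap.validate(lesions)
    return mmap


class MetastaticMapBuilder(BaseEstimator):
    """Estimator inferring the parsimonious metastatic map of one patient.

    ``fit`` takes the clonality matrix plus the clone tree and lesion list;
    fitted attributes expose the per-lesion seeding clone sets and the map.
    """

    def __init__(self, patient_id: str = ""):
        self.patient_id = patient_id

    def fit(
        self,
        X: ClonalityMatrix,
        y=None,
        *,
        tree: CloneTree,
        lesions: Sequence[Lesion],
        matrix: Optional[ClusterCCFMatrix] = None,
    ):
        self.seeding_sets_ = {
            l.lesion_id: seeding_clone_set(l, tree, X, matrix)
            for l in lesions
            if not l.is_primary
        }
        self.map_ = infer_metastatic_map(
            lesions, tree, X, matrix, patient_id=self.patient_id
        )
        self.routes_ = self.map_.routes
        return self
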