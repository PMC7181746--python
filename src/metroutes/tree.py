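"""Clone-tree reconstruction from CCF constraints via the pigeonhole principle.

A patient's mutation clusters are arranged into a rooted tree whose root is
the trunk cluster (the MRCA, clonal in every lesion). For any two clusters
the per-lesion CCFs determine their relationship:

* linear (one is an ancestor of the other) when one has larger CCFs in all
  lesions, or when their CCFs sum to more than 1 somewhere (two disjoint
  subclones cannot jointly exceed the whole tumor);
* branching (disjoint subclones) when their relative CCFs are reversed
  between lesions;
* and two subclones in disjoint subtrees can never sum above the CCF of a
  shared ancestor in any lesion (the pigeonhole constraint).

All comparisons carry a tolerance ``epsilon``. Consistent-order evidence
(one cluster at least as large in every lesion, strictly larger somewhere)
orients a pair — the smaller cluster can never be the ancestor — and makes
the larger one a *preferred* parent; it does not force nesting on its own,
because two disjoint subclones can show a consistent order by chance when
they co-occur in few lesions. Nesting is forced exactly where the
pigeonhole requires it: whenever the joint CCF of two disjoint subclones
would exceed a shared ancestor's capacity. A cluster called clonal in a
lesion is treated as occupying the full cancer-cell population there
(capacity 1.0) when it serves as an ancestor bound, since the clonal call
already asserts ubiquity and the measured shortfall below 1 is depth noise.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .model import (
    ABSENT,
    CLONAL,
    ClonalityMatrix,
    CloneTree,
    ClusterCCFMatrix,
    ClusterRole,
    InconsistencyError,
    PairRelation,
    Role,
)

log = logging.getLogger("metroutes")

__all__ = [
    "classify_cluster_roles",
    "pairwise_relation",
    "build_clone_tree",
    "nested_ovals",
    "CloneTreeBuilder",
]


def classify_cluster_roles(status: ClonalityMatrix) -> List[ClusterRole]:
    """Assign trunk / branch / leaf roles from the clonality matrix.

    The trunk is the unique cluster clonal in every lesion; clusters present
    (not absent) in two or more lesions are branches; clusters present in
    exactly one lesion are leaves. A cluster present everywhere but
    subclonal somewhere is a branch, not a trunk.
    """
    df = status.status
    if df.empty:
        raise InconsistencyError("no clusters to classify")
    trunk_candidates = [
        cid for cid in df.index if (df.loc[cid] == CLONAL).all()
    ]
    if len(trunk_candidates) == 0:
        raise InconsistencyError("no trunk cluster: no cluster is clonal in all lesions")
    if len(trunk_candidates) > 1:
        raise InconsistencyError(
            f"ambiguous MRCA: clusters {trunk_candidates} are all clonal in every lesion"
        )
    trunk = trunk_candidates[0]
    roles = []
    for cid in df.index:
        n_present = int((df.loc[cid] != ABSENT).sum())
        if cid == trunk:
            roles.append(ClusterRole(cid, Role.TRUNK))
        elif n_present >= 2:
            roles.append(ClusterRole(cid, Role.BRANCH))
        elif n_present == 1:
            roles.append(ClusterRole(cid, Role.LEAF))
        else:
            raise InconsistencyError(f"cluster {cid} is absent in every lesion")
    return roles


def _relation(a: np.ndarray, b: np.ndarray, epsilon: float) -> str:
    """Raw pairwise relationship: 'branching', 'a_over_b', 'b_over_a',
    'tied_linear' (equal within epsilon but jointly exceeding 1 somewhere,
    hence nested in one direction or the other), or 'none'."""
    a_strict = bool(np.any(a > b + epsilon))
    b_strict = bool(np.any(b > a + epsilon))
    if a_strict and b_strict:
        return "branching"
    if a_strict:
        return "a_over_b"
    if b_strict:
        return "b_over_a"
    if bool(np.any(a + b > 1.0 + epsilon)):
        return "tied_linear"
    return "none"


def pairwise_relation(
    ccf_a: Sequence[float], ccf_b: Sequence[float], epsilon: float = 0.05
) -> PairRelation:
    """Pigeonhole relationship between two clusters' per-lesion CCF vectors."""
    a = np.asarray(ccf_a, dtype=float)
    b = np.asarray(ccf_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pairwise_relation: vectors must share the lesion axis")
    rel = _relation(a, b, epsilon)
    if rel == "branching":
        return PairRelation.BRANCHING
    if rel == "a_over_b":
        return PairRelation.LINEAR_A_OVER_B
    if rel == "b_over_a":
        return PairRelation.LINEAR_B_OVER_A
    if rel == "tied_linear":
        # nested, but the orientation is not identified; report the larger
        # mean as the ancestor (first argument wins an exact tie)
        return (
            PairRelation.LINEAR_A_OVER_B
            if float(a.mean()) >= float(b.mean())
            else PairRelation.LINEAR_B_OVER_A
        )
    return PairRelation.UNDETERMINED


class _Constraints:
    """Precomputed CCF vectors, capacities and pairwise relations."""

    def __init__(
        self,
        matrix: ClusterCCFMatrix,
        status: ClonalityMatrix,
        clusters: Sequence[str],
        epsilon: float,
    ):
        self.epsilon = epsilon
        self.clusters = list(clusters)
        self.ccf = {c: matrix.ccf.loc[c].to_numpy(dtype=float) for c in clusters}
        # ancestor capacity: clonal clusters bound their subtrees by the full
        # cancer-cell population, not by their (noise-shrunk) measured mean
        self.capacity = {
            c: np.where(
                status.status.loc[c].to_numpy() == CLONAL, 1.0, self.ccf[c]
            )
            for c in clusters
        }
        self.rel = {}
        for x, y in itertools.combinations(self.clusters, 2):
            r = _relation(self.ccf[x], self.ccf[y], epsilon)
            self.rel[(x, y)] = r
            self.rel[(y, x)] = {
                "a_over_b": "b_over_a",
                "b_over_a": "a_over_b",
            }.get(r, r)

    def can_parent(self, p: str, c: str) -> bool:
        """Nesting admissible: c fits under p in every lesion and the pair
        is not branching / reversed-linear."""
        r = self.rel[(p, c)]
        if r in ("branching", "b_over_a"):
            return False
        return bool(np.all(self.ccf[c] <= self.capacity[p] + self.epsilon))


def _tree_is_valid(parent: Dict[str, str], root: str, cons: _Constraints) -> bool:
    eps = cons.epsilon
    anc: Dict[str, set] = {}
    for node in cons.clusters:
        chain = set()
        cur = node
        while cur in parent:
            cur = parent[cur]
            chain.add(cur)
        anc[node] = chain
    # edge nesting
    for c, p in parent.items():
        if not np.all(cons.ccf[c] <= cons.capacity[p] + eps):
            return False
    for x, y in itertools.combinations(cons.clusters, 2):
        related = x in anc[y] or y in anc[x]
        r = cons.rel[(x, y)]
        if r == "branching" and related:
            # reversed CCFs between lesions: disjoint subclones, never nested
            return False
        if r == "a_over_b" and y in anc[x]:
            # orientation: the strictly-smaller cluster cannot be the ancestor
            return False
        if r == "b_over_a" and x in anc[y]:
            return False
        if not related:
            # pigeonhole: disjoint subclones must fit jointly inside every
            # common ancestor (trunk capacity 1 covers the sum-above-one
            # branch of the linearity rule)
            for a in anc[x] & anc[y]:
                if np.any(
                    cons.ccf[x] + cons.ccf[y] > cons.capacity[a] + eps
                ):
                    return False
    return True


def _search_tree(
    root: str,
    order: List[str],
    candidates: Dict[str, List[str]],
    cons: _Constraints,
) -> Optional[Dict[str, str]]:
    """Depth-first search over parent assignments; first valid tree wins.

    ``candidates`` lists admissible parents for each cluster; at each step
    they are re-ranked to prefer the shallowest feasible ancestor (largest
    maximum CCF, then cluster ID, as tie-breaks). Nesting below a subclone
    is asserted only where the pigeonhole sum constraints force it: CCF
    dominance alone cannot distinguish a descendant from a disjoint smaller
    subclone, and an unforced nesting would silently eat the ancestor's
    residual clone. The first solution found is the deterministic
    shallowest-consistent tree.
    """
    parent: Dict[str, str] = {}

    def cur_depth(p: str) -> int:
        d = 0
        while p in parent:
            p = parent[p]
            d += 1
        return d

    def chain_ok(c: str) -> bool:
        # prune: no assigned ancestor of c may be branching with c, and c
        # must fit inside every assigned ancestor's capacity
        cur = c
        seen = {c}
        while cur in parent:
            cur = parent[cur]
            if cur in seen:
                return False
            seen.add(cur)
            if cons.rel[(cur, c)] in ("branching", "b_over_a"):
                return False
            if not np.all(cons.ccf[c] <= cons.capacity[cur] + cons.epsilon):
                return False
        return True

    def rec(i: int) -> bool:
        if i == len(order):
            return _tree_is_valid(parent, root, cons)
        c = order[i]
        ranked = sorted(
            candidates[c],
            key=lambda p: (cur_depth(p), -float(cons.ccf[p].max()), p),
        )
        for p in ranked:
            parent[c] = p
            # cycle check among assigned plus chain pruning
            if chain_ok(c) and rec(i + 1):
                return True
            del parent[c]
        return False

    return dict(parent) if rec(0) else None


def build_clone_tree(
    matrix: ClusterCCFMatrix,
    status: ClonalityMatrix,
    roles: Optional[Sequence[ClusterRole]] = None,
    epsilon: float = 0.05,
) -> CloneTree:
    """Reconstruct the rooted clone tree satisfying the pigeonhole rules.

    The tree is built over the trunk and branch clusters; each non-trunk
    cluster attaches to the shallowest feasible ancestor, so nesting below
    another subclone is asserted exactly where the pigeonhole sum
    constraints require it (CCF dominance alone cannot separate a
    descendant from a disjoint smaller subclone). Clusters whose pairwise
    relation is undetermined default to branching under a common parent and
    are only nested when no tree exists otherwise. Leaf clusters are
    attached afterwards under the deepest cluster clonal in their single
    lesion; they never constrain the core tree.
    """
    if roles is None:
        roles = classify_cluster_roles(status)
    role_of = {r.cluster_id: r.role for r in roles}
    trunk = next(r.cluster_id for r in roles if r.role is Role.TRUNK)
    core = [c for c in matrix.cluster_ids if role_of[c] in (Role.TRUNK, Role.BRANCH)]
    leaves = [c for c in matrix.cluster_ids if role_of[c] is Role.LEAF]

    cons = _Constraints(matrix, status, core, epsilon)
    non_trunk = sorted(
        (c for c in core if c != trunk),
        key=lambda c: (-float(cons.ccf[c].max()), c),
    )

    def cand(c: str, allow_undetermined: bool) -> List[str]:
        out = []
        for p in core:
            if p == c or not cons.can_parent(p, c):
                continue
            r = cons.rel[(p, c)]
            if r in ("a_over_b", "tied_linear") or (
                allow_undetermined and r == "none"
            ):
                out.append(p)
        out.sort(key=lambda p: (float(cons.ccf[p].max()), p))
        return out

    parent = None
    for allow_undetermined in (False, True):
        candidates = {c: cand(c, allow_undetermined) for c in non_trunk}
        if any(not v for v in candidates.values()):
            continue
        parent = _search_tree(trunk, non_trunk, candidates, cons)
        if parent is not None:
            if allow_undetermined:
                log.info(
                    "build_clone_tree: nested one or more undetermined pairs "
                    "to satisfy the pigeonhole constraints"
                )
            break
    if parent is None:
        raise InconsistencyError(
            "no clone tree satisfies the pigeonhole constraints for clusters "
            f"{core} at epsilon={epsilon}"
        )

    tree = CloneTree(
        parent=dict(parent),
        root=trunk,
        n_mutations={c: int(matrix.n_mutations[c]) for c in matrix.cluster_ids},
        roles={c: role_of[c].value for c in matrix.cluster_ids},
    )

    # attach leaf clusters under the deepest cluster clonal in their lesion
    for leaf in leaves:
        row = status.status.loc[leaf]
        lesion = next(l for l in status.lesion_ids if row[l] != ABSENT)
        clonal_here = [
            c for c in core if status.status.at[c, lesion] == CLONAL
        ]
        host = max(clonal_here, key=lambda c: (tree.depth(c), c))
        tree.parent[leaf] = host
        log.info(
            "build_clone_tree: leaf cluster %s (private to %s) attached under %s",
            leaf, lesion, host,
        )
    # re-validate connectivity including the leaves
    return CloneTree(
        parent=tree.parent, root=trunk, n_mutations=tree.n_mutations, roles=tree.roles
    )


def nested_ovals(
    tree: CloneTree, status: ClonalityMatrix, matrix: ClusterCCFMatrix
) -> Dict[str, List[Tuple[str, float]]]:
    """Machine-readable nesting (oval-plot) description per lesion.

    For each lesion, the present clusters are listed in pre-order of the
    clone tree, i.e. each cluster is preceded by the ovals that contain it.
    Raises if a present cluster's tree parent is absent in the lesion.
    """
    out: Dict[str, List[Tuple[str, float]]] = {}
    for lesion in status.lesion_ids:
        present = set(status.present_clusters(lesion))
        for c in sorted(present):
            p = tree.parent.get(c)
            if p is not None and p not in present:
                raise InconsistencyError(
                    f"lesion {lesion}: cluster {c} is present but its parent "
                    f"{p} is absent — nesting violated"
                )
        ordered: List[Tuple[str, float]] = []

        def visit(node: str) -> None:
            if node in present:
                ordered.append((node, float(matrix.ccf.at[node, lesion])))
            for child in tree.children(node):
                visit(child)

        visit(tree.root)
        out[lesion] = ordered
    return out


class CloneTreeBuilder(BaseEstimator):
    """Estimator reconstructing the clone tree of one patient.

    Parameters
    ----------
    epsilon : float, default 0.05
        Tolerance for all CCF comparisons in the pigeonhole rules.

    Attributes
    ----------
    roles_ : list of ClusterRole
    tree_ : CloneTree
    """

    def __init__(self, epsilon: float = 0.05):
        self.epsilon = epsilon

    def fit(self, X: ClusterCCFMatrix, y: Optional[ClonalityMatrix] = None):
        if y is None:
            raise ValueError("CloneTreeBuilder.fit requires the clonality matrix as y")
        self.roles_ = classify_cluster_roles(y)
        self.tree_ = build_clone_tree(X, y, self.roles_, epsilon=self.epsilon)
        return self
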