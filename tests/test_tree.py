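import numpy as np
import pytest

from metroutes.model import InconsistencyError, PairRelation, Role
from metroutes.simulate import SimulationConfig, simulate_patient
from metroutes.pipeline import RouteAnalyzer
from metroutes.tree import (
    CloneTreeBuilder,
    build_clone_tree,
    classify_cluster_roles,
    nested_ovals,
    pairwise_relation,
)

from .conftest import make_matrix, make_status
from .oracles import enumerate_valid_trees


# ---------------------------------------------------------------------------
# roles
# ---------------------------------------------------------------------------


def _roles(status_rows, lesions):
    return {
        r.cluster_id: r.role
        for r in classify_cluster_roles(make_status(status_rows, lesions))
    }


def test_trunk_branch_leaf_classification():
    roles = _roles(
        {
            "1": ["clonal", "clonal", "clonal"],
            "2": ["clonal", "clonal", "subclonal"],  # everywhere, not clonal
            "3": ["subclonal", "absent", "absent"],  # single lesion
        },
        ["T", "P1", "P2"],
    )
    assert roles == {"1": Role.TRUNK, "2": Role.BRANCH, "3": Role.LEAF}


def test_no_trunk_candidate_is_structural_error():
    with pytest.raises(InconsistencyError, match="no trunk"):
        _roles({"1": ["clonal", "subclonal"]}, ["T", "P1"])


def test_multiple_trunk_candidates_is_ambiguous_mrca():
    with pytest.raises(InconsistencyError, match="ambiguous MRCA"):
        _roles(
            {"1": ["clonal", "clonal"], "2": ["clonal", "clonal"]}, ["T", "P1"]
        )


# ---------------------------------------------------------------------------
# pairwise relations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((0.9, 0.8), (0.4, 0.3), PairRelation.LINEAR_A_OVER_B),
        ((0.6, 0.2), (0.3, 0.5), PairRelation.BRANCHING),
        ((0.6,), (0.6,), PairRelation.LINEAR_A_OVER_B),  # joint CCF above 1
        ((0.3, 0.3), (0.3, 0.3), PairRelation.UNDETERMINED),
    ],
)
def test_pairwise_relation_rules(a, b, expected):
    assert pairwise_relation(a, b) == expected


def test_pairwise_relation_mirror_consistency():
    rng = np.random.default_rng(7)
    for _ in range(50):
        a = rng.random(4)
        b = rng.random(4)
        assert pairwise_relation(a, b) == pairwise_relation(b, a).mirror()


# ---------------------------------------------------------------------------
# build_clone_tree
# ---------------------------------------------------------------------------


def _chain_instance():
    ccf = {"1": [1.0, 1.0], "2": [0.7, 0.7], "3": [0.4, 0.4]}
    status = {
        "1": ["clonal", "clonal"],
        "2": ["subclonal", "subclonal"],
        "3": ["subclonal", "subclonal"],
    }
    return make_matrix(ccf, ["L1", "L2"]), make_status(status, ["L1", "L2"])


def test_single_cluster_gives_single_node_tree():
    mat = make_matrix({"1": [0.95]}, ["T"])
    status = make_status({"1": ["clonal"]}, ["T"])
    tree = build_clone_tree(mat, status)
    assert tree.nodes == ["1"] and tree.parent == {}


def test_chain_ccfs_force_a_unique_chain():
    """CCFs 1.0 / 0.7 / 0.4 in every lesion admit exactly one tree: the
    chain (0.7 + 0.4 > 1 forces nesting, order forces direction)."""
    mat, status = _chain_instance()
    tree = build_clone_tree(mat, status)
    assert tree.parent == {"2": "1", "3": "2"}
    valid = enumerate_valid_trees(mat.ccf, status.status)
    assert valid == [{"2": "1", "3": "2"}]


def test_branching_pair_cannot_share_a_tight_ancestor():
    """Two reversed subclones whose joint CCF exceeds an ancestor's cannot
    both nest inside it; one attaches above."""
    lesions = ["L1", "L2"]
    mat = make_matrix(
        {"1": [1.0, 1.0], "A": [0.6, 0.6], "B": [0.38, 0.06], "C": [0.3, 0.55]},
        lesions,
    )
    status = make_status(
        {
            "1": ["clonal", "clonal"],
            "A": ["subclonal", "subclonal"],
            "B": ["subclonal", "subclonal"],
            "C": ["subclonal", "subclonal"],
        },
        lesions,
    )
    tree = build_clone_tree(mat, status)
    under_a = {c for c, p in tree.parent.items() if p == "A"}
    assert not {"B", "C"} <= under_a
    for parent_map in enumerate_valid_trees(mat.ccf, status.status):
        assert not (parent_map.get("B") == "A" and parent_map.get("C") == "A")


def test_build_is_deterministic(lymph_analysis):
    again = RouteAnalyzer().fit(
        __import__("metroutes.examples", fromlist=["x"]).lymphatic_reseeding_patient()
    )
    assert again.tree_.parent == lymph_analysis.tree_.parent


def test_nesting_invariant_holds_on_simulated_patients():
    """Child CCF never exceeds the parent's capacity (1 where clonal) by
    more than epsilon, in any lesion."""
    for seed in range(5):
        ds, _ = simulate_patient(SimulationConfig(noise="none", seed=seed))
        a = RouteAnalyzer().fit(ds)
        ccf, status = a.ccf_matrix_.ccf, a.clonality_.status
        for child, parent in a.tree_.parent.items():
            cap = np.where(
                status.loc[parent].to_numpy() == "clonal",
                1.0,
                ccf.loc[parent].to_numpy(),
            )
            assert (ccf.loc[child].to_numpy() <= cap + 0.05 + 1e-9).all()


def test_trunk_is_root_and_clonal_everywhere(lymph_analysis):
    tree = lymph_analysis.tree_
    assert tree.root == "1"
    assert (lymph_analysis.clonality_.status.loc["1"] == "clonal").all()


def test_builder_estimator_exposes_fitted_attributes():
    mat, status = _chain_instance()
    builder = CloneTreeBuilder(epsilon=0.05).fit(mat, status)
    assert builder.tree_.parent == {"2": "1", "3": "2"}
    assert {r.cluster_id: r.role for r in builder.roles_}["1"] is Role.TRUNK


# ---------------------------------------------------------------------------
# nested ovals
# ---------------------------------------------------------------------------


def test_nested_ovals_lists_containment_order():
    mat, status = _chain_instance()
    tree = build_clone_tree(mat, status)
    ovals = nested_ovals(tree, status, mat)
    assert [c for c, _ in ovals["L1"]] == ["1", "2", "3"]


def test_nested_ovals_flags_present_child_of_absent_parent():
    lesions = ["L1", "L2"]
    mat = make_matrix({"1": [1.0, 1.0], "2": [0.7, 0.0], "3": [0.4, 0.3]}, lesions)
    status = make_status(
        {
            "1": ["clonal", "clonal"],
            "2": ["subclonal", "absent"],
            "3": ["subclonal", "subclonal"],
        },
        lesions,
    )
    tree = build_clone_tree(mat, status)
    if tree.parent.get("3") == "2":
        with pytest.raises(InconsistencyError):
            nested_ovals(tree, status, mat)
    else:
        nested_ovals(tree, status, mat)  # consistent placement, no error


# ---------------------------------------------------------------------------
# oracle equivalence (small sample; the full family runs in acceptance)
# ---------------------------------------------------------------------------


def _random_instance(rng):
    """Random clone tree + compositions over <=4 lesions, as CCFs."""
    n_clusters = int(rng.integers(2, 6))
    n_lesions = int(rng.integers(1, 5))
    parent = {}
    nodes = ["1"]
    for i in range(2, n_clusters + 1):
        parent[str(i)] = nodes[int(rng.integers(0, len(nodes)))]
        nodes.append(str(i))
    lesions = [f"L{j}" for j in range(n_lesions)]
    ccf = {c: [] for c in nodes}
    for _ in lesions:
        frac = rng.dirichlet(np.ones(n_clusters))
        vals = {}
        for idx, c in enumerate(nodes):
            vals[c] = frac[idx]
        # cumulative CCF down the tree
        def total(c):
            return vals[c] + sum(total(d) for d, p in parent.items() if p == c)

        for c in nodes:
            ccf[c].append(round(min(1.0, total(c)), 3))
    for c in nodes:  # trunk clonal everywhere
        if c == "1":
            ccf[c] = [1.0] * n_lesions
    return ccf, lesions


def test_tree_agrees_with_enumeration_on_random_instances():
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(60):
        ccf, lesions = _random_instance(rng)
        mat = make_matrix(ccf, lesions)
        from metroutes.ccf import call_clonality

        status = call_clonality(mat)
        if not (status.status.loc["1"] == "clonal").all():
            continue
        if any((status.status.loc[c] == "absent").all() for c in mat.cluster_ids):
            continue  # degenerate cluster; the pipeline drops these upstream
        valid = enumerate_valid_trees(mat.ccf, status.status)
        try:
            tree = build_clone_tree(mat, status)
        except InconsistencyError:
            assert valid == []
            continue
        core = [c for c in tree.nodes if tree.roles.get(c) != "leaf"]
        core_parent = {c: p for c, p in tree.parent.items() if c in core}
        projected = [{c: p for c, p in v.items() if c in core} for v in valid]
        assert core_parent in projected
        uniq = {tuple(sorted(v.items())) for v in projected}
        if len(uniq) == 1:
            assert tuple(sorted(core_parent.items())) in uniq
        checked += 1
    assert checked >= 30
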