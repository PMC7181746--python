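import numpy as np
import pytest

from metroutes.model import CloneTree, InfeasibilityError, Route
from metroutes.pipeline import RouteAnalyzer
from metroutes.routes import (
    MetastaticMapBuilder,
    candidate_sources,
    color_route,
    infer_metastatic_map,
    seeding_clone_set,
)
from metroutes.simulate import SimulationConfig, simulate_patient

from .conftest import lesions_for
from .oracles import min_metastasis_routes


# ---------------------------------------------------------------------------
# seeding clone sets (on the lymphatic example patient)
# ---------------------------------------------------------------------------


def _seed_set(analysis, lesion_id):
    lesion = next(l for l in analysis.lesions_ if l.lesion_id == lesion_id)
    return seeding_clone_set(
        lesion, analysis.tree_, analysis.clonality_, analysis.ccf_matrix_
    )


def test_multiclonal_lesion_with_clonal_parent_clone(lymph_analysis):
    """A lesion where two clusters are clonal and two subclonal was founded
    by the parental clone plus both subclones jointly."""
    s = _seed_set(lymph_analysis, "P9")
    assert s.clones == ("2", "3", "6")
    assert s.classification == "multiclonal"


def test_all_clonal_chain_is_monoclonal_deepest(lymph_analysis):
    s = _seed_set(lymph_analysis, "I1")
    assert s.clones == ("4",)
    assert s.classification == "monoclonal"


def test_trunk_only_lesion_is_monoclonal_trunk():
    lesions = lesions_for({"T": "T", "P1": "P"})
    from .conftest import make_matrix, make_status

    mat = make_matrix({"1": [1.0, 1.0], "2": [0.4, 0.0]}, ["T", "P1"])
    status = make_status(
        {"1": ["clonal", "clonal"], "2": ["subclonal", "absent"]}, ["T", "P1"]
    )
    from metroutes.tree import build_clone_tree

    tree = build_clone_tree(mat, status)
    s = seeding_clone_set(lesions[1], tree, status, mat)
    assert s.clones == ("1",) and s.classification == "monoclonal"


# ---------------------------------------------------------------------------
# candidate sources
# ---------------------------------------------------------------------------


def test_private_subclone_restricts_candidates(lymph_analysis):
    """P7 needs the subclone private to P6/P7/P8; only P6 and P8 qualify."""
    cands = candidate_sources(
        _seed_set(lymph_analysis, "P7"),
        lymph_analysis.lesions_,
        lymph_analysis.clonality_,
        lymph_analysis.tree_,
        lymph_analysis.ccf_matrix_,
    )
    assert cands == ["P6", "P8"]


def test_layer_order_forbids_central_seeding_paracolic(lymph_analysis):
    cands = candidate_sources(
        _seed_set(lymph_analysis, "P1"),
        lymph_analysis.lesions_,
        lymph_analysis.clonality_,
        lymph_analysis.tree_,
        lymph_analysis.ccf_matrix_,
    )
    assert "C1" not in cands  # central node can never seed a paracolic one
    assert "T" in cands


def test_unsourceable_seeding_set_raises(liver_analysis):
    cands_fail = _seed_set(liver_analysis, "LM1")
    lesions = [l for l in liver_analysis.lesions_ if l.lesion_id != "LM2"]
    with pytest.raises(InfeasibilityError, match="LM1"):
        candidate_sources(
            cands_fail,
            lesions,
            liver_analysis.clonality_,
            liver_analysis.tree_,
            liver_analysis.ccf_matrix_,
        )


# ---------------------------------------------------------------------------
# metastatic maps on the example patients
# ---------------------------------------------------------------------------


def test_lymphatic_example_full_map(lymph_analysis):
    mmap = lymph_analysis.map_
    pairs = {(r.source_lesion_id, r.target_lesion_id) for r in mmap.routes}
    assert ("P6", "P7") in pairs and ("P6", "P8") in pairs
    for target in ("P1", "P2", "P5", "P6", "P9", "I1", "I2", "C1"):
        assert ("T", target) in pairs
    assert len(mmap.routes) == 10
    assert mmap.ambiguity_groups == []


def test_liver_example_conventional_direction(liver_analysis):
    mmap = liver_analysis.map_
    pairs = {(r.source_lesion_id, r.target_lesion_id) for r in mmap.routes}
    assert pairs == {("T", "LM3"), ("T", "LM2"), ("LM2", "LM1")}
    assert mmap.ambiguity_groups == [("LM1", "LM2")]
    assert all(r.classification == "monoclonal" for r in mmap.routes)


def test_head_route_reports_transported_clones(lymph_analysis):
    """The externally seeded group head's route carries the reduced clone
    set (its group-private subclone arose in situ)."""
    route = lymph_analysis.map_.route_to("P6")
    assert route.source_lesion_id == "T"
    assert "7" not in route.seeding_clones
    assert set(route.seeding_clones) == {"2", "3", "4"}


def test_map_builder_estimator(liver_analysis):
    builder = MetastaticMapBuilder(patient_id="x").fit(
        liver_analysis.clonality_,
        tree=liver_analysis.tree_,
        lesions=liver_analysis.lesions_,
        matrix=liver_analysis.ccf_matrix_,
    )
    assert {r.target_lesion_id for r in builder.routes_} == {"LM1", "LM2", "LM3"}
    assert builder.seeding_sets_["LM3"].clones == ("4",)


# ---------------------------------------------------------------------------
# color
# ---------------------------------------------------------------------------


def test_color_is_most_derived_clone():
    tree = CloneTree(parent={"2": "1", "3": "2"}, root="1")
    route = Route("T", "P1", ("2", "3"), "multiclonal")
    assert color_route(route, tree) == "3"


def test_color_tie_breaks_to_lower_cluster_id():
    tree = CloneTree(parent={"B": "1", "C": "1"}, root="1")
    route = Route("T", "P1", ("B", "C"), "multiclonal")
    assert color_route(route, tree) == "B"


def test_singleton_color_is_that_clone():
    tree = CloneTree(parent={"2": "1"}, root="1")
    assert color_route(Route("T", "P1", ("2",), "monoclonal"), tree) == "2"


# ---------------------------------------------------------------------------
# structural invariants + parsimony (sampled; the full oracle sweep is in
# the acceptance suite)
# ---------------------------------------------------------------------------


def _layer(lesions, lid):
    return next(l.layer for l in lesions if l.lesion_id == lid)


def test_maps_are_rooted_trees_without_layer_violations():
    from metroutes.model import LAYER_RANK

    for seed in range(12):
        ds, _ = simulate_patient(SimulationConfig(noise="none", seed=900 + seed))
        a = RouteAnalyzer().fit(ds)
        a.map_.validate(ds.lesions)  # in-degree 1, rooted at primary, acyclic
        for r in a.map_.routes:
            src = _layer(ds.lesions, r.source_lesion_id)
            tgt = _layer(ds.lesions, r.target_lesion_id)
            if tgt != "LM":
                assert src != "LM"
                assert LAYER_RANK[src] <= LAYER_RANK[tgt]


def test_parsimony_matches_exhaustive_minimum_on_small_instances():
    from metroutes.routes import _Inference

    cfg_layers = {"P": 2, "I": 1, "C": 1, "LM": 1}
    compared = 0
    for seed in range(40):
        ds, _ = simulate_patient(
            SimulationConfig(
                noise="none", seed=500 + seed, n_lesions_per_layer=cfg_layers
            )
        )
        a = RouteAnalyzer().fit(ds)
        inf = _Inference(ds.lesions, a.tree_, a.clonality_, a.ccf_matrix_)
        best = min_metastasis_routes(inf.cands, "T")
        if best is None:
            continue  # only resolvable via in-situ clone masking
        achieved = sum(
            1 for r in a.map_.routes if r.source_lesion_id != "T"
        )
        assert achieved == best
        compared += 1
    assert compared >= 10
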