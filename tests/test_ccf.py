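import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from metroutes.ccf import (
    ClonalityCaller,
    ClusterFilter,
    call_clonality,
    ccf_from_counts,
    cluster_lesion_ccf,
    filter_clusters,
    merge_ccf,
)
from metroutes.model import (
    ContractError,
    Lesion,
    MutationCall,
    PatientDataset,
    ThresholdConfig,
)

from .conftest import make_matrix


# ---------------------------------------------------------------------------
# ccf_from_counts
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "alt, ref, purity, cn, mult, expected",
    [
        (50, 50, 1.0, 2, 1, 1.0),  # diploid clonal heterozygous
        (25, 75, 1.0, 2, 1, 0.5),
        (30, 70, 0.6, 2, 1, 1.0),  # 0.3 * (1.2 + 0.8) / 0.6
    ],
)
def test_ccf_from_counts_known_values(alt, ref, purity, cn, mult, expected):
    assert ccf_from_counts(alt, ref, purity, cn, mult) == pytest.approx(expected)


def test_ccf_from_counts_rejects_zero_reads():
    with pytest.raises(ContractError):
        ccf_from_counts(0, 0, 0.7)


def test_ccf_from_counts_clips_to_upper_bound():
    assert ccf_from_counts(100, 0, 0.1, 2, 1) == 1.5


# ---------------------------------------------------------------------------
# merge_ccf
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ccfs, depths, expected",
    [
        ((0.5, 0.5), (100, 200), 0.5),  # constant input
        ((0.8, 0.4), (100, 300), 0.5),  # (80 + 120) / 400
        ((1.2, 1.0), (50, 50), 1.0),  # cap branch
    ],
)
def test_merge_ccf_known_values(ccfs, depths, expected):
    assert merge_ccf(ccfs, depths) == pytest.approx(expected)


@pytest.mark.parametrize(
    "ccfs, depths",
    [((), ()), ((0.5,), (100, 200)), ((0.5, 0.5), (100, 0))],
)
def test_merge_ccf_contract_errors(ccfs, depths):
    with pytest.raises(ContractError):
        merge_ccf(ccfs, depths)


ccf_lists = st.lists(st.floats(0, 1.5), min_size=1, max_size=6)


@given(data=st.data())
@settings(max_examples=200, deadline=None)
def test_merge_ccf_range_and_permutation_invariance(data):
    ccfs = data.draw(ccf_lists)
    depths = data.draw(
        st.lists(st.integers(1, 1000), min_size=len(ccfs), max_size=len(ccfs))
    )
    merged = merge_ccf(ccfs, depths)
    assert 0.0 <= merged <= 1.0
    perm = data.draw(st.permutations(list(range(len(ccfs)))))
    assert merge_ccf([ccfs[i] for i in perm], [depths[i] for i in perm]) == pytest.approx(
        merged
    )


@given(
    c=st.floats(0, 1),
    depths=st.lists(st.integers(1, 1000), min_size=1, max_size=5),
)
@settings(max_examples=100, deadline=None)
def test_merge_ccf_homogeneity(c, depths):
    """All regions sharing CCF c <= 1 merge to exactly c."""
    assert merge_ccf([c] * len(depths), depths) == pytest.approx(c)


@given(
    ccfs=st.lists(st.floats(0, 1), min_size=2, max_size=5),
    depth=st.integers(1, 1000),
)
@settings(max_examples=100, deadline=None)
def test_merge_ccf_equals_mean_at_equal_depths(ccfs, depth):
    assert merge_ccf(ccfs, [depth] * len(ccfs)) == pytest.approx(
        min(1.0, float(np.mean(ccfs)))
    )


# ---------------------------------------------------------------------------
# cluster_lesion_ccf
# ---------------------------------------------------------------------------


def _dataset(lesions, calls):
    return PatientDataset("pt", lesions=lesions, mutations=calls)


def test_cluster_mean_over_single_region_lesion():
    ds = _dataset(
        [Lesion("T", "T", ("s1",))],
        [
            MutationCall("m1", "s1", 0.9, 100, "1"),
            MutationCall("m2", "s1", 0.7, 100, "1"),
        ],
    )
    mat = cluster_lesion_ccf(ds)
    assert mat.ccf.at["1", "T"] == pytest.approx(0.8)
    assert mat.n_mutations["1"] == 2


def test_missing_observation_imputed_as_zero_then_merged():
    """One mutation seen at CCF 1.0 in one region and absent in the other
    (equal depths) merges to 0.5."""
    ds = _dataset(
        [Lesion("T", "T", ("r1", "r2"))],
        [
            MutationCall("m1", "r1", 1.0, 100, "1"),
            # m1 unobserved in r2; r2's median depth comes from m2
            MutationCall("m2", "r2", 0.2, 100, "2"),
            MutationCall("m2", "r1", 0.2, 100, "2"),
        ],
    )
    mat = cluster_lesion_ccf(ds)
    assert mat.ccf.at["1", "T"] == pytest.approx(0.5)


def test_all_ccf_one_everywhere_stays_one():
    ds = _dataset(
        [Lesion("T", "T", ("r1", "r2")), Lesion("P1", "P", ("p1",))],
        [
            MutationCall("m1", s, 1.0, d, "1")
            for s, d in [("r1", 100), ("r2", 300), ("p1", 150)]
        ],
    )
    mat = cluster_lesion_ccf(ds)
    assert (mat.ccf.to_numpy() == 1.0).all()


def test_chromosome_sets_parsed_from_coordinate_ids():
    ds = _dataset(
        [Lesion("T", "T", ("s1",))],
        [
            MutationCall("chr1:5:A:T", "s1", 0.5, 100, "1"),
            MutationCall("chr2:9:G:C", "s1", 0.5, 100, "1"),
        ],
    )
    mat = cluster_lesion_ccf(ds)
    assert mat.chromosomes["1"] == frozenset({"chr1", "chr2"})


# ---------------------------------------------------------------------------
# call_clonality / filter_clusters
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value, expected",
    [(0.90, "clonal"), (0.05, "absent"), (0.85, "subclonal"), (0.50, "subclonal"),
     (0.04, "absent"), (0.851, "clonal")],
)
def test_clonality_thresholds_and_boundaries(value, expected):
    mat = make_matrix({"1": [value]}, ["T"])
    status = call_clonality(mat)
    assert status.status.at["1", "T"] == expected


@given(lo=st.floats(0, 1), delta=st.floats(0, 1))
@settings(max_examples=100, deadline=None)
def test_clonality_is_monotone_in_ccf(lo, delta):
    hi = min(1.0, lo + delta)
    order = {"absent": 0, "subclonal": 1, "clonal": 2}
    s_lo = call_clonality(make_matrix({"1": [lo]}, ["T"])).status.at["1", "T"]
    s_hi = call_clonality(make_matrix({"1": [hi]}, ["T"])).status.at["1", "T"]
    assert order[s_hi] >= order[s_lo]


def test_filter_drops_small_clusters_keeps_boundary():
    mat = make_matrix(
        {"1": [0.9], "2": [0.5], "3": [0.4]},
        ["T"],
        n_mutations={"1": 100, "2": 5, "3": 4},
    )
    out = filter_clusters(mat)
    assert out.cluster_ids == ["1", "2"]  # 4 substitutions dropped, 5 kept
    # pure selection: retained values untouched
    assert out.ccf.loc["1"].equals(mat.ccf.loc["1"])


def test_filter_by_chromosome_span_when_enabled():
    mat = make_matrix({"1": [0.9], "2": [0.5]}, ["T"],
                      n_mutations={"1": 10, "2": 10})
    mat.chromosomes = {"1": frozenset({"chr1", "chr2"}), "2": frozenset({"chr3"})}
    out = filter_clusters(mat, ThresholdConfig(min_chromosomes=2))
    assert out.cluster_ids == ["1"]


def test_filter_everything_dropped_is_an_error():
    mat = make_matrix({"1": [0.9]}, ["T"], n_mutations={"1": 2})
    with pytest.raises(ContractError):
        filter_clusters(mat)


# ---------------------------------------------------------------------------
# estimator wrappers
# ---------------------------------------------------------------------------


def test_estimators_compose_with_sklearn_cloning():
    caller = ClonalityCaller(clonal_ccf=0.9)
    assert clone(caller).get_params()["clonal_ccf"] == 0.9
    mat = make_matrix({"1": [0.95, 0.3]}, ["T", "P1"])
    status = caller.fit(mat).transform(mat)
    assert status.status.at["1", "T"] == "clonal"
    assert status.status.at["1", "P1"] == "subclonal"

    filt = ClusterFilter(min_cluster_size=11)
    mat2 = make_matrix({"1": [0.9], "2": [0.5]}, ["T"],
                       n_mutations={"1": 20, "2": 10})
    assert filt.fit(mat2).transform(mat2).cluster_ids == ["1"]
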