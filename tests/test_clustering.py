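"""Clustering: profiles, distances, oracle agreement, cuts, Newick export."""

import dendropy
import numpy as np
import pytest

from acumine.clustering import (
    agglomerate,
    build_profiles,
    cut,
    distance_matrix,
    partition_table,
    to_newick,
)
from conftest import make_db, naive_agglomerate_heights


def test_profiles_threshold_and_order(fixture_db):
    profiles = build_profiles(fixture_db, min_count=9)
    assert [p.item for p in profiles] == ["ST36", "RN12", "SP6", "PC6", "RN4", "DU20", "HT7"]
    assert all(p.count == p.vector.sum() for p in profiles)
    everything = build_profiles(fixture_db, min_count=1)
    assert len(everything) == 38
    with pytest.raises(ValueError):
        build_profiles(fixture_db, min_count=100)


def test_fixture_threshold_selects_21_cluster_items(fixture_db):
    profiles = build_profiles(fixture_db, min_count=2)
    assert len(profiles) == 21


def test_identical_profiles_distance_zero():
    db = make_db([{"AA1", "BB1"}, {"AA1", "BB1"}, {"CC1"}])
    profiles = build_profiles(db)
    d = distance_matrix(profiles, "squared_euclidean")
    idx = {p.item: i for i, p in enumerate(profiles)}
    assert d[idx["AA1"], idx["BB1"]] == 0.0
    assert (np.diag(d) == 0).all()


def test_disjoint_items_forced_distances():
    # a in 3 transactions, b in 4 disjoint ones
    db = make_db([{"AA1"}] * 3 + [{"BB1"}] * 4 + [{"CC1"}] * 2)
    profiles = [p for p in build_profiles(db) if p.item in ("AA1", "BB1")]
    assert distance_matrix(profiles, "squared_euclidean")[0, 1] == 7.0
    assert distance_matrix(profiles, "jaccard")[0, 1] == 1.0


def test_contained_item_distance_from_counts(fixture_db):
    # HT7's 9 transactions all contain RN12 (count 22): sq-euclid = 22 - 9
    profiles = {p.item: p for p in build_profiles(fixture_db, min_count=9)}
    d = distance_matrix([profiles["HT7"], profiles["RN12"]], "squared_euclidean")
    assert d[0, 1] == 13.0


def test_three_point_merge_order():
    dist = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
    dendro = agglomerate(dist, ["AA1", "BB1", "CC1"])
    assert dendro.merges[0][:2] == (0, 1)
    assert dendro.merges[0][2] == 1.0


def test_two_profiles_single_merge():
    dist = np.array([[0.0, 2.5], [2.5, 0.0]])
    dendro = agglomerate(dist, ["AA1", "BB1"])
    assert len(dendro.merges) == 1
    assert dendro.merges[0][2] == 2.5


@pytest.mark.parametrize("linkage", ["average", "complete", "single"])
@pytest.mark.parametrize("seed", range(4))
def test_heights_match_naive_oracle(linkage, seed):
    """Merge heights equal a from-scratch O(n^3) agglomeration, all linkages."""
    rng = np.random.default_rng(500 + seed)
    n = int(rng.integers(4, 13))
    raw = rng.uniform(0.1, 10.0, size=(n, n))
    dist = (raw + raw.T) / 2
    np.fill_diagonal(dist, 0.0)
    dendro = agglomerate(dist, [f"AA{i + 1}" for i in range(n)], linkage)
    assert np.allclose(dendro.heights, naive_agglomerate_heights(dist, linkage))


@pytest.mark.parametrize("linkage", ["average", "complete"])
def test_heights_monotone_for_monotone_linkages(fixture_db, linkage):
    profiles = build_profiles(fixture_db, min_count=2)
    dendro = agglomerate(
        distance_matrix(profiles), [p.item for p in profiles], linkage
    )
    heights = dendro.heights
    assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


def test_cut_properties(fixture_db):
    profiles = build_profiles(fixture_db, min_count=2)
    dendro = agglomerate(distance_matrix(profiles), [p.item for p in profiles])
    n = len(profiles)
    for k in (1, 3, 6, n):
        part = cut(dendro, k)
        assert len(part) == k
        assert sorted(i for c in part.values() for i in c) == sorted(
            p.item for p in profiles
        )
    assert all(len(c) == 1 for c in cut(dendro, n).values())
    assert len(cut(dendro, 1)[1]) == n
    with pytest.raises(ValueError):
        cut(dendro, 0)
    with pytest.raises(ValueError):
        cut(dendro, n + 1)


def test_cut_refinement(fixture_db):
    """Every cluster at k+1 sits inside a single cluster at k."""
    profiles = build_profiles(fixture_db, min_count=2)
    dendro = agglomerate(distance_matrix(profiles), [p.item for p in profiles])
    for k in range(1, 10):
        coarse = cut(dendro, k)
        fine = cut(dendro, k + 1)
        parents = {
            item: cid for cid, items in coarse.items() for item in items
        }
        for items in fine.values():
            assert len({parents[i] for i in items}) == 1


def test_newick_round_trips_with_all_leaves(fixture_db):
    profiles = build_profiles(fixture_db, min_count=2)
    dendro = agglomerate(distance_matrix(profiles), [p.item for p in profiles])
    tree = dendropy.Tree.get(data=to_newick(dendro), schema="newick")
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert taxa == {p.item for p in profiles}


def test_partition_table_layout(fixture_db):
    profiles = build_profiles(fixture_db, min_count=9)
    dendro = agglomerate(distance_matrix(profiles), [p.item for p in profiles])
    frame = partition_table(cut(dendro, 3))
    assert list(frame.columns) == ["item", "cluster_id"]
    assert len(frame) == len(profiles)
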