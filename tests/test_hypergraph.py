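from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperfix import (
    Hypergraph,
    degree_size_profile,
    is_connected,
    make_model_hypergraph,
    one_mode_projection,
    random_hypergraph,
    randomize_hypergraph,
    read_hyperedge_list,
    write_hyperedge_list,
)


class TestConstruction:
    def test_repeated_node_in_hyperedge_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            Hypergraph(3, ((0, 1, 1),))

    def test_node_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            Hypergraph(3, ((0, 1, 3),))

    def test_duplicate_hyperedges_are_kept(self):
        H = Hypergraph(2, ((0, 1), (0, 1)))
        assert H.M == 2
        assert tuple(H.degrees()) == (2, 2)

    def test_size_one_hyperedge_warns(self):
        with pytest.warns(UserWarning, match="size-1"):
            Hypergraph(2, ((0,), (0, 1)))


class TestGenerators:
    @pytest.mark.parametrize(
        "family,N,expected_M",
        [
            ("complete3", 4, 4),
            ("complete3", 7, comb(7, 3)),
            ("cyclic3", 8, 8),
            ("star3", 5, comb(4, 2)),
            ("complete_graph", 5, comb(5, 2)),
        ],
    )
    def test_hyperedge_counts(self, family, N, expected_M):
        H = make_model_hypergraph(family, N)
        assert H.M == expected_M
        assert is_connected(H)

    def test_complete3_n4_is_all_triples(self):
        H = make_model_hypergraph("complete3", 4)
        assert set(H.hyperedges) == {(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)}

    def test_cyclic3_n8_is_3_regular(self):
        H = make_model_hypergraph("cyclic3", 8)
        assert all(d == 3 for d in H.degrees())
        assert all(len(e) == 3 for e in H.hyperedges)

    def test_star3_hub_in_every_hyperedge(self):
        H = make_model_hypergraph("star3", 6)
        assert all(0 in e for e in H.hyperedges)
        deg = H.degrees()
        # hub sits in all leaf pairs; each leaf pairs with the N-2 other leaves
        assert deg[0] == comb(5, 2)
        assert all(d == 4 for d in deg[1:])

    @pytest.mark.parametrize(
        "family,N",
        [("complete3", 2), ("cyclic3", 3), ("star3", 3), ("complete_graph", 1)],
    )
    def test_family_minimum_sizes(self, family, N):
        with pytest.raises(ValueError):
            make_model_hypergraph(family, N)


class TestConnectivity:
    def test_two_disjoint_edges_disconnected(self):
        assert not is_connected(Hypergraph(4, ((0, 1), (2, 3))))

    def test_single_hyperedge_connected(self):
        assert is_connected(Hypergraph(3, ((0, 1, 2),)))

    def test_isolated_node_disconnects(self):
        assert not is_connected(Hypergraph(3, ((0, 1),)))


class TestProfile:
    def test_star3_n4_profile(self):
        prof = degree_size_profile(make_model_hypergraph("star3", 4))
        assert prof.degrees == (3, 2, 2, 2)
        assert prof.sizes == (3, 3, 3)
        assert sum(prof.degrees) == sum(prof.sizes)

    def test_duplicated_edge_counts_twice(self):
        prof = degree_size_profile(Hypergraph(2, ((0, 1), (0, 1))))
        assert prof.degrees == (2, 2)
        assert prof.sizes == (2, 2)


class TestProjection:
    def test_weighted_projection_of_cyclic3_multiplicities(self):
        H = make_model_hypergraph("cyclic3", 8)
        P = one_mode_projection(H, weighted=True)
        counts = P.edge_multiset()
        # node 0 shares two hyperedges with each ring neighbour, one with
        # each next-nearest neighbour
        assert counts[(0, 1)] == 2 and counts[(0, 7)] == 2
        assert counts[(0, 2)] == 1 and counts[(0, 6)] == 1
        assert (0, 3) not in counts
        assert all(d == 6 for d in P.degrees())

    def test_unweighted_projection_of_star3_is_complete_graph(self):
        P = one_mode_projection(make_model_hypergraph("star3", 6), weighted=False)
        assert set(P.hyperedges) == set(
            tuple(c) for c in combinations(range(6), 2)
        )
        assert P.M == comb(6, 2)

    def test_weighted_projection_of_complete3_is_regular(self):
        P = one_mode_projection(make_model_hypergraph("complete3", 4), weighted=True)
        assert all(c == 2 for c in P.edge_multiset().values())
        deg = P.degrees()
        assert all(d == deg[0] for d in deg)


class TestRandomize:
    def test_zero_swaps_is_identity(self):
        H = make_model_hypergraph("cyclic3", 8)
        assert randomize_hypergraph(H, n_swaps=0, seed=1) == H

    def test_single_hyperedge_unchanged(self):
        H = Hypergraph(3, ((0, 1, 2),))
        assert randomize_hypergraph(H, n_swaps=10, seed=0) == H

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_profile_preserved(self, seed):
        H = random_hypergraph(12, 18, sizes=(2, 3, 4, 5), seed=seed)
        HR = randomize_hypergraph(H, seed=seed)
        assert degree_size_profile(HR) == degree_size_profile(H)
        assert HR != H  # swaps actually happened for this size

    def test_reproducible(self):
        H = random_hypergraph(10, 14, seed=5)
        assert randomize_hypergraph(H, seed=9) == randomize_hypergraph(H, seed=9)


class TestFileIO:
    def test_reads_labelled_hyperedges(self, tmp_path):
        p = tmp_path / "toy.hyperedges"
        p.write_text("1 2 3\n3 4 5\n4 5 6\n6 1 2\n")
        H = read_hyperedge_list(p)
        assert H.N == 6
        assert H.M == 4
        assert H.labels == ("1", "2", "3", "4", "5", "6")

    def test_comments_and_blanks_skipped(self, tmp_path):
        p = tmp_path / "c.hyperedges"
        p.write_text("# header\n\na b c\n")
        assert read_hyperedge_list(p).N == 3

    def test_duplicate_hyperedge_lines_kept(self, tmp_path):
        p = tmp_path / "d.hyperedges"
        p.write_text("a b\na b\n")
        H = read_hyperedge_list(p)
        assert H.N == 2 and H.M == 2
        assert tuple(H.degrees()) == (2, 2)

    def test_repeated_label_in_line_raises_with_lineno(self, tmp_path):
        p = tmp_path / "bad.hyperedges"
        p.write_text("a b\nc c d\n")
        with pytest.raises(ValueError, match=":2"):
            read_hyperedge_list(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.hyperedges"
        p.write_text("# nothing\n")
        with pytest.raises(ValueError, match="no hyperedges"):
            read_hyperedge_list(p)

    @staticmethod
    def _labelled_multiset(H):
        labels = H.labels or tuple(str(v) for v in range(H.N))
        out = {}
        for e in H.hyperedges:
            key = frozenset(labels[v] for v in e)
            out[key] = out.get(key, 0) + 1
        return out

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip(self, tmp_path, seed):
        # reading assigns indices by first appearance, so the round trip is
        # the identity on the labelled structure (and exactly idempotent)
        H = random_hypergraph(9, 12, sizes=(2, 3, 4), seed=seed)
        p, p2 = tmp_path / "rt.hyperedges", tmp_path / "rt2.hyperedges"
        write_hyperedge_list(H, p)
        H2 = read_hyperedge_list(p)
        assert H2.N == H.N
        assert self._labelled_multiset(H2) == self._labelled_multiset(H)
        write_hyperedge_list(H2, p2)
        assert read_hyperedge_list(p2) == H2


class TestRandomHypergraph:
    def test_contract(self):
        H = random_hypergraph(6, 8, sizes=(2, 3, 4), seed=0)
        assert H.N == 6 and H.M == 8 and is_connected(H)

    def test_minimal_case(self):
        H = random_hypergraph(2, 1, sizes=(2,), seed=0)
        assert H.hyperedges == ((0, 1),)

    def test_same_seed_same_hypergraph(self):
        assert random_hypergraph(8, 10, seed=3) == random_hypergraph(8, 10, seed=3)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_generator_invariants(self, seed):
        H = random_hypergraph(7, 9, sizes=(2, 3), seed=seed)
        assert is_connected(H)
        assert all(2 <= len(e) <= 3 for e in H.hyperedges)
        prof = degree_size_profile(H)
        assert sum(prof.degrees) == sum(prof.sizes)
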