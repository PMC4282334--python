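import numpy as np
import pytest

from mmnet import (
    DirectedNetwork,
    ego_alters,
    enumerate_maximal_cliques,
    network_descriptives,
    parse_adjacency_list,
    parse_edge_list,
    symmetrize,
)
from oracles import brute_force_maximal_cliques


def net_from_rows(rows, ids=None):
    D = np.asarray(rows)
    ids = tuple(ids) if ids else tuple(range(D.shape[0]))
    return DirectedNetwork(ids, D)


class TestParseAdjacencyList:
    def test_basic_construction(self):
        net = parse_adjacency_list([("A", ["B", "C"]), ("B", []), ("C", [])])
        assert net.node_ids == ("A", "B", "C")
        assert net.D.tolist() == [[0, 1, 1], [0, 0, 0], [0, 0, 0]]

    def test_self_nominations_removed(self):
        net = parse_adjacency_list([("A", ["A", "B"]), ("B", [])])
        assert net.D[0, 0] == 0 and net.D[0, 1] == 1

    def test_out_of_sample_alters_dropped_creating_isolates(self):
        net = parse_adjacency_list([("A", ["Z"]), ("B", ["A"])])
        i, j = net.index("A"), net.index("B")
        assert net.D[i].sum() == 0  # A becomes a sample isolate
        assert net.D[j, i] == 1

    def test_unknown_alter_raises_on_flag(self):
        with pytest.raises(ValueError, match="unknown alter"):
            parse_adjacency_list([("A", ["Z"])], on_unknown="error")

    def test_duplicate_ego_named_in_error(self):
        with pytest.raises(ValueError, match="'A'"):
            parse_adjacency_list([("A", ["B"]), ("A", [])])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            parse_adjacency_list([])

    def test_roster_gives_zero_rows_to_non_egos(self):
        net = parse_adjacency_list([("A", ["C"])], node_ids=["A", "B", "C"])
        assert net.node_ids == ("A", "B", "C")
        assert net.D[net.index("B")].sum() == 0
        assert net.D[net.index("A"), net.index("C")] == 1

    def test_edge_list_equivalent(self):
        n1 = parse_edge_list([("A", "B"), ("A", "C"), ("B", "A")])
        n2 = parse_adjacency_list([("A", ["B", "C"]), ("B", ["A"]), ("C", [])])
        assert n1.node_ids == n2.node_ids
        assert np.array_equal(n1.D, n2.D)


class TestDirectedNetworkInvariants:
    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DirectedNetwork((0, 1), np.eye(2, dtype=int))

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            DirectedNetwork((0, 1), np.array([[0, 2], [0, 0]]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            DirectedNetwork(("A", "A"), np.zeros((2, 2), int))


class TestSymmetrize:
    def test_one_way_nomination_becomes_tie(self):
        net = net_from_rows([[0, 1], [0, 0]])
        u = symmetrize(net)
        assert u.Dstar[0, 1] == u.Dstar[1, 0] == 1

    def test_zero_matrix_unchanged(self):
        u = symmetrize(net_from_rows(np.zeros((4, 4), int)))
        assert u.Dstar.sum() == 0

    def test_idempotent_on_symmetric(self, rng):
        for _ in range(10):
            D = (rng.random((8, 8)) < 0.3).astype(int)
            np.fill_diagonal(D, 0)
            u = symmetrize(net_from_rows(D))
            u2 = symmetrize(net_from_rows(u.Dstar))
            assert np.array_equal(u.Dstar, u2.Dstar)

    def test_monotone_density_never_decreases(self, rng):
        for _ in range(10):
            D = (rng.random((8, 8)) < 0.2).astype(int)
            np.fill_diagonal(D, 0)
            u1 = symmetrize(net_from_rows(D))
            # add one edge
            zeros = np.argwhere((D == 0) & ~np.eye(8, dtype=bool))
            i, j = zeros[rng.integers(len(zeros))]
            D2 = D.copy()
            D2[i, j] = 1
            u2 = symmetrize(net_from_rows(D2))
            assert (u2.Dstar >= u1.Dstar).all()


class TestEgoAlters:
    def test_alters_are_nonzero_row_entries(self):
        net = net_from_rows([[0, 1, 0, 1]] + [[0] * 4] * 3)
        assert ego_alters(net, 0) == (1, 3)

    def test_isolate_has_no_alters(self):
        net = net_from_rows(np.zeros((3, 3), int))
        assert ego_alters(net, 1) == ()

    def test_unknown_id_raises(self):
        net = net_from_rows(np.zeros((2, 2), int))
        with pytest.raises(KeyError):
            ego_alters(net, "nope")


class TestMaximalCliques:
    def test_triangle_is_single_clique(self):
        A = np.ones((3, 3), int) - np.eye(3, dtype=int)
        cs = enumerate_maximal_cliques(symmetrize(net_from_rows(np.triu(A))), 3)
        assert cs.cliques == ((0, 1, 2),)

    def test_path_has_no_triangle(self):
        D = np.zeros((4, 4), int)
        for i in range(3):
            D[i, i + 1] = 1
        cs = enumerate_maximal_cliques(symmetrize(net_from_rows(D)), 3)
        assert cs.cliques == ()
        cs2 = enumerate_maximal_cliques(symmetrize(net_from_rows(D)), 2)
        assert cs2.cliques == ((0, 1), (1, 2), (2, 3))

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            enumerate_maximal_cliques(symmetrize(net_from_rows(np.zeros((2, 2), int))), 1)

    @pytest.mark.parametrize("min_size", [2, 3])
    def test_matches_brute_force_on_random_graphs(self, rng, min_size):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            A = (rng.random((n, n)) < 0.4).astype(int)
            A = np.maximum(A, A.T)
            np.fill_diagonal(A, 0)
            unet = symmetrize(net_from_rows(A))
            got = enumerate_maximal_cliques(unet, min_size).cliques
            assert list(got) == brute_force_maximal_cliques(A, min_size)

    def test_disjoint_union_equals_union_of_components(self, rng):
        # parse -> symmetrize -> enumerate on a disjoint union of two graphs
        def random_block(n):
            A = (rng.random((n, n)) < 0.5).astype(int)
            np.fill_diagonal(A, 0)
            return A

        A, B = random_block(6), random_block(5)
        blocks = np.zeros((11, 11), int)
        blocks[:6, :6], blocks[6:, 6:] = A, B
        whole = enumerate_maximal_cliques(symmetrize(net_from_rows(blocks)), 2)
        part_a = enumerate_maximal_cliques(symmetrize(net_from_rows(A)), 2)
        part_b = enumerate_maximal_cliques(
            symmetrize(net_from_rows(B, ids=range(6, 11))), 2
        )
        assert set(whole.cliques) == set(part_a.cliques) | set(part_b.cliques)

    def test_canonical_ordering_deterministic(self, rng):
        A = (rng.random((10, 10)) < 0.4).astype(int)
        np.fill_diagonal(A, 0)
        unet = symmetrize(net_from_rows(np.maximum(A, A.T)))
        c1 = enumerate_maximal_cliques(unet, 2)
        c2 = enumerate_maximal_cliques(unet, 2)
        assert c1.cliques == c2.cliques == tuple(sorted(c1.cliques))


class TestNetworkDescriptives:
    def test_star_graph(self):
        D = np.zeros((4, 4), int)
        D[0, 1:] = 1
        s = network_descriptives(net_from_rows(D))
        assert s.n_isolates == 3
        assert s.isolate_fraction == pytest.approx(0.75)
        assert s.mean_egonet_size_nonisolate == pytest.approx(3.0)

    def test_empty_network_all_isolates(self):
        s = network_descriptives(net_from_rows(np.zeros((5, 5), int)))
        assert s.n_isolates == 5

    def test_clique_counts_match_direct_recount(self, rng):
        A = (rng.random((12, 12)) < 0.35).astype(int)
        np.fill_diagonal(A, 0)
        net = net_from_rows(np.maximum(A, A.T))
        unet = symmetrize(net)
        cs = enumerate_maximal_cliques(unet, 2)
        s = network_descriptives(net, unet, {"cliq": cs})
        recount = [sum(v in c for c in cs.cliques) for v in net.node_ids]
        assert s.clique_membership_counts["cliq"].tolist() == recount
        assert s.max_memberships["cliq"] == max(recount)
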