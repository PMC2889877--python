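"""Binary-matrix powers and order-k enumeration against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from stpnet.errors import LookupNodeError, StpnetError, ValidationError
from stpnet.matrix import (
    build_matrix,
    hub_tables,
    matrix_power,
    order_k_partners,
    order_report,
    second_order_intermediates,
    third_order_intermediates,
)
from stpnet.network import AnnotatedNetwork

from conftest import make_network, random_gnp


# -- independent oracles ----------------------------------------------


def walk_counts_oracle(B, k: int) -> np.ndarray:
    """Exhaustive DFS enumeration of length-k walks between all node pairs."""
    n = B.n
    counts = np.zeros((n, n), dtype=int)
    adj = [list(np.flatnonzero(B.A[i])) for i in range(n)]

    def extend(start: int, cur: int, depth: int):
        if depth == k:
            counts[start, cur] += 1
            return
        for nxt in adj[cur]:
            extend(start, nxt, depth + 1)

    for s in range(n):
        extend(s, s, 0)
    return counts


def simple_paths_oracle(B, i: str, j: str, length: int) -> set:
    """Intermediate tuples of all simple paths with `length` edges from i to j.

    No repeated vertices, so intermediates exclude both endpoints by
    construction.
    """
    pi, pj = B.index(i), B.index(j)
    adj = [set(np.flatnonzero(B.A[r])) for r in range(B.n)]
    out = set()

    def rec(cur, path):
        if len(path) - 1 == length:
            if cur == pj:
                out.add(tuple(B.order[x] for x in path[1:-1]))
            return
        for nxt in adj[cur]:
            if nxt not in path:
                rec(nxt, path + [nxt])

    rec(pi, [pi])
    return out


class TestBuildMatrix:
    def test_path_entries(self, path3):
        B = build_matrix(path3)
        assert B.order == ["A", "B", "C"]
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert (B.A == expected).all()

    def test_empty_network(self):
        B = build_matrix(AnnotatedNetwork(name="empty"))
        assert B.n == 0 and B.A.shape == (0, 0)

    def test_ordering_must_cover_nodes(self, path3):
        with pytest.raises(ValidationError):
            build_matrix(path3, order=["A", "B"])

    def test_custom_ordering_permutes(self, path3):
        B = build_matrix(path3, order=["C", "A", "B"])
        assert B.neighbors("B") == {"A", "C"}


class TestMatrixPower:
    def test_path_k2(self, path3):
        W = matrix_power(build_matrix(path3), 2)
        assert W.count("A", "C") == 1
        assert W.count("A", "A") == 1  # walk A-B-A

    def test_star_k2(self):
        net = make_network([("C", f"L{i}") for i in range(4)])
        W = matrix_power(build_matrix(net), 2)
        assert W.count("C", "C") == 4
        assert W.count("L0", "L1") == 1

    def test_k_below_one_rejected(self, path3):
        with pytest.raises(StpnetError):
            matrix_power(build_matrix(path3), 0)

    def test_diagonal_of_square_is_degree(self):
        rng = np.random.default_rng(11)
        net = random_gnp(rng, 25, 0.2)
        B = build_matrix(net)
        W = matrix_power(B, 2)
        for nid in net.node_ids:
            assert W.count(nid, nid) == net.degree(nid)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_walk_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        net = random_gnp(rng, 14, 0.25)
        B = build_matrix(net)
        for k in (1, 2, 3):
            assert (matrix_power(B, k).counts == walk_counts_oracle(B, k)).all()


class TestIntermediates:
    def test_path_second_order(self, path3):
        B = build_matrix(path3)
        assert second_order_intermediates(B, "A", "C") == {"B"}

    def test_triangle_second_order(self, triangle):
        B = build_matrix(triangle)
        assert second_order_intermediates(B, "A", "B") == {"C"}

    def test_unknown_node(self, path3):
        with pytest.raises(LookupNodeError):
            second_order_intermediates(build_matrix(path3), "A", "ZZZ")

    def test_second_order_size_equals_walk_count(self):
        rng = np.random.default_rng(5)
        net = random_gnp(rng, 30, 0.15)
        B = build_matrix(net)
        W = matrix_power(B, 2)
        ids = net.node_ids
        for i in range(0, 30, 5):
            for j in range(1, 30, 7):
                if ids[i] != ids[j]:
                    inter = second_order_intermediates(B, ids[i], ids[j])
                    assert len(inter) == W.count(ids[i], ids[j])
                    assert inter == (net.neighbors(ids[i]) & net.neighbors(ids[j]))

    def test_path4_third_order(self, path4):
        B = build_matrix(path4)
        assert third_order_intermediates(B, "A", "D") == {("B", "C")}

    def test_triangle_third_order_endpoints_excluded(self, triangle):
        B = build_matrix(triangle)
        assert third_order_intermediates(B, "A", "A") == set()

    @pytest.mark.parametrize("seed", [3, 4])
    def test_third_order_matches_simple_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_gnp(rng, 20, 0.25)
        B = build_matrix(net)
        ids = net.node_ids
        for i, j in [(0, 5), (1, 7), (2, 19), (3, 3)]:
            got = third_order_intermediates(B, ids[i], ids[j])
            expect = {
                (x, y) for (x, y) in simple_paths_oracle(B, ids[i], ids[j], 3)
            }
            assert got == expect


class TestOrderKPartners:
    def test_simple_new_excludes_shorter_orders(self, path4):
        B = build_matrix(path4)
        assert order_k_partners(B, "A", 2, "simple_new") == {"C"}
        assert order_k_partners(B, "A", 2, "walks") == {"C"}  # A has no 2-walk to B
        assert order_k_partners(B, "A", 3, "simple_new") == {"D"}
        assert order_k_partners(B, "A", 3, "walks") == {"B", "D"}

    def test_policies_agree_at_k1(self, triangle):
        B = build_matrix(triangle)
        for policy in ("walks", "simple_new"):
            assert order_k_partners(B, "A", 1, policy) == {"B", "C"}

    def test_unsupported_order(self, triangle):
        with pytest.raises(StpnetError):
            order_k_partners(build_matrix(triangle), "A", 4)

    def test_invariant_to_node_ordering(self):
        rng = np.random.default_rng(9)
        net = random_gnp(rng, 15, 0.3)
        B1 = build_matrix(net)
        perm = list(net.node_ids)
        rng.shuffle(perm)
        B2 = build_matrix(net, order=perm)
        for k in (1, 2, 3):
            assert order_k_partners(B1, "N03", k) == order_k_partners(B2, "N03", k)


class TestHubTables:
    def test_two_hubs_sharing_three_neighbors(self):
        edges = [("H1", f"S{i}") for i in range(3)] + [("H2", f"S{i}") for i in range(3)]
        edges += [("H1", "X"), ("H2", "Y")]
        net = make_network(edges, hubs=["H1", "H2"])
        B = build_matrix(net)
        T = hub_tables(B, ["H1", "H2"], k=2)
        assert T.loc["H1", "H2"] == 3

    def test_disconnected_hubs(self):
        net = make_network([("H1", "A"), ("H2", "B")], hubs=["H1", "H2"])
        T = hub_tables(build_matrix(net), ["H1", "H2"], k=2)
        assert T.loc["H1", "H2"] == 0

    def test_k1_diagonal_is_degree(self):
        net = make_network([("H1", "A"), ("H1", "B"), ("H2", "B")], hubs=["H1", "H2"])
        T = hub_tables(build_matrix(net), ["H1", "H2"], k=1)
        assert T.loc["H1", "H1"] == 2
        assert T.loc["H2", "H2"] == 1
        assert T.loc["H1", "H2"] == 0

    def test_upper_triangular_display(self, triangle):
        B = build_matrix(triangle)
        T = hub_tables(B, ["A", "B", "C"], k=2, upper_triangular=True)
        assert (np.tril(T.to_numpy(), -1) == 0).all()

    def test_unknown_hub(self, triangle):
        with pytest.raises(LookupNodeError):
            hub_tables(build_matrix(triangle), ["A", "ZZ"], k=1)


def test_order_report_exposes_both_third_order_counts(path4):
    B = build_matrix(path4)
    rep = order_report(B, ["A", "D"], k=3)
    key = frozenset(("A", "D"))
    assert rep.per_pair[key] == {("B", "C")}
    assert rep.pair_walk_counts[key] == 1
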