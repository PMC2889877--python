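"""Binary-matrix formalism for order-k interaction analysis.

An undirected network is represented as a symmetric 0/1 adjacency matrix A
with zero diagonal. Matrix powers count walks: (A^2)_ij is the number of
two-edge routes i-x-j, i.e. for i != j the number of common neighbours
(intermediate proteins); (A^3)_ij counts three-edge routes. Because walks
may revisit vertices, the enumeration operations below default to simple
paths — intermediates exclude the endpoints and each other — while the raw
walk counts stay available through :func:`matrix_power`.

Order-k partner sets around a hub come in two flavours:

* ``walks`` — every node with at least one length-k walk from the hub;
* ``simple_new`` — additionally excludes nodes already reachable by a
  shorter walk, i.e. the genuinely new proteins at order k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LookupNodeError, StpnetError, ValidationError
from .network import AnnotatedNetwork

__all__ = [
    "BinaryMatrix",
    "WalkCountMatrix",
    "OrderKReport",
    "build_matrix",
    "matrix_power",
    "second_order_intermediates",
    "third_order_intermediates",
    "order_k_partners",
    "hub_tables",
    "order_report",
]

MAX_ORDER = 3


@dataclass
class BinaryMatrix:
    """Symmetric 0/1 adjacency with a fixed node ordering."""

    order: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int64)
        n = len(self.order)
        if self.A.shape != (n, n):
            raise ValidationError("matrix shape does not match node ordering")
        if (self.A != self.A.T).any():
            raise ValidationError("adjacency matrix must be symmetric")
        if self.A.diagonal().any():
            raise ValidationError("adjacency matrix must have zero diagonal")
        if not set(np.unique(self.A)) <= {0, 1}:
            raise ValidationError("adjacency matrix must be binary")
        self._pos = {nid: i for i, nid in enumerate(self.order)}
        if len(self._pos) != n:
            raise ValidationError("duplicate node ids in ordering")

    def index(self, nid: str) -> int:
        try:
            return self._pos[nid]
        except KeyError:
            raise LookupNodeError(f"node {nid!r} not in matrix") from None

    def neighbors(self, nid: str) -> set[str]:
        i = self.index(nid)
        return {self.order[j] for j in np.flatnonzero(self.A[i])}

    @property
    def n(self) -> int:
        return len(self.order)


@dataclass
class WalkCountMatrix:
    """Counts of length-k walks between all node pairs."""

    order_k: int
    order: list[str]
    counts: np.ndarray

    def count(self, i: str, j: str) -> int:
        pos = {nid: k for k, nid in enumerate(self.order)}
        try:
            return int(self.counts[pos[i], pos[j]])
        except KeyError as exc:
            raise LookupNodeError(str(exc)) from None


def build_matrix(
    net: AnnotatedNetwork, order: Sequence[str] | None = None
) -> BinaryMatrix:
    """Adjacency matrix of the network; default ordering is lexicographic."""
    if order is None:
        order = net.node_ids
    else:
        order = list(order)
        missing = set(net.node_ids) - set(order)
        if missing:
            raise ValidationError(
                f"ordering omits {len(missing)} nodes (e.g. {sorted(missing)[:3]})"
            )
        extra = set(order) - set(net.node_ids)
        if extra:
            raise ValidationError(f"ordering names unknown nodes: {sorted(extra)[:3]}")
    n = len(order)
    pos = {nid: i for i, nid in enumerate(order)}
    A = np.zeros((n, n), dtype=np.int64)
    for a, b in net.graph.edges:
        A[pos[a], pos[b]] = 1
        A[pos[b], pos[a]] = 1
    return BinaryMatrix(order=list(order), A=A)


def matrix_power(B: BinaryMatrix, k: int) -> WalkCountMatrix:
    """Length-k walk counts via the k-th power of the adjacency matrix."""
    if k < 1:
        raise StpnetError(f"walk order must be >= 1, got {k}")
    counts = np.linalg.matrix_power(B.A, k)
    return WalkCountMatrix(order_k=k, order=list(B.order), counts=counts)


def second_order_intermediates(B: BinaryMatrix, i: str, j: str) -> set[str]:
    """Common neighbours of i and j, excluding the endpoints themselves.

    For i != j (zero diagonal) the size equals the walk count (A^2)_ij.
    """
    pi, pj = B.index(i), B.index(j)
    both = np.flatnonzero(B.A[pi] & B.A[pj])
    return {B.order[x] for x in both if B.order[x] not in (i, j)}


def third_order_intermediates(B: BinaryMatrix, i: str, j: str) -> set[tuple[str, str]]:
    """Ordered intermediate pairs (x, y) with edges i-x, x-y, y-j.

    Simple-path policy: x and y are distinct and exclude both endpoints, so
    each returned pair corresponds to a three-edge simple path i-x-y-j. For
    i == j the result is empty (a simple path cannot revisit its start).
    """
    pi, pj = B.index(i), B.index(j)
    if pi == pj:
        return set()
    ni = np.flatnonzero(B.A[pi])
    nj = np.flatnonzero(B.A[pj])
    banned = {pi, pj}
    out: set[tuple[str, str]] = set()
    nj_set = set(int(y) for y in nj) - banned
    for x in ni:
        x = int(x)
        if x in banned:
            continue
        for y in np.flatnonzero(B.A[x]):
            y = int(y)
            if y in nj_set and y != x:
                out.add((B.order[x], B.order[y]))
    return out


def order_k_partners(
    B: BinaryMatrix, hub: str, k: int, policy: str = "simple_new"
) -> set[str]:
    """Order-k interaction partners of a hub.

    ``walks``: nodes with at least one length-k walk from the hub (hub
    excluded). ``simple_new``: additionally excludes nodes reachable by any
    shorter walk, leaving the proteins first reached at order k.
    """
    if k not in (1, 2, 3):
        raise StpnetError(f"order k must be in 1..{MAX_ORDER}, got {k}")
    if policy not in ("walks", "simple_new"):
        raise StpnetError(f"unknown counting policy {policy!r}")
    pi = B.index(hub)
    power = np.linalg.matrix_power(B.A, k)
    reach_k = set(np.flatnonzero(power[pi]))
    reach_k.discard(pi)
    if policy == "simple_new":
        seen: set[int] = set()
        for m in range(1, k):
            pm = np.linalg.matrix_power(B.A, m)
            seen |= set(np.flatnonzero(pm[pi]))
        reach_k -= seen
    return {B.order[x] for x in reach_k}


def hub_tables(
    B: BinaryMatrix, hubs: Sequence[str], k: int, upper_triangular: bool = False
) -> pd.DataFrame:
    """Square hub-by-hub count table.

    k=1: diagonal holds first-order partner counts (degrees), off-diagonal 0.
    k=2: off-diagonal (i, j) holds the number of intermediate proteins
    between hubs i and j; the diagonal holds the count of each hub's new
    second-order partners (``simple_new`` policy).

    ``upper_triangular=True`` zeroes the strict lower triangle for display;
    internally everything stays symmetric.
    """
    if k not in (1, 2):
        raise StpnetError(f"hub tables defined for k in {{1, 2}}, got {k}")
    for h in hubs:
        B.index(h)  # raises LookupNodeError if absent
    n = len(hubs)
    T = np.zeros((n, n), dtype=int)
    if k == 1:
        for i, h in enumerate(hubs):
            T[i, i] = len(B.neighbors(h))
    else:
        for i, hi in enumerate(hubs):
            T[i, i] = len(order_k_partners(B, hi, 2, policy="simple_new"))
            for j in range(i + 1, n):
                c = len(second_order_intermediates(B, hi, hubs[j]))
                T[i, j] = c
                T[j, i] = c
    if upper_triangular:
        T = np.triu(T)
    return pd.DataFrame(T, index=list(hubs), columns=list(hubs))


@dataclass
class OrderKReport:
    """Partner sets and intermediate sets around a hub list at order k."""

    policy: str
    order_k: int
    per_hub: dict[str, set[str]]
    per_pair: dict[frozenset[str], set]
    # For k=3 both counting views of the pair enumeration are kept:
    # distinct intermediate pairs (simple paths) and raw walk counts.
    pair_walk_counts: dict[frozenset[str], int]


def order_report(
    B: BinaryMatrix, hubs: Sequence[str], k: int, policy: str = "simple_new"
) -> OrderKReport:
    """Order-k partner sets per hub plus intermediates per hub pair."""
    if k not in (1, 2, 3):
        raise StpnetError(f"order k must be in 1..{MAX_ORDER}, got {k}")
    per_hub = {h: order_k_partners(B, h, k, policy=policy) for h in hubs}
    per_pair: dict[frozenset[str], set] = {}
    pair_walks: dict[frozenset[str], int] = {}
    if k >= 2:
        walk = matrix_power(B, k)
        for i, hi in enumerate(hubs):
            for hj in hubs[i + 1 :]:
                key = frozenset((hi, hj))
                if k == 2:
                    per_pair[key] = second_order_intermediates(B, hi, hj)
                else:
                    per_pair[key] = third_order_intermediates(B, hi, hj)
                pair_walks[key] = walk.count(hi, hj)
    return OrderKReport(
        policy=policy,
        order_k=k,
        per_hub=per_hub,
        per_pair=per_pair,
        pair_walk_counts=pair_walks,
    )
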