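"""Hub-neighbourhood overlap, transcription-factor statistics and
cross-network comparison.

A *Venn partition* assigns every non-hub protein adjacent to at least one
hub to the exact subset of hubs it touches. For four hubs this yields up to
15 disjoint regions; aggregating by cardinality (adjacent to exactly 1, 2,
3 or 4 hubs) gives the classic 13-position view of a four-set Venn diagram
(4 single regions, the "any two", "any three" and all-four classes).

Hubs themselves are never counted as another hub's partner; hub-hub
adjacency is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .errors import LookupNodeError, StpnetError
from .network import AnnotatedNetwork, canonicalize_id

__all__ = [
    "VennPartition",
    "TFReport",
    "OverlapReport",
    "venn_partition",
    "cardinality_summary",
    "tf_report",
    "edge_overlap",
]


@dataclass
class VennPartition:
    """Disjoint regions keyed by hub subset; values are partner-protein sets."""

    hubs: tuple[str, ...]
    regions: dict[frozenset[str], set[str]]
    hub_hub_edges: set[frozenset[str]]

    def region(self, *hubs: str) -> set[str]:
        """Partners whose hub-neighbour set is exactly the given subset."""
        return set(self.regions.get(frozenset(canonicalize_id(h) for h in hubs), set()))

    def all_partners(self) -> set[str]:
        out: set[str] = set()
        for members in self.regions.values():
            out |= members
        return out


def venn_partition(net: AnnotatedNetwork, hubs: Sequence[str]) -> VennPartition:
    """Partition hub-adjacent non-hub proteins by exact hub-neighbour subset."""
    if len(hubs) < 1:
        raise StpnetError("venn_partition needs at least one hub")
    hubs = tuple(canonicalize_id(h) for h in hubs)
    for h in hubs:
        if not net.has_node(h):
            raise LookupNodeError(f"hub {h!r} not in network")
    hub_set = set(hubs)
    regions: dict[frozenset[str], set[str]] = {}
    hub_hub: set[frozenset[str]] = set()
    for h in hubs:
        for nb in net.neighbors(h):
            if nb in hub_set:
                hub_hub.add(frozenset((h, nb)))
    partners = {nb for h in hubs for nb in net.neighbors(h)} - hub_set
    for p in partners:
        key = frozenset(net.neighbors(p) & hub_set)
        regions.setdefault(key, set()).add(p)
    return VennPartition(hubs=hubs, regions=regions, hub_hub_edges=hub_hub)


def cardinality_summary(vp: VennPartition) -> dict[int, int]:
    """Partner counts by number of adjacent hubs (1..len(hubs))."""
    out = {m: 0 for m in range(1, len(vp.hubs) + 1)}
    for key, members in vp.regions.items():
        out[len(key)] += len(members)
    return out


@dataclass
class TFReport:
    """Transcription-factor interaction statistics around the hubs."""

    total_tfs: int
    per_hub_tf_neighbors: dict[str, int]
    per_hub_share: dict[str, float]  # percent of all TF-hub adjacencies
    multi_hub_tf_counts: dict[str, int]  # {"exactly_2": n, "more_than_2": n}

    def to_dict(self) -> dict:
        return {
            "total_tfs": self.total_tfs,
            "per_hub_tf_neighbors": self.per_hub_tf_neighbors,
            "per_hub_share": self.per_hub_share,
            "multi_hub_tf_counts": self.multi_hub_tf_counts,
        }


def tf_report(net: AnnotatedNetwork, hubs: Sequence[str]) -> TFReport:
    """TF counts, per-hub share of TF-hub adjacencies, multi-hub TF counts.

    The share of hub h is 100 x (TF neighbours of h) / (total TF-hub
    adjacencies), reported to one decimal place. Multi-hub counts are over
    TF nodes adjacent to exactly two, or more than two, of the hubs.
    """
    hubs = [canonicalize_id(h) for h in hubs]
    for h in hubs:
        if not net.has_node(h):
            raise LookupNodeError(f"hub {h!r} not in network")
    hub_set = set(hubs)
    tfs = set(net.tfs())
    per_hub = {h: len(net.neighbors(h) & tfs) for h in hubs}
    total_adj = sum(per_hub.values())
    if total_adj == 0:
        raise StpnetError("no TF-hub adjacencies: shares undefined")
    shares = {h: round(100.0 * c / total_adj, 1) for h, c in per_hub.items()}
    exactly2 = 0
    more2 = 0
    for tf in tfs - hub_set:
        m = len(net.neighbors(tf) & hub_set)
        if m == 2:
            exactly2 += 1
        elif m > 2:
            more2 += 1
    return TFReport(
        total_tfs=len(tfs),
        per_hub_tf_neighbors=per_hub,
        per_hub_share=shares,
        multi_hub_tf_counts={"exactly_2": exactly2, "more_than_2": more2},
    )


@dataclass
class OverlapReport:
    """Edge-set and hub-coverage agreement between two networks."""

    shared_edges: int
    jaccard_edges: float
    per_hub_shared_neighbors: dict[str, int]
    multi_hub_proteins_in_other: int

    def to_dict(self) -> dict:
        return {
            "shared_edges": self.shared_edges,
            "jaccard_edges": self.jaccard_edges,
            "per_hub_shared_neighbors": self.per_hub_shared_neighbors,
            "multi_hub_proteins_in_other": self.multi_hub_proteins_in_other,
        }


def edge_overlap(
    a: AnnotatedNetwork,
    b: AnnotatedNetwork,
    hubs: Sequence[str] | None = None,
) -> OverlapReport:
    """Compare two networks: shared edges, Jaccard, hub-neighbour coverage.

    ``hubs`` defaults to the hub-flagged nodes of network ``a``.
    ``multi_hub_proteins_in_other`` counts non-hub proteins of ``b`` adjacent
    (within ``b``) to more than one of the hubs.
    """
    ea, eb = a.edge_keys(), b.edge_keys()
    shared = len(ea & eb)
    union = len(ea | eb)
    jaccard = shared / union if union else 1.0
    if hubs is None:
        hubs = a.hubs()
    hubs = [canonicalize_id(h) for h in hubs]
    per_hub: dict[str, int] = {}
    for h in hubs:
        na = a.neighbors(h) if a.has_node(h) else set()
        nb = b.neighbors(h) if b.has_node(h) else set()
        per_hub[h] = len(na & nb)
    hub_set = set(hubs)
    counts: dict[str, int] = {}
    for h in hubs:
        if not b.has_node(h):
            continue
        for nb in b.neighbors(h):
            if nb not in hub_set:
                counts[nb] = counts.get(nb, 0) + 1
    multi = sum(1 for c in counts.values() if c > 1)
    return OverlapReport(
        shared_edges=shared,
        jaccard_edges=jaccard,
        per_hub_shared_neighbors=per_hub,
        multi_hub_proteins_in_other=multi,
    )
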