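"""Annotated protein-protein interaction networks.

The central container is :class:`AnnotatedNetwork`, an undirected simple
graph (backed by :class:`networkx.Graph`) whose nodes are canonicalized
protein identifiers carrying annotations (display name, hub flag,
transcription-factor flag, free-text notes, literature references) and whose
edges carry an interaction category (``physical`` or ``functional``), an
optional direction hint (annotation only — the topology is undirected) and
references.

Readers and writers cover the interchange formats used by network tools:

* edge-list TSV (``source  target  category  references``, header required)
* SIF (``nodeA pp nodeB`` for physical, ``fn`` for functional)
* square labeled 0/1 adjacency CSV
* GraphML (node attributes ``is_hub`` / ``is_tf`` are preserved)

Identifiers are case-insensitive and stored uppercase; self-loops are
rejected by default (``policy="drop"`` silently discards them instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import (
    InvalidIdentifierError,
    LookupNodeError,
    ParseError,
    ValidationError,
)

__all__ = [
    "ProteinNode",
    "Interaction",
    "AnnotatedNetwork",
    "NetworkSummary",
    "canonicalize_id",
    "read_edge_list",
    "read_adjacency_table",
    "merge_networks",
    "write_network",
    "summarize",
]

CATEGORIES = ("physical", "functional")

_SIF_RELATIONS = {"pp": "physical", "fn": "functional"}
_SIF_TOKENS = {"physical": "pp", "functional": "fn"}


def canonicalize_id(raw: str) -> str:
    """Normalize a protein identifier: trim whitespace, uppercase.

    Idempotent. Raises :class:`InvalidIdentifierError` on empty or
    whitespace-only input.
    """
    if raw is None:
        raise InvalidIdentifierError("identifier is None")
    cleaned = str(raw).strip().upper()
    if not cleaned:
        raise InvalidIdentifierError(f"empty identifier: {raw!r}")
    return cleaned


@dataclass
class ProteinNode:
    """A protein (node) with its curation annotations."""

    id: str
    display_name: str = ""
    is_hub: bool = False
    is_tf: bool = False
    notes: str = ""
    references: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.id = canonicalize_id(self.id)
        if not self.display_name:
            self.display_name = self.id


@dataclass
class Interaction:
    """An undirected interaction between two distinct proteins.

    ``direction_hint`` records curated directionality (e.g. information flow
    between kinases) purely as annotation; it never affects topology.
    """

    a: str
    b: str
    category: str = "physical"
    direction_hint: tuple[str, str] | None = None
    references: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.a = canonicalize_id(self.a)
        self.b = canonicalize_id(self.b)
        if self.a == self.b:
            raise ValidationError(f"self-loop on {self.a!r} is not allowed")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown interaction category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )

    @property
    def key(self) -> frozenset[str]:
        """Unordered endpoint pair; (a,b) == (b,a)."""
        return frozenset((self.a, self.b))


class AnnotatedNetwork:
    """Undirected PPI network with per-node and per-edge annotations."""

    def __init__(self, name: str = "", provenance: str = ""):
        self.name = name
        self.provenance = provenance
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(self, node: ProteinNode | str, **attrs) -> str:
        if isinstance(node, str):
            node = ProteinNode(id=node, **attrs)
        nid = node.id
        if nid in self.graph:
            # merge annotations: flags OR-ed, references deduplicated,
            # first display name wins
            data = self.graph.nodes[nid]
            if node.display_name != nid and data["display_name"] != node.display_name:
                if data["display_name"] == nid:
                    data["display_name"] = node.display_name
                elif node.display_name != nid:
                    warnings.warn(
                        f"conflicting display names for {nid}: keeping "
                        f"{data['display_name']!r}, ignoring {node.display_name!r}"
                    )
            data["is_hub"] = data["is_hub"] or node.is_hub
            data["is_tf"] = data["is_tf"] or node.is_tf
            if node.notes and node.notes not in data["notes"]:
                data["notes"] = (data["notes"] + " " + node.notes).strip()
            for ref in node.references:
                if ref not in data["references"]:
                    data["references"].append(ref)
        else:
            self.graph.add_node(
                nid,
                display_name=node.display_name,
                is_hub=node.is_hub,
                is_tf=node.is_tf,
                notes=node.notes,
                references=list(node.references),
            )
        return nid

    def add_edge(self, inter: Interaction) -> None:
        a, b = inter.a, inter.b
        for nid in (a, b):
            if nid not in self.graph:
                self.add_node(nid)
        if self.graph.has_edge(a, b):
            data = self.graph.edges[a, b]
            for ref in inter.references:
                if ref not in data["references"]:
                    data["references"].append(ref)
        else:
            self.graph.add_edge(
                a,
                b,
                category=inter.category,
                direction_hint=inter.direction_hint,
                references=list(inter.references),
            )

    # -- queries -------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_keys(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def hubs(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data="is_hub") if d)

    def tfs(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data="is_tf") if d)

    def neighbors(self, nid: str) -> set[str]:
        nid = canonicalize_id(nid)
        if nid not in self.graph:
            raise LookupNodeError(f"node {nid!r} not in network {self.name!r}")
        return set(self.graph.neighbors(nid))

    def degree(self, nid: str) -> int:
        return len(self.neighbors(nid))

    def has_node(self, nid: str) -> bool:
        return canonicalize_id(nid) in self.graph

    def validate(self) -> None:
        """Check structural invariants; raise ValidationError on breach."""
        for a, b in self.graph.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
        degsum = sum(d for _, d in self.graph.degree())
        if degsum != 2 * self.n_edges:
            raise ValidationError("degree sum != 2 x edge count")

    def copy(self) -> "AnnotatedNetwork":
        out = AnnotatedNetwork(name=self.name, provenance=self.provenance)
        out.graph = self.graph.copy()
        for n in out.graph.nodes:
            out.graph.nodes[n]["references"] = list(self.graph.nodes[n]["references"])
        for a, b in out.graph.edges:
            out.graph.edges[a, b]["references"] = list(self.graph.edges[a, b]["references"])
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AnnotatedNetwork(name={self.name!r}, nodes={self.n_nodes}, "
            f"edges={self.n_edges})"
        )


# -- readers ----------------------------------------------------------


def _parse_refs(token: str) -> list[str]:
    token = (token or "").strip()
    if not token:
        return []
    return [t.strip() for t in token.split(";") if t.strip()]


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    self_loop_policy: str = "reject",
    name: str | None = None,
) -> AnnotatedNetwork:
    """Read a network from an edge-list file.

    ``dialect="tsv"`` expects a header ``source<TAB>target`` with optional
    ``category`` and ``references`` columns. ``dialect="sif"`` reads simple
    interaction format lines ``A pp B [C ...]`` (whitespace separated; one
    source, one relation, one or more targets).
    """
    path = Path(path)
    if dialect not in ("tsv", "sif"):
        raise ValidationError(f"unknown edge-list dialect {dialect!r}")
    if self_loop_policy not in ("reject", "drop"):
        raise ValidationError(f"unknown self-loop policy {self_loop_policy!r}")
    net = AnnotatedNetwork(name=name or path.stem, provenance=str(path))

    def handle_pair(a: str, b: str, category: str, refs: list[str], lineno: int):
        try:
            ca, cb = canonicalize_id(a), canonicalize_id(b)
        except InvalidIdentifierError as exc:
            raise ParseError(str(exc), line=lineno) from exc
        if ca == cb:
            if self_loop_policy == "reject":
                raise ParseError(f"self-loop on {ca!r}", line=lineno)
            return
        if category not in CATEGORIES:
            raise ParseError(f"unknown category token {category!r}", line=lineno)
        net.add_edge(Interaction(ca, cb, category=category, references=refs))

    lines = path.read_text().splitlines()
    if dialect == "tsv":
        if not lines:
            raise ParseError("empty file", line=1)
        header = [h.strip().lower() for h in lines[0].split("\t")]
        if header[:2] != ["source", "target"]:
            raise ParseError(
                "expected header starting with 'source<TAB>target'", line=1
            )
        col = {h: i for i, h in enumerate(header)}
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("record has fewer than two columns", line=lineno)
            category = "physical"
            if "category" in col and len(parts) > col["category"]:
                tok = parts[col["category"]].strip()
                if tok:
                    category = tok.lower()
            refs: list[str] = []
            if "references" in col and len(parts) > col["references"]:
                refs = _parse_refs(parts[col["references"]])
            handle_pair(parts[0], parts[1], category, refs, lineno)
    else:  # sif
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) == 1:
                # isolated node: legal SIF
                net.add_node(parts[0])
                continue
            if len(parts) < 3:
                raise ParseError("SIF record needs node, relation, node", line=lineno)
            relation = parts[1].lower()
            if relation not in _SIF_RELATIONS:
                raise ParseError(f"unknown SIF relation {parts[1]!r}", line=lineno)
            for target in parts[2:]:
                handle_pair(parts[0], target, _SIF_RELATIONS[relation], [], lineno)
    return net


def read_adjacency_table(path: str | Path, name: str | None = None) -> AnnotatedNetwork:
    """Read a square labeled 0/1 adjacency table (CSV, or XLSX convenience).

    The table must be square with matching row/column labels, symmetric, and
    binary. Nonzero diagonal entries are ignored with a warning (the network
    has no self-interactions).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(canonicalize_id)
    df.columns = df.columns.map(canonicalize_id)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(
            f"adjacency table is not square: {df.shape[0]} rows x {df.shape[1]} columns"
        )
    if list(df.index) != list(df.columns):
        raise ValidationError("row labels do not match column labels")
    values = df.to_numpy()
    uniq = set(pd.unique(values.ravel()))
    if not uniq <= {0, 1}:
        raise ValidationError(f"non-binary entries in adjacency table: {sorted(uniq - {0, 1})}")
    if (values != values.T).any():
        raise ValidationError("adjacency table is not symmetric")
    if values.diagonal().any():
        warnings.warn("nonzero diagonal in adjacency table ignored (no self-loops)")
    net = AnnotatedNetwork(name=name or path.stem, provenance=str(path))
    ids = list(df.index)
    for nid in ids:
        net.add_node(nid)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if values[i, j]:
                net.add_edge(Interaction(a, ids[j]))
    return net


def merge_networks(parts: Sequence[AnnotatedNetwork], name: str = "merged") -> AnnotatedNetwork:
    """Union of networks by canonical id: the super-network through shared proteins.

    Node annotations are merged (flags OR-ed, references concatenated without
    duplicates, first display name kept); edges are united under unordered
    equality.
    """
    if not parts:
        raise ValidationError("merge_networks requires at least one network")
    out = AnnotatedNetwork(
        name=name, provenance="; ".join(p.provenance for p in parts if p.provenance)
    )
    for part in parts:
        for nid, data in part.graph.nodes(data=True):
            out.add_node(
                ProteinNode(
                    id=nid,
                    display_name=data.get("display_name", nid),
                    is_hub=data.get("is_hub", False),
                    is_tf=data.get("is_tf", False),
                    notes=data.get("notes", ""),
                    references=list(data.get("references", [])),
                )
            )
        for a, b, data in part.graph.edges(data=True):
            out.add_edge(
                Interaction(
                    a,
                    b,
                    category=data.get("category", "physical"),
                    direction_hint=data.get("direction_hint"),
                    references=list(data.get("references", [])),
                )
            )
    return out


# -- writers ----------------------------------------------------------


def write_network(net: AnnotatedNetwork, path: str | Path, format: str = "tsv") -> Path:
    """Write the network; round-trips are identity on (node ids, edge set)."""
    path = Path(path)
    if format == "tsv":
        lines = ["source\ttarget\tcategory\treferences"]
        for a, b in sorted(net.edge_keys(), key=sorted):
            a, b = sorted((a, b))
            data = net.graph.edges[a, b]
            lines.append(
                f"{a}\t{b}\t{data.get('category', 'physical')}\t"
                + ";".join(data.get("references", []))
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "sif":
        lines = []
        for a, b in sorted(net.edge_keys(), key=sorted):
            a, b = sorted((a, b))
            rel = _SIF_TOKENS[net.graph.edges[a, b].get("category", "physical")]
            lines.append(f"{a} {rel} {b}")
        covered = {n for k in net.edge_keys() for n in k}
        for nid in net.node_ids:
            if nid not in covered:
                lines.append(nid)
        path.write_text("\n".join(lines) + "\n")
    elif format == "adjacency_csv":
        ids = net.node_ids
        import numpy as np

        A = np.zeros((len(ids), len(ids)), dtype=int)
        pos = {nid: i for i, nid in enumerate(ids)}
        for a, b in net.graph.edges:
            A[pos[a], pos[b]] = 1
            A[pos[b], pos[a]] = 1
        pd.DataFrame(A, index=ids, columns=ids).to_csv(path)
    elif format == "graphml":
        g = nx.Graph()
        for nid, data in net.graph.nodes(data=True):
            g.add_node(
                nid,
                display_name=data.get("display_name", nid),
                is_hub=bool(data.get("is_hub", False)),
                is_tf=bool(data.get("is_tf", False)),
                references=";".join(data.get("references", [])),
            )
        for a, b, data in net.graph.edges(data=True):
            g.add_edge(
                a,
                b,
                category=data.get("category", "physical"),
                references=";".join(data.get("references", [])),
            )
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown output format {format!r}")
    return path


def read_graphml(path: str | Path) -> AnnotatedNetwork:
    """Read a GraphML file written by :func:`write_network`."""
    g = nx.read_graphml(Path(path))
    net = AnnotatedNetwork(name=Path(path).stem, provenance=str(path))
    for nid, data in g.nodes(data=True):
        net.add_node(
            ProteinNode(
                id=nid,
                display_name=data.get("display_name", nid),
                is_hub=bool(data.get("is_hub", False)),
                is_tf=bool(data.get("is_tf", False)),
                references=_parse_refs(data.get("references", "")),
            )
        )
    for a, b, data in g.edges(data=True):
        net.add_edge(
            Interaction(
                a,
                b,
                category=data.get("category", "physical"),
                references=_parse_refs(data.get("references", "")),
            )
        )
    return net


# -- summary ----------------------------------------------------------


@dataclass
class NetworkSummary:
    name: str
    n_nodes: int
    n_edges: int
    n_tfs: int
    hubs: list[str]
    hub_degrees: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_tfs": self.n_tfs,
            "hubs": self.hubs,
            "hub_degrees": self.hub_degrees,
        }


def summarize(net: AnnotatedNetwork) -> NetworkSummary:
    hubs = net.hubs()
    return NetworkSummary(
        name=net.name,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        n_tfs=len(net.tfs()),
        hubs=hubs,
        hub_degrees={h: net.degree(h) for h in hubs},
    )
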