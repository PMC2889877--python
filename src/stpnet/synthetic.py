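"""Synthetic hub-centric networks and expression p-values with known truth.

The network generator builds a four-hub network region by region: for every
hub subset a prescribed number of partner proteins adjacent to exactly those
hubs is created, then each hub is topped up with exclusive partners until
its degree is met exactly. Optional partner-partner edges add clustering
without touching hub degrees. Transcription-factor flags are assigned either
by fraction or by an explicit per-region plan.

The expression generator emulates the statistical structure the sub-network
search assumes: null genes draw p ~ Uniform(0,1) (equivalently z ~ N(0,1)),
planted module genes draw an effect z* ~ N(effect_mean, effect_sd) and
report p = 1 - Phi(z*), so converting back through the inverse normal CDF
recovers z* exactly.

``curated_like()`` is a fixed preset encoding the curated-network geometry:
hub degrees 241/129/300/98, pairwise hub-neighbour overlaps 5/10/7/7/3/6,
two triple-overlap partners plus one partner shared by all four hubs, 44
TFs (five adjacent to exactly two hubs, two to three hubs) and 11
partner-partner edges for a total of 779 interactions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .active import DEFAULT_EPSILON, NodeScores
from .errors import ConfigError, GenerationError
from .network import AnnotatedNetwork, Interaction, ProteinNode, write_network

__all__ = [
    "SynthNetConfig",
    "SynthExprConfig",
    "generate_network",
    "plant_module",
    "plant_nested_modules",
    "generate_pvalues",
    "two_level_pvalues",
    "curated_like",
    "benchmark",
    "write_fixture",
]

DEFAULT_HUBS = ("SNF1", "TOR1", "PKA1", "HOG1")


@dataclass
class SynthNetConfig:
    """Recipe for a four-hub network with prescribed neighbourhood overlaps.

    ``pairwise_overlap[{a,b}]`` is the *total* number of partners shared by
    hubs a and b (including those in triple/quadruple regions);
    ``higher_overlap[S]`` for |S| in {3, 4} is the exact count of partners
    adjacent to precisely the hubs in S. ``n_second_shell`` adds nodes that
    attach to a random non-hub node instead of a hub, thinning the topology
    away from pure hub stars without touching hub degrees or Venn regions.
    TF flags follow ``tf_plan`` (exact per-region counts, keyed by hub
    subset) when given, otherwise ``tf_fraction`` of all partners.
    """

    hub_names: tuple[str, str, str, str] = DEFAULT_HUBS
    hub_degrees: tuple[int, int, int, int] = (241, 129, 300, 98)
    pairwise_overlap: dict[frozenset, int] = field(default_factory=dict)
    higher_overlap: dict[frozenset, int] = field(default_factory=dict)
    n_extra_partner_edges: int = 0
    n_second_shell: int = 0
    tf_fraction: float = 0.0
    tf_plan: dict[frozenset, int] | None = None
    seed: int = 0
    name: str = "synthetic"

    def exact_regions(self) -> dict[frozenset, int]:
        """Exact partner count per hub subset (singletons included)."""
        hubs = list(self.hub_names)
        if len(set(hubs)) != 4:
            raise ConfigError("four distinct hub names required")
        for key in self.pairwise_overlap:
            if len(key) != 2 or not key <= set(hubs):
                raise ConfigError(f"bad pairwise key {set(key)}")
        for key, cnt in self.higher_overlap.items():
            if len(key) not in (3, 4) or not key <= set(hubs):
                raise ConfigError(f"bad higher-overlap key {set(key)}")
            if cnt < 0:
                raise ConfigError("negative overlap count")
        regions: dict[frozenset, int] = {}
        for key, cnt in self.higher_overlap.items():
            if cnt:
                regions[key] = cnt
        for i, a in enumerate(hubs):
            for b in hubs[i + 1 :]:
                pair = frozenset((a, b))
                total = self.pairwise_overlap.get(pair, 0)
                covered = sum(
                    c for s, c in self.higher_overlap.items() if pair <= s
                )
                exact = total - covered
                if exact < 0:
                    raise ConfigError(
                        f"pairwise overlap {sorted(pair)} = {total} smaller than "
                        f"its triple/quadruple regions ({covered})"
                    )
                if exact:
                    regions[pair] = exact
        for h, deg in zip(hubs, self.hub_degrees):
            if deg < 0:
                raise ConfigError("negative hub degree")
            multi = sum(c for s, c in regions.items() if h in s)
            exclusive = deg - multi
            if exclusive < 0:
                raise ConfigError(
                    f"hub {h}: degree {deg} cannot accommodate {multi} "
                    "shared partners"
                )
            if exclusive:
                regions[frozenset((h,))] = exclusive
        if self.tf_plan is not None:
            for key, cnt in self.tf_plan.items():
                avail = regions.get(frozenset(key), 0)
                if cnt > avail:
                    raise ConfigError(
                        f"tf_plan wants {cnt} TFs in region {sorted(key)} "
                        f"but it has only {avail} partners"
                    )
        if not 0 <= self.tf_fraction <= 1:
            raise ConfigError("tf_fraction must lie in [0, 1]")
        return regions


def generate_network(cfg: SynthNetConfig) -> AnnotatedNetwork:
    """Build the configured network; byte-identical under the same seed."""
    regions = cfg.exact_regions()  # raises ConfigError if inconsistent
    rng = np.random.default_rng(cfg.seed)
    net = AnnotatedNetwork(name=cfg.name, provenance=f"synthetic seed={cfg.seed}")
    for h in cfg.hub_names:
        net.add_node(ProteinNode(id=h, is_hub=True))
    counter = 0
    region_partners: dict[frozenset, list[str]] = {}
    # deterministic creation order: larger regions first, then lexicographic
    for key in sorted(regions, key=lambda s: (-len(s), tuple(sorted(s)))):
        members = []
        for _ in range(regions[key]):
            counter += 1
            pid = f"P{counter:04d}"
            net.add_node(pid)
            for h in sorted(key):
                net.add_edge(Interaction(h, pid))
            members.append(pid)
        region_partners[key] = members
    partners = [f"P{i:04d}" for i in range(1, counter + 1)]
    # second shell: nodes hanging off random non-hub nodes (hub degrees fixed)
    non_hub = list(partners)
    for _ in range(cfg.n_second_shell):
        if not non_hub:
            raise GenerationError("second shell needs at least one partner")
        counter += 1
        pid = f"P{counter:04d}"
        net.add_node(pid)
        anchor = non_hub[int(rng.integers(len(non_hub)))]
        net.add_edge(Interaction(anchor, pid))
        non_hub.append(pid)
    # TF flags
    if cfg.tf_plan is not None:
        for key, cnt in sorted(
            cfg.tf_plan.items(), key=lambda kv: (-len(kv[0]), tuple(sorted(kv[0])))
        ):
            pool = region_partners.get(frozenset(key), [])
            chosen = rng.choice(len(pool), size=cnt, replace=False)
            for idx in sorted(int(i) for i in chosen):
                net.graph.nodes[pool[idx]]["is_tf"] = True
    elif cfg.tf_fraction > 0 and partners:
        n_tf = int(cfg.tf_fraction * len(partners))
        chosen = rng.choice(len(partners), size=n_tf, replace=False)
        for idx in sorted(int(i) for i in chosen):
            net.graph.nodes[partners[idx]]["is_tf"] = True
    # extra partner-partner edges: never touch hub degrees
    added = 0
    attempts = 0
    max_attempts = 200 * max(cfg.n_extra_partner_edges, 1)
    while added < cfg.n_extra_partner_edges:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                "could not place the requested partner-partner edges"
            )
        i, j = rng.integers(0, len(non_hub), size=2)
        a, b = non_hub[int(i)], non_hub[int(j)]
        if a == b or net.graph.has_edge(a, b):
            continue
        net.add_edge(Interaction(a, b, category="functional"))
        added += 1
    net.validate()
    return net


def plant_module(
    net: AnnotatedNetwork, size: int, seed: int = 0, within: Iterable[str] | None = None
) -> set[str]:
    """Grow a connected node set of exactly ``size`` by random expansion.

    ``within`` restricts growth to an induced subgraph (used for nested
    planting). Raises GenerationError if no connected set of the requested
    size can be grown from the drawn start node.
    """
    pool = sorted(within) if within is not None else net.node_ids
    if size < 1 or size > len(pool):
        raise GenerationError(f"cannot plant module of size {size} in {len(pool)} nodes")
    pool_set = set(pool)
    rng = np.random.default_rng(seed)
    start = pool[int(rng.integers(len(pool)))]
    members = {start}
    while len(members) < size:
        frontier = sorted(
            {nb for m in members for nb in net.neighbors(m) if nb in pool_set}
            - members
        )
        if not frontier:
            raise GenerationError(
                f"growth stalled at {len(members)} members (requested {size})"
            )
        members.add(frontier[int(rng.integers(len(frontier)))])
    return members


def plant_nested_modules(
    net: AnnotatedNetwork, warm_size: int, core_size: int, seed: int = 0
) -> tuple[set[str], set[str]]:
    """Plant a warm module with a hot core inside it (core subset of warm)."""
    if core_size > warm_size:
        raise GenerationError("core must not exceed the warm module")
    warm = plant_module(net, warm_size, seed=seed)
    core = plant_module(net, core_size, seed=seed + 1, within=warm)
    return warm, core


@dataclass
class SynthExprConfig:
    """Planted differential-expression signal on top of a uniform null."""

    module_size: int = 10
    effect_mean: float = 2.5
    effect_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_sd <= 0:
            raise ConfigError("effect_sd must be positive")
        if self.module_size < 0:
            raise ConfigError("module_size must be non-negative")


def generate_pvalues(
    net: AnnotatedNetwork,
    module: Iterable[str],
    cfg: SynthExprConfig,
    epsilon: float = DEFAULT_EPSILON,
) -> NodeScores:
    """Uniform null p-values with a planted shifted-z module.

    Module genes draw z* ~ N(effect_mean, effect_sd) and report
    p = 1 - Phi(z*); everything else draws p ~ Uniform(0,1).
    """
    module = {m for m in module}
    unknown = module - set(net.node_ids)
    if unknown:
        raise GenerationError(f"module names unknown nodes: {sorted(unknown)[:3]}")
    rng = np.random.default_rng(cfg.seed)
    pvals: dict[str, float] = {}
    for nid in net.node_ids:
        if nid in module:
            zstar = rng.normal(cfg.effect_mean, cfg.effect_sd)
            pvals[nid] = float(norm.sf(zstar))
        else:
            pvals[nid] = float(rng.uniform())
    return NodeScores.from_pvalues(pvals, epsilon=epsilon)


def two_level_pvalues(
    net: AnnotatedNetwork,
    warm: Iterable[str],
    core: Iterable[str],
    cfg: SynthExprConfig,
    epsilon: float = DEFAULT_EPSILON,
) -> NodeScores:
    """Warm module at half the effect mean, hot core at the full mean."""
    warm, core = set(warm), set(core)
    if not core <= warm:
        raise GenerationError("core must be a subset of the warm module")
    rng = np.random.default_rng(cfg.seed)
    pvals: dict[str, float] = {}
    for nid in net.node_ids:
        if nid in core:
            zstar = rng.normal(cfg.effect_mean, cfg.effect_sd)
            pvals[nid] = float(norm.sf(zstar))
        elif nid in warm:
            zstar = rng.normal(cfg.effect_mean / 2.0, cfg.effect_sd)
            pvals[nid] = float(norm.sf(zstar))
        else:
            pvals[nid] = float(rng.uniform())
    return NodeScores.from_pvalues(pvals, epsilon=epsilon)


# -- presets ----------------------------------------------------------


def curated_like(seed: int = 0) -> SynthNetConfig:
    """Preset mirroring the curated four-kinase network geometry.

    Hub degrees 241/129/300/98 (Snf1, Tor1, Pka1, Hog1); total pairwise
    hub-neighbour overlaps Snf1-Tor1 5, Snf1-Pka1 10, Snf1-Hog1 7,
    Tor1-Pka1 7, Tor1-Hog1 3, Pka1-Hog1 6; one partner shared by
    Snf1/Tor1/Pka1, one by Snf1/Pka1/Hog1, one by all four hubs. 44 TFs:
    five adjacent to exactly two hubs, two adjacent to three, placed so the
    per-hub TF-neighbour counts are 22/7/17/7. Eleven partner-partner edges
    bring the interaction total to 779.
    """
    S, T, P, H = DEFAULT_HUBS
    return SynthNetConfig(
        hub_names=DEFAULT_HUBS,
        hub_degrees=(241, 129, 300, 98),
        pairwise_overlap={
            frozenset((S, T)): 5,
            frozenset((S, P)): 10,
            frozenset((S, H)): 7,
            frozenset((T, P)): 7,
            frozenset((T, H)): 3,
            frozenset((P, H)): 6,
        },
        higher_overlap={
            frozenset((S, T, P)): 1,
            frozenset((S, P, H)): 1,
            frozenset((S, T, P, H)): 1,
        },
        n_extra_partner_edges=11,
        tf_plan={
            frozenset((S,)): 17,
            frozenset((T,)): 4,
            frozenset((P,)): 11,
            frozenset((H,)): 5,
            frozenset((S, P)): 2,
            frozenset((S, T)): 1,
            frozenset((T, P)): 1,
            frozenset((P, H)): 1,
            frozenset((S, T, P)): 1,
            frozenset((S, P, H)): 1,
        },
        seed=seed,
        name="curated",
    )


def benchmark(seed: int = 0) -> SynthNetConfig:
    """A 200-node four-hub network for planted-module recovery studies.

    Sparse by design: hub degrees 12/9/14/10, small pairwise overlaps and a
    159-node second shell give a mean degree near 2.
    The sparsity is what makes planted-module recovery well-posed. The
    aggregate score sum(z)/sqrt(k) absorbs any connected cluster of mildly
    positive null genes; on a graph of mean degree >= 3 the positive-z
    nodes (half of all genes under the uniform null) percolate into one
    giant connected cluster, so the score optimum is a large diffuse set no
    matter how the search is run — the large-first-module behaviour that
    motivates the two-pass refinement. Near mean degree 2 the induced
    positive subgraph is at its percolation threshold, null clusters stay
    small, and a planted coherent module is the global optimum.
    """
    S, T, P, H = DEFAULT_HUBS
    return SynthNetConfig(
        hub_names=DEFAULT_HUBS,
        hub_degrees=(12, 9, 14, 10),
        pairwise_overlap={
            frozenset((S, T)): 1,
            frozenset((S, P)): 2,
            frozenset((S, H)): 1,
            frozenset((T, P)): 2,
            frozenset((T, H)): 1,
            frozenset((P, H)): 1,
        },
        n_extra_partner_edges=0,
        n_second_shell=159,
        tf_fraction=0.07,
        seed=seed,
        name="benchmark-200",
    )


def write_fixture(
    out_dir: str | Path,
    net: AnnotatedNetwork,
    scores: NodeScores | None = None,
    truth: Mapping | None = None,
) -> dict[str, Path]:
    """Write a generated fixture: network TSV, score TSV, ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"network": write_network(net, out_dir / "network.tsv", format="tsv")}
    ann = out_dir / "annotations.tsv"
    lines = ["id\tis_hub\tis_tf"]
    for nid in net.node_ids:
        d = net.graph.nodes[nid]
        lines.append(f"{nid}\t{int(d.get('is_hub', False))}\t{int(d.get('is_tf', False))}")
    ann.write_text("\n".join(lines) + "\n")
    paths["annotations"] = ann
    if scores is not None:
        sp = out_dir / "scores.tsv"
        rows = ["gene\tp_value"]
        for g in sorted(scores.p_values):
            rows.append(f"{g}\t{scores.p_values[g]:.17g}")
        sp.write_text("\n".join(rows) + "\n")
        paths["scores"] = sp
    if truth is not None:
        tp = out_dir / "truth.json"
        tp.write_text(json.dumps(truth, indent=2, default=sorted) + "\n")
        paths["truth"] = tp
    return paths
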