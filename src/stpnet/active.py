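"""Identification of transcriptionally highly active sub-networks.

Per-gene p-values (from an upstream differential-expression analysis) are
converted to z-scores through the inverse standard-normal CDF,
``z = Phi^-1(1 - p)``, so small p-values map to large positive z. A
connected sub-network s of k genes is scored by the aggregate

    Zs = sum(z_i for i in s) / sqrt(k)

and standardized against a Monte-Carlo background: mu_k and sigma_k are the
mean and standard deviation of Zs over random size-k gene sets (connectivity
not required in the background), giving the corrected score
(Zs - mu_k) / sigma_k. The highest-scoring connected sub-network is searched
by simulated annealing with a geometric cooling schedule; the search can be
run twice in series, the second pass restricted to (and its background
recalibrated on) the members found by the first, to refine a large first
module down to its most active core.

All randomness is driven by explicit integer seeds; identical inputs and
seeds give identical results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import (
    ConfigError,
    DegenerateBackgroundError,
    StpnetError,
    ValidationError,
)
from .network import AnnotatedNetwork, canonicalize_id

__all__ = [
    "NodeScores",
    "BackgroundModel",
    "SAConfig",
    "SubnetworkResult",
    "p_to_z",
    "read_scores",
    "score_subnetwork",
    "calibrate_background",
    "corrected_score",
    "find_active_subnetwork",
    "iterated_search",
    "shared_interactors",
    "module_score_significance",
]

DEFAULT_EPSILON = 1e-16


def p_to_z(p, epsilon: float = DEFAULT_EPSILON):
    """Convert p-values to z-scores via the inverse normal CDF.

    z = Phi^-1(1 - clamp(p, eps, 1-eps)); monotone decreasing in p, finite
    for p = 0 or 1 thanks to the clamp. Accepts scalars or arrays.
    """
    if not 0 < epsilon < 0.5:
        raise StpnetError(f"epsilon must be in (0, 0.5), got {epsilon}")
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise StpnetError("p-values must lie in [0, 1]")
    clamped = np.clip(arr, epsilon, 1.0 - epsilon)
    z = norm.isf(clamped)  # isf(p) == ppf(1 - p), numerically stable tail
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


@dataclass
class NodeScores:
    """Per-gene p-values and derived z-scores."""

    p_values: dict[str, float]
    z_scores: dict[str, float]
    epsilon: float = DEFAULT_EPSILON

    @classmethod
    def from_pvalues(
        cls, p_values: Mapping[str, float], epsilon: float = DEFAULT_EPSILON
    ) -> "NodeScores":
        p = {canonicalize_id(g): float(v) for g, v in p_values.items()}
        z = {g: p_to_z(v, epsilon) for g, v in p.items()}
        return cls(p_values=p, z_scores=z, epsilon=epsilon)

    @classmethod
    def from_zscores(cls, z_scores: Mapping[str, float]) -> "NodeScores":
        z = {canonicalize_id(g): float(v) for g, v in z_scores.items()}
        p = {g: float(norm.sf(v)) for g, v in z.items()}
        return cls(p_values=p, z_scores=z)

    def align(
        self, net: AnnotatedNetwork, missing: str = "zero"
    ) -> tuple[dict[str, float], list[str]]:
        """z-scores for every network node; returns (z map, dropped genes).

        Scored genes absent from the network are dropped (returned for
        logging). Network nodes without a score get z = 0 under
        ``missing="zero"`` or raise under ``missing="error"``.
        """
        if missing not in ("zero", "error"):
            raise StpnetError(f"unknown missing-score policy {missing!r}")
        nodes = set(net.node_ids)
        dropped = sorted(set(self.z_scores) - nodes)
        z: dict[str, float] = {}
        for nid in nodes:
            if nid in self.z_scores:
                z[nid] = self.z_scores[nid]
            elif missing == "zero":
                z[nid] = 0.0
            else:
                raise StpnetError(f"node {nid!r} has no score")
        return z, dropped


def read_scores(path: str | Path, epsilon: float = DEFAULT_EPSILON) -> NodeScores:
    """Read a TSV score table: header ``gene<TAB>p_value`` (optional ``z``).

    If a ``z`` column is present it bypasses the p-to-z conversion.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValidationError("empty score file")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if "gene" not in header:
        raise ValidationError("score file needs a 'gene' column")
    gi = header.index("gene")
    zi = header.index("z") if "z" in header else None
    pi = header.index("p_value") if "p_value" in header else None
    if zi is None and pi is None:
        raise ValidationError("score file needs a 'p_value' or 'z' column")
    pvals: dict[str, float] = {}
    zvals: dict[str, float] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        gene = canonicalize_id(parts[gi])
        if zi is not None:
            zvals[gene] = float(parts[zi])
        else:
            pvals[gene] = float(parts[pi])
    if zi is not None:
        return NodeScores.from_zscores(zvals)
    return NodeScores.from_pvalues(pvals, epsilon=epsilon)


def score_subnetwork(zs: NodeScores | Mapping[str, float], members: Iterable[str]) -> float:
    """Aggregate score Zs = sum(z_i) / sqrt(k) for a k-member gene set."""
    zmap = zs.z_scores if isinstance(zs, NodeScores) else zs
    members = [canonicalize_id(m) for m in members]
    if not members:
        raise StpnetError("cannot score an empty member set")
    if len(set(members)) != len(members):
        raise StpnetError("duplicate members in sub-network")
    try:
        total = sum(zmap[m] for m in members)
    except KeyError as exc:
        raise StpnetError(f"member {exc.args[0]!r} has no score") from None
    return total / math.sqrt(len(members))


@dataclass
class BackgroundModel:
    """Monte-Carlo mean/sd of Zs over random size-k sets, k = 1..max_k."""

    sizes: np.ndarray  # 1..max_k
    mu: np.ndarray
    sigma: np.ndarray
    n_samples: int
    seed: int

    def mu_of(self, k: int) -> float:
        return float(self.mu[k - 1])

    def sigma_of(self, k: int) -> float:
        return float(self.sigma[k - 1])

    @property
    def max_k(self) -> int:
        return int(self.sizes[-1])


def calibrate_background(
    zs: NodeScores | Mapping[str, float],
    max_k: int,
    n_samples: int = 1000,
    seed: int = 0,
) -> BackgroundModel:
    """Estimate mu_k and sigma_k of Zs over random size-k gene samples.

    Genes are drawn uniformly with replacement (an iid bootstrap from the
    empirical score distribution); connectivity is deliberately not
    required. Bootstrap rather than subset sampling keeps sigma_k near the
    population sd for every k: drawing subsets from a small universe drives
    sigma_k to zero as k approaches the universe size, which would make any
    near-universe-sized set look arbitrarily significant. One sample matrix
    provides the draws for every k at once via prefix sums.
    """
    zmap = zs.z_scores if isinstance(zs, NodeScores) else dict(zs)
    z = np.array([zmap[g] for g in sorted(zmap)], dtype=float)
    n = z.size
    if max_k > n:
        raise StpnetError(f"max_k={max_k} exceeds number of scored genes ({n})")
    if max_k < 1:
        raise StpnetError("max_k must be >= 1")
    if n_samples < 2:
        raise StpnetError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(n_samples, max_k))
    prefix = np.cumsum(z[draws], axis=1)  # (n_samples, max_k)
    ks = np.arange(1, max_k + 1)
    scores = prefix / np.sqrt(ks)
    mu = scores.mean(axis=0)
    sigma = scores.std(axis=0, ddof=0)
    return BackgroundModel(sizes=ks, mu=mu, sigma=sigma, n_samples=n_samples, seed=seed)


def corrected_score(raw: float, k: int, bg: BackgroundModel) -> float:
    """Background-standardized score (raw - mu_k) / sigma_k."""
    if not 1 <= k <= bg.max_k:
        raise StpnetError(f"k={k} outside calibrated range 1..{bg.max_k}")
    s = bg.sigma_of(k)
    if s <= 1e-12:  # exact zero up to accumulated rounding
        raise DegenerateBackgroundError(f"sigma_{k} = 0: corrected score undefined")
    return (raw - bg.mu_of(k)) / s


@dataclass
class SAConfig:
    """Simulated-annealing schedule and seeding.

    ``n_steps`` is the total move budget (default 100 x |search universe| at
    run time), split evenly over ``n_restarts`` independent annealing runs;
    each run starts from a fresh random connected seed of ``start_size``
    nodes and cools geometrically, T_i = t_start * (t_end/t_start)^(i/steps).
    Restarts share one seeded generator, so the whole search is a pure
    function of (inputs, seed).
    """

    t_start: float = 1.0
    t_end: float = 0.01
    n_steps: int | None = None
    seed: int = 0
    start_size: int = 5
    n_restarts: int = 10

    def __post_init__(self) -> None:
        if self.t_start <= 0 or self.t_end <= 0 or self.t_end >= self.t_start:
            raise ConfigError("need 0 < t_end < t_start")
        if self.n_steps is not None and self.n_steps < 1:
            raise ConfigError("n_steps must be positive")
        if self.start_size < 1:
            raise ConfigError("start_size must be >= 1")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")


@dataclass
class SubnetworkResult:
    """Best connected sub-network found by one annealing run."""

    members: frozenset[str]
    raw_score: float
    corrected_score: float
    k: int
    best_trace: list[tuple[int, float]]
    seed: int

    def to_dict(self) -> dict:
        return {
            "members": sorted(self.members),
            "raw_score": self.raw_score,
            "corrected_score": self.corrected_score,
            "k": self.k,
            "seed": self.seed,
        }


def _corrected_or_none(raw: float, k: int, bg: BackgroundModel) -> float | None:
    """Corrected score tolerant of degenerate sigma (all-equal z-scores)."""
    if not 1 <= k <= bg.max_k:
        return None
    s = bg.sigma_of(k)
    d = raw - bg.mu_of(k)
    if s > 1e-12:
        return d / s
    return 0.0 if abs(d) < 1e-9 else None


def _connected_after_removal(
    members: set[str], adj: Mapping[str, set[str]], node: str
) -> bool:
    """Would the induced subgraph stay connected without ``node``?"""
    remaining = members - {node}
    if not remaining:
        return False
    start = next(iter(remaining))
    seen = {start}
    stack = [start]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb in remaining and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(remaining)


def _quench(
    members: set[str],
    adj: Mapping[str, set[str]],
    zmap: Mapping[str, float],
    bg: BackgroundModel,
) -> tuple[set[str], float, float]:
    """Zero-temperature polish: apply improving moves until none remain.

    Two deterministic move families, swept in lexicographic order until a
    joint fixpoint: single-node toggles, and branch drops — restricting the
    set to one connected component of ``members - {v}`` (with or without v),
    which can excise in one move a whole branch that single-node removals
    cannot reach because its connector is an articulation point. Returns
    (members, raw, corrected). Complements the stochastic phase, which
    tends to end in a superset of the optimum.
    """

    def _score(mset: set[str], total: float) -> float | None:
        return _corrected_or_none(total / math.sqrt(len(mset)), len(mset), bg)

    members = set(members)
    sum_z = sum(zmap[m] for m in members)
    cur = _score(members, sum_z)
    if cur is None:
        return members, sum_z / math.sqrt(len(members)), float("nan")

    def _components(mset: set[str]) -> list[set[str]]:
        out = []
        left = set(mset)
        while left:
            start = left.pop()
            comp = {start}
            stack = [start]
            while stack:
                c = stack.pop()
                for nb in adj[c]:
                    if nb in left:
                        left.discard(nb)
                        comp.add(nb)
                        stack.append(nb)
            out.append(comp)
        return out

    improved = True
    while improved:
        improved = False
        # single-node toggles
        frontier = {nb for m in members for nb in adj[m]} - members
        for node in sorted(members | frontier):
            k = len(members)
            if node in members:
                if k == 1 or not _connected_after_removal(members, adj, node):
                    continue
                new_set, new_sum = members - {node}, sum_z - zmap[node]
            else:
                if not (adj[node] & members):
                    continue
                new_set, new_sum = members | {node}, sum_z + zmap[node]
            new_score = _score(new_set, new_sum)
            if new_score is not None and new_score > cur + 1e-12:
                members, sum_z, cur = new_set, new_sum, new_score
                improved = True
        # branch drops around articulation points
        for node in sorted(members):
            if len(members) < 3:
                break
            rest = members - {node}
            comps = _components(rest)
            if len(comps) < 2:
                continue
            best_alt = None
            for comp in comps:
                for cand in (comp, comp | {node}):
                    total = sum(zmap[m] for m in cand)
                    s = _score(cand, total)
                    if s is not None and (best_alt is None or s > best_alt[2]):
                        best_alt = (cand, total, s)
            if best_alt is not None and best_alt[2] > cur + 1e-12:
                members, sum_z, cur = set(best_alt[0]), best_alt[1], best_alt[2]
                improved = True
    return members, sum_z / math.sqrt(len(members)), cur


def _random_connected_seed(
    universe: list[str], adj: Mapping[str, set[str]], size: int, rng: np.random.Generator
) -> set[str]:
    """Grow a connected seed set by random frontier expansion."""
    start = universe[int(rng.integers(len(universe)))]
    members = {start}
    while len(members) < size:
        frontier = sorted(
            {nb for m in members for nb in adj[m]} - members
        )
        if not frontier:
            break
        members.add(frontier[int(rng.integers(len(frontier)))])
    return members


def find_active_subnetwork(
    net: AnnotatedNetwork,
    zs: NodeScores,
    bg: BackgroundModel,
    cfg: SAConfig,
    restrict_to: Iterable[str] | None = None,
) -> SubnetworkResult:
    """Search for the highest-scoring connected sub-network by annealing.

    The step budget is split over ``cfg.n_restarts`` independent annealing
    runs, each from a fresh random connected seed. One move: a node is
    chosen uniformly among the admissible toggles — current members plus
    their frontier (non-members adjacent to the set); toggling any other
    node could only disconnect the set. Removals that would disconnect (or
    empty) the set are rejected. Improving moves are always accepted; a
    worsening move with corrected-score change delta < 0 is accepted with
    probability exp(delta / T) under the geometric schedule. Each run is
    punctuated by zero-temperature quenches (greedy toggles plus branch
    drops) that polish the current state; the best state encountered across
    all runs and quenches is returned.
    """
    zmap, _dropped = zs.align(net, missing="zero")
    if restrict_to is not None:
        restrict = {canonicalize_id(x) for x in restrict_to}
        unknown = restrict - set(net.node_ids)
        if unknown:
            raise StpnetError(f"restrict_to names unknown nodes: {sorted(unknown)[:3]}")
        universe = sorted(restrict)
    else:
        universe = net.node_ids
    if not universe:
        raise StpnetError("empty search universe")
    uset = set(universe)
    adj = {n: (net.neighbors(n) & uset) for n in universe}

    rng = np.random.default_rng(cfg.seed)
    total_steps = cfg.n_steps if cfg.n_steps is not None else 100 * len(universe)
    n_restarts = min(cfg.n_restarts, total_steps)
    seg_steps = total_steps // n_restarts
    ratio = cfg.t_end / cfg.t_start

    best_members: set[str] | None = None
    best_score = -math.inf
    best_raw = 0.0
    trace: list[tuple[int, float]] = []
    step0 = 0  # global step offset for the trace

    def _note_best(mset: set[str], raw: float, score: float, at: int) -> None:
        nonlocal best_members, best_score, best_raw
        if best_members is None or score > best_score:
            best_members, best_raw, best_score = set(mset), raw, score
            trace.append((at, score))

    for _restart in range(n_restarts):
        members = _random_connected_seed(
            universe, adj, min(cfg.start_size, len(universe)), rng
        )
        sum_z = sum(zmap[m] for m in members)
        k = len(members)
        cur = _corrected_or_none(sum_z / math.sqrt(k), k, bg)
        # a degenerate starting size is repaired by shrinking
        while cur is None and k > 1:
            victim = sorted(members)[0]
            if not _connected_after_removal(members, adj, victim):
                break
            members.discard(victim)
            sum_z -= zmap[victim]
            k -= 1
            cur = _corrected_or_none(sum_z / math.sqrt(k), k, bg)
        if cur is None:
            raise DegenerateBackgroundError(
                "background degenerate at all reachable sizes"
            )
        _note_best(members, sum_z / math.sqrt(k), cur, step0)

        # incremental candidate bookkeeping: members and frontier as
        # swap-remove lists, plus per-node counts of member neighbours
        mem_list: list[str] = []
        mem_pos: dict[str, int] = {}
        fr_list: list[str] = []
        fr_pos: dict[str, int] = {}
        n_in: dict[str, int] = {}

        def _drop(lst: list, pos: dict, node: str) -> None:
            i = pos.pop(node)
            last = lst[-1]
            lst[i] = last
            lst.pop()
            if last != node:
                pos[last] = i

        def _push(lst: list, pos: dict, node: str) -> None:
            pos[node] = len(lst)
            lst.append(node)

        def _rebuild(new_members: set[str]) -> None:
            nonlocal members, sum_z, k, cur, mem_list, mem_pos
            nonlocal fr_list, fr_pos, n_in
            members = set(new_members)
            sum_z = sum(zmap[m] for m in members)
            k = len(members)
            cur = _corrected_or_none(sum_z / math.sqrt(k), k, bg)
            mem_list = sorted(members)
            mem_pos = {n: i for i, n in enumerate(mem_list)}
            n_in = {n: 0 for n in universe}
            for m in members:
                for nb in adj[m]:
                    n_in[nb] += 1
            fr_list = sorted(
                n for n in universe if n_in[n] > 0 and n not in members
            )
            fr_pos = {n: i for i, n in enumerate(fr_list)}

        _rebuild(members)
        quench_every = max(1, seg_steps // 4)
        for i in range(seg_steps):
            if i and i % quench_every == 0:
                q_members, q_raw, q_score = _quench(members, adj, zmap, bg)
                if not math.isnan(q_score):
                    _note_best(q_members, q_raw, q_score, step0 + i)
                    if q_score > cur:
                        _rebuild(q_members)
            n_mem, n_fr = len(mem_list), len(fr_list)
            r = int(rng.integers(n_mem + n_fr))
            if r < n_mem:
                node = mem_list[r]
                if k == 1:
                    continue
                if not _connected_after_removal(members, adj, node):
                    continue
                new_sum = sum_z - zmap[node]
                new_k = k - 1
                removing = True
            else:
                node = fr_list[r - n_mem]
                new_sum = sum_z + zmap[node]
                new_k = k + 1
                removing = False
            new_score = _corrected_or_none(new_sum / math.sqrt(new_k), new_k, bg)
            if new_score is None:
                continue
            delta = new_score - cur
            if delta <= 0:
                T = cfg.t_start * ratio ** (i / seg_steps)
                if rng.random() >= math.exp(delta / T):
                    continue
            if removing:
                members.discard(node)
                _drop(mem_list, mem_pos, node)
                for nb in adj[node]:
                    n_in[nb] -= 1
                    if n_in[nb] == 0 and nb not in members and nb in fr_pos:
                        _drop(fr_list, fr_pos, nb)
                # node had >= 1 member neighbour (the set was connected)
                _push(fr_list, fr_pos, node)
            else:
                members.add(node)
                _drop(fr_list, fr_pos, node)
                _push(mem_list, mem_pos, node)
                for nb in adj[node]:
                    if n_in[nb] == 0 and nb not in members:
                        _push(fr_list, fr_pos, nb)
                    n_in[nb] += 1
            sum_z, k, cur = new_sum, new_k, new_score
            if cur > best_score:
                _note_best(members, sum_z / math.sqrt(k), cur, step0 + i + 1)

        # end-of-run quench from both the current and the best state
        for state in (members, best_members):
            q_members, q_raw, q_score = _quench(set(state), adj, zmap, bg)
            if not math.isnan(q_score):
                _note_best(q_members, q_raw, q_score, step0 + seg_steps)
        step0 += seg_steps

    assert best_members is not None
    return SubnetworkResult(
        members=frozenset(best_members),
        raw_score=best_raw,
        corrected_score=best_score,
        k=len(best_members),
        best_trace=trace,
        seed=cfg.seed,
    )


def iterated_search(
    net: AnnotatedNetwork,
    zs: NodeScores,
    bg: BackgroundModel | None,
    cfg: SAConfig,
    passes: int = 2,
    bg_n_samples: int = 1000,
) -> list[SubnetworkResult]:
    """Run the annealing search ``passes`` times in series.

    Each pass restricts the search universe to the previous pass's members
    and recalibrates the background on that restricted universe, so that a
    large first-pass module can be refined down to its most active core.
    ``bg`` (if given) is used for the first pass; passes stop early with a
    warning once a result drops below two members.
    """
    if passes < 1:
        raise StpnetError("passes must be >= 1")
    results: list[SubnetworkResult] = []
    universe: set[str] | None = None
    for m in range(passes):
        if universe is not None and len(universe) < 2:
            warnings.warn(f"pass {m}: universe below two nodes, stopping early")
            break
        if m == 0 and bg is not None:
            bg_m = bg
        else:
            pool = universe if universe is not None else set(net.node_ids)
            zmap, _ = zs.align(net, missing="zero")
            sub = {g: zmap[g] for g in pool}
            bg_m = calibrate_background(
                sub, max_k=len(sub), n_samples=bg_n_samples, seed=cfg.seed + m
            )
        cfg_m = SAConfig(
            t_start=cfg.t_start,
            t_end=cfg.t_end,
            n_steps=cfg.n_steps,
            seed=cfg.seed + m,
            start_size=cfg.start_size,
        )
        res = find_active_subnetwork(net, zs, bg_m, cfg_m, restrict_to=universe)
        results.append(res)
        universe = set(res.members)
    return results


def shared_interactors(
    result: SubnetworkResult, net: AnnotatedNetwork, hubs: Sequence[str]
) -> dict[frozenset[str], set[str]]:
    """Sub-network members adjacent to both hubs of each hub pair."""
    hubs = [canonicalize_id(h) for h in hubs]
    out: dict[frozenset[str], set[str]] = {}
    for i, hi in enumerate(hubs):
        ni = net.neighbors(hi) if net.has_node(hi) else set()
        for hj in hubs[i + 1 :]:
            nj = net.neighbors(hj) if net.has_node(hj) else set()
            shared = (ni & nj & set(result.members)) - {hi, hj}
            out[frozenset((hi, hj))] = shared
    return out


def module_score_significance(
    result: SubnetworkResult,
    zs: NodeScores,
    bg: BackgroundModel,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the found module's corrected score.

    Gene labels of the z-scores are permuted and the fixed member set is
    re-scored; the p-value is the fraction of permutations reaching the
    observed corrected score (add-one correction).
    """
    rng = np.random.default_rng(seed)
    z = np.array([zs.z_scores[g] for g in sorted(zs.z_scores)], dtype=float)
    k = result.k
    exceed = 0
    for _ in range(n_permutations):
        sample = rng.choice(z, size=k, replace=False)
        raw = sample.sum() / math.sqrt(k)
        c = _corrected_or_none(raw, k, bg)
        if c is not None and c >= result.corrected_score:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1)
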