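# Methods

## Network model

A PPI network is an undirected simple graph over canonicalized protein
identifiers (trimmed, uppercased). Node annotations carry a display name,
hub and transcription-factor flags, free-text notes and literature
references; edges carry a category (`physical` or `functional`), an
optional direction hint and references. Direction hints are annotation
only: curated kinase networks record plausible information flow (e.g.
through a shared transcription factor), but the underlying evidence —
two-hybrid interactions, co-purification — is symmetric, so all topology
operations treat edges as unordered pairs. Self-loops are rejected by
default (`drop` discards them instead); duplicate records collapse under
unordered equality, concatenating references. Merging networks is a union
by canonical id with flags OR-ed — the "super-network through shared
proteins" construction used when hub-wise curated sub-networks are
combined.

## Order-k interactions

With the adjacency matrix A (symmetric, zero diagonal), (Aᵏ)ᵢⱼ counts
length-k walks. Because walks revisit vertices ((A²)ᵢᵢ is the degree, not a
meaningful "self-interaction"), the enumeration API defaults to simple
paths:

* order-2 intermediates of (i, j): common neighbours excluding the
  endpoints; for i ≠ j the count equals (A²)ᵢⱼ exactly;
* order-3 intermediates: ordered pairs (x, y) with edges i–x, x–y, y–j,
  x ≠ y, endpoints excluded; for i = j this set is empty by definition.
  Raw walk counts remain available through `matrix_power` since the two
  views differ (a triangle has a 3-walk from a node to itself but no simple
  3-path).

Per-hub partner sets at order k come in two policies: `walks` (any node
with a length-k walk from the hub) and `simple_new` (additionally excluding
nodes reachable at a shorter order — the proteins genuinely first reached
at order k). The hub-pair table at k = 2 uses intermediate counts
off-diagonal and the `simple_new` partner count on the diagonal; the
diagonal definition is an interpretation choice, since a walk-count
diagonal would merely restate hub degree. k is capped at 3; higher orders
blur into the whole network for hub-centric topologies.

## Hub overlap and TF statistics

The Venn partition assigns each non-hub protein adjacent to ≥ 1 hub to the
exact subset of hubs it touches; with four hubs that is up to 15 disjoint
regions, aggregated by cardinality into the 13-position view (four single
regions plus the "exactly two", "exactly three" and "all four" classes).
Hubs are never partners of other hubs; hub–hub adjacency is reported
separately. TF shares are per-hub fractions of all TF–hub adjacencies,
reported to one decimal place; multi-hub TF counts are computed over TF
nodes only. Cross-network comparison reports shared edges, edge Jaccard,
per-hub shared-neighbour counts, and how many proteins in the other network
touch more than one hub — the quantity that distinguishes an integrated
multi-hub reconstruction from single-bait screens.

## Active sub-network search

### Scoring

Per-gene p-values (from any upstream differential-expression analysis) are
clamped to [ε, 1−ε], ε = 10⁻¹⁶, and converted as z = Φ⁻¹(1 − p), so
small p ⇒ large positive z and the uniform null maps exactly to N(0, 1). A
connected k-gene set s scores Zs = Σ z⁄√k — the variance-stabilised
aggregate under which iid-null sets of every size score N(0, 1). Genes
scored but absent from the network are dropped (logged); network nodes
without scores default to z = 0 (configurable to an error).

### Background correction

μₖ and σₖ are the Monte-Carlo mean and standard deviation of Zs over
random size-k gene samples drawn **with replacement** from the scored
genes (1000 samples per k by default; connectivity deliberately not
required). The bootstrap, rather than subset sampling, is a deliberate
choice: drawing subsets without replacement from a universe of N genes
shrinks σₖ by the finite-population factor √((N−k)/(N−1)), which vanishes
as k → N and makes any near-universe set appear arbitrarily significant —
on a 200-gene benchmark the search then returns half the network. The
bootstrap keeps σₖ near the population standard deviation at every k, so
corrected scores of small and large sets are comparable. Implementation:
one draw matrix per calibration, prefix sums giving every k at once. The
corrected score is Zs′ = (Zs − μₖ)/σₖ; σₖ = 0 (all scores equal) is a
documented degenerate case — the public API raises, and the search treats
such states as score 0 when Zs = μₖ.

### Annealing

The search universe is the (optionally restricted) node set; moves toggle
the membership of a node drawn uniformly from the current members and
their frontier — the only toggles that can preserve connectivity — and
removals that would disconnect the induced subgraph are rejected
(connectivity by move rejection, checked by BFS). Improving moves are
always accepted; a move worsening the corrected score by Δ < 0 is accepted
with probability exp(Δ/T) under geometric cooling
Tᵢ = t_start·(t_end/t_start)^(i/n). Defaults: t_start = 1, t_end = 0.01,
total budget n = 100 × |universe| moves, initial state a random connected
seed of 5 nodes.

Two refinements address the rugged landscape of sparse graphs. First, the
budget is split over 10 independent restarts so distinct basins are
sampled. Second, each run is punctuated by zero-temperature quenches:
greedy single-node toggles plus *branch drops* — replacing the state by
the best-scoring connected component of `members − {v}` (with or without
v) over all members v. Branch drops matter because on tree-like regions
every interior node is an articulation point, so a low-value branch can
never be shed by single-node removals once its connector is inside the
set. The best state encountered anywhere (by corrected score) is returned
together with its improvement trace; the whole search is a pure function
of (inputs, seed).

### Two-pass iterated search

Aggregate-score module finding is known to return large first modules: any
connected cluster of mildly positive genes raises Zs, and under a uniform
null half of all genes have z > 0, so on graphs of mean degree ≥ 3 the
positive genes percolate into one giant cluster that the optimum absorbs.
The iterated search therefore re-runs the search inside the first-pass
members, recalibrating the background on that restricted universe. The
recalibration is essential: against the global background the best subset
of a module is the module itself, whereas against the within-module
background (mean z̄ of the module, not of the network) only genes hotter
than their module-mates raise the corrected score, and the search
contracts to the most active core. Passes stop early (with a warning) if a
result drops below two members. An optional permutation utility reports a
significance level for a found module's corrected score against relabelled
gene sets.

## Synthetic data

The network generator builds four hubs and, for every hub subset, exactly
the prescribed number of partners adjacent to precisely those hubs, then
tops each hub up with exclusive partners to hit its degree exactly —
degrees and overlaps are satisfied by construction, not in expectation.
Optional second-shell nodes attach to a uniformly chosen non-hub node
(a random recursive tree hanging off the partner layer), and optional
partner–partner edges add cycles; neither touches hub degrees or Venn
regions. TF flags follow either a fraction or an exact per-region plan.
Expression data: null genes draw p ~ Uniform(0,1); planted module genes
draw z* ~ N(effect_mean, effect_sd) and report p = 1 − Φ(z*), so the p→z
conversion recovers z* exactly. Planted modules grow by seeded random
frontier expansion and are connected by construction; the two-level
variant nests a hot core (full effect) inside a warm module (half effect).

Two presets define the study conditions:

* `curated_like` — the curated-geometry fixture: hub degrees 241/129/300/98,
  total pairwise overlaps 5/10/7/7/3/6 (Snf1–Tor1, Snf1–Pka1, Snf1–Hog1,
  Tor1–Pka1, Tor1–Hog1, Pka1–Hog1), one Snf1/Tor1/Pka1 and one
  Snf1/Pka1/Hog1 triple partner, one partner shared by all four hubs, and
  11 partner–partner edges, giving 739 nodes and 779 edges. 44 TFs are
  placed so that five touch exactly two hubs, two touch three, and the
  per-hub TF-neighbour counts are 22/17/7/7 — with 53 TF–hub adjacencies
  one adjacency is worth 1.9 percentage points, so the shares
  (41.5/32.1/13.2/13.2) match published-style rounded percentages to
  within a single adjacency step.
* `benchmark` — a 200-node network for recovery studies: hub degrees
  12/9/14/10, small overlaps, a 159-node shell tree, no extra edges (mean
  degree ≈ 2). The sparsity is what keeps planted-module recovery
  well-posed: at mean degree ≥ 3 the positive-z null genes percolate and
  the score optimum is a large diffuse set regardless of the search.

What the generator does **not** emulate: scale-free degree distributions,
correlated expression noise, annotation errors, or incomplete coverage of
the score table. Passing recovery tests therefore demonstrate that the
search optimises its objective and that the objective identifies coherent
planted signals on sparse topologies — not that modules in a dense real
interactome are uniquely determined.

## Numerical choices and degenerate inputs

* p-value clamp ε = 10⁻¹⁶; `isf` rather than `ppf(1−p)` for tail accuracy.
* σ ≤ 10⁻¹² treated as exactly zero (accumulated rounding in prefix sums).
* Node iteration is lexicographic everywhere; candidate draws use a single
  `numpy` generator per search, so results are invariant to
  order-preserving relabelling and fully reproducible under the seed.
* Quench acceptance requires improvement > 10⁻¹², preventing cycling on
  ties.
* Empty networks, empty search universes, oversized module requests and
  infeasible generator configurations raise typed errors before any work.

## Known limitations

* The aggregate score Σz/√k has no parsimony pressure: a gene adjacent to
  a k-member module joins the optimum whenever its z exceeds roughly
  Zs·(√(k+1)−√k)·√k ≈ Zs/(2√k) (about 1.3 for a strong 10-gene module),
  and net-positive blocks reachable through cheap bridges join as well.
  Found modules are therefore systematically supersets of a planted truth,
  with a halo whose size depends on the null draws; the two-pass search
  mitigates but does not eliminate this. The recovery benchmarks report
  exact-overlap statistics against planted truth and should be read with
  that behaviour in mind.
* Background calibration assumes exchangeable gene scores; structured
  confounding (e.g. degree-correlated expression variance) is not
  modelled.
* The binary matrix is dense; the implementation targets curated networks
  of order 10³ nodes, not genome-scale interactomes.
* Order-k analysis is capped at k = 3 and unweighted; no shortest-path or
  centrality machinery beyond degree.
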