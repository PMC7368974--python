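# Methods

This note documents the model conventions, algorithmic details, numerical
choices, and the synthetic test bed behind `nild`.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Graph model and metric conventions

Graphs are undirected and simple (no self-loops or parallel edges), held in
`networkx.Graph`; node identifiers are opaque but must be mutually orderable,
because **all iteration and tie-breaking is by ascending identifier** — this
single rule makes every algorithm in the package deterministic.

* **LCC.** `LCC(v) = n_v / C(d(v), 2)` with `n_v` the number of edges among
  `v`'s neighbors.  A node of degree < 2 has LCC 0: its neighborhood admits no
  pairs, and "no clustering" is the conservative reading that keeps the
  objective defined for leaves and isolates.  Both the batch and the
  incremental code paths evaluate the same expression `n_v / C(d, 2)` from
  integer counts, so their floats agree bitwise.
* **Betweenness** is exact shortest-path betweenness (Brandes, via networkx),
  endpoints excluded, normalized by `C(n−1, 2)` so thresholds such as
  `ω_b = 0.01` are scale-free across graph sizes.
* **Closeness** uses the Wasserman–Faust form
  `(r−1)/Σd · (r−1)/(n−1)` over the `r` nodes reachable from `v`: unreachable
  nodes penalize the score, isolated nodes get 0.  These are declared
  conventions — the underlying formulation does not fix a normalization.
* Centralities are always **recomputed exactly** on the current graph when an
  algorithm needs them (no approximation, no incremental patching); only the
  triangle-based quantities are maintained incrementally.

**A caveat on closeness monotonicity.** Within a connected graph, adding an
edge can only shrink distances, so closeness is non-decreasing for every node
— the randomized suites use connected graphs and assert exactly this for the
targets.  On *disconnected* graphs the reachable-component scaling breaks the
guarantee: an edge that attaches a far-away component enlarges `r` but can
inflate `Σd` enough to lower the score of nodes distant from the attachment
point.  The property is therefore claimed, and tested, for connected graphs
only.

## Constraint semantics

* The degradation cap `τ` is **cumulative**: every node's LCC on the augmented
  graph is compared with its LCC on the *original* graph, never edge-by-edge.
  All greedy loops enforce it constructively (a candidate edge is committed
  only if the cumulative increments of its affected nodes stay within `τ`),
  so every emitted plan satisfies the cap by construction; `check_tau`
  re-verifies it independently by full recomputation.
* The centrality floors are **strict** (`> ω`).  Instances whose floors are
  unreachable are not errors: algorithms return a best-effort plan and the
  `FeasibilityReport` carries the failure with signed margins.
* **The budget is a cap, not a quota.**  Adding the last affordable edge can
  *raise* the objective (the new neighbor may close triangles at the target),
  so all algorithms treat `k` as an upper bound: the single-target greedy
  returns the best prefix of its runs, the level sweep competes every prefix
  of every level, and the exhaustive search ranges over all sizes ≤ `k` with
  ties preferring fewer edges.  This choice is load-bearing for the
  equivalence between the greedy and the enumerated optimum on threshold
  graphs.

## Single-target greedy (CRPD)

One pass keeps a candidate pool `C` (non-neighbors of `t` individually
addable within `τ`), commits the minimum-degree member, then moves every
member whose addition would now violate `τ` into a reject set `R`.  Two
refinements:

* **MISS.** While `t`'s betweenness or closeness sits below its floor,
  candidates are ranked by `w_b·b(u) + w_c·c(u) + w_d·d̃(u)` instead of
  minimum degree.  The weights are the clipped shortfalls
  `w_b = max(0, ω_b − b(t))`, `w_c = max(0, ω_c − c(t))`, rescaled to sum to
  at most 1, with `w_d = 1 − w_b − w_c`; the degree term is normalized by
  `n − 1` so the three terms share the `[0, 1]` scale (a flag restores raw
  degree).  Ties: smaller degree, then smaller identifier.
* **RNR.** After the pass, the minimum-degree member of `R` (original-graph
  degree, ties by identifier) is force-seeded as `t`'s first new link and the
  pass is rerun; the better outcome wins.  "Better" compares target LCC, then
  larger closeness, then larger betweenness; the first run is kept on full
  ties.  Only this single re-seed is explored.

On threshold graphs — graphs realizable as `f(i) + f(j) > t_G` for node
weights `f`, equivalently graphs dismantlable by repeatedly deleting an
isolated or dominating vertex — neighborhoods are nested, the min-degree
prefix of each size is optimal for that size, and the greedy's objective
equals the enumerated optimum; the test suite checks this over 100+ seeded
instances.

## Multi-target level sweep (OISA)

Intervention edges are drawn from within the target set (both endpoints in
`T`), the same universe the baselines search, keeping comparisons
apples-to-apples; option sets are defined inside `T` by construction.  A flag
on the exhaustive search widens its universe to one-endpoint-in-`T` for
exploratory use.

* **Level schedule (EORE).**  Candidate objective levels are
  `l_j = j / C(d̂_2k, 2)`, `j = 1, 2, …`, where `d̂_2k` is the maximum degree
  among the (up to) `2k` targets of largest baseline LCC — `k` edges can touch
  at most `2k` targets, so finer levels are pointless.  Levels run while
  `l_j` stays below the maximum baseline LCC of the whole graph (a flag
  restricts the roof to the targets).  For a node of baseline clustering `c`
  and degree `d`, reaching level `l` needs at least the smallest `k_t` with
  `c·d(d−1) ≤ l·(d+k_t)(d+k_t−1)` — added edges can only grow the
  denominator — solved in closed form via the quadratic root and then
  verified by unit steps so float rounding at the boundary cannot misreport.
  The per-graph need is `k_G = ⌈½ Σ_t max{k_t, ω_d − d(t)}⌉` (an edge serves
  at most two targets; the ceiling keeps it integral).  Levels with
  `k_G > k` are skipped — a level needing exactly `k` edges is admitted — and
  a level is aborted once some target's remaining need exceeds the remaining
  budget (`k − |F| + x_t < max{k_t, ω_d − d(t)}`).
* **Pairing (PONF).**  Each iteration pairs `m`, the target with maximal
  current LCC — ties resolved toward the *smallest optionality*, because a
  target with few safe partners only loses options as the graph densifies —
  with the largest-LCC member of `m`'s option set (MISS-ranked instead while
  one of `m`'s floors is unmet).  A fellow target is an *option* when it sits
  ≥ 3 hops away (no LCC can rise at all: the endpoints share no neighbors and
  their own clustering can only be diluted) or exactly 2 hops away with every
  common neighbor's cumulative increment within `τ`.  Distances and option
  sets are evaluated on the current, partially intervened graph, so options
  are valid at commit time.  The commit itself re-verifies the full
  cumulative cap over all affected nodes (the option definition guards only
  common neighbors; a 2-hop link can also lift an *endpoint's* clustering);
  an edge failing the commit check falls through to the next-ranked option,
  and the level is abandoned when none remains.
* **Acceleration (ALC).**  Clustering is maintained incrementally — an added
  edge `(m, u)` touches only `m`, `u`, and their common neighbors — and the
  max-LCC scan skips targets whose closed-form ceiling
  `max_{k1+k2=k} (n_v + k2 + k1·d + C(k1,2)) / C(d + k1, 2)` (capped at 1;
  the raw value may exceed 1) is already below the current maximum: such a
  node can never become the argmax, so the skip is exactness-preserving and
  `use_alc=False` (full batch recomputation, no skipping) returns the
  identical plan, which the suite asserts instance-by-instance.  The ceiling
  is *not* applied to the partner choice: the best partner need not carry a
  maximal LCC, so skipping there could change results.

The returned plan is the best recorded prefix across all levels (objective,
then fewer edges, then lexicographic edge list), which also means the sweep
never returns anything worse than doing nothing.

## Baselines

`bum` repeatedly links the two largest-LCC targets that remain
degradation-safe; `sim` links the top target to the farthest safe target
(infinite distance outranks all finite; ties prefer larger LCC, then smaller
identifier).  Both fall through to the next-ranked partner when a candidate
would breach the cap, use MISS ranking while the chosen target's floors are
unmet, and stop early when no safe partner exists.  `enum` exhausts every
edge set up to the budget, prefers floor-feasible plans, then smaller
objective, fewer edges, lexicographic order; it refuses (naming the count)
when the number of subsets exceeds a configurable cap, and serves as the
ground-truth lower envelope in the test suite.

Because `bum` and `sim` are themselves degradation-safe and MISS-equipped,
their gap to the level sweep on clustered fixtures is statistical rather than
per-instance: the suite asserts the mean-objective ordering over 100 seeded
planted instances and an at-least-as-good majority, not strict dominance.

## Synthetic test bed

* **Threshold graphs** draw `n` node weights uniformly from a seeded stream
  and set the threshold at a random quantile (0.15–0.85) of the pairwise
  sums; the realizing weights are stored so tests can check the defining
  biconditional directly, with the isolated-or-dominating-vertex dismantling
  characterization as an independent oracle.
* **Instance recipes** mirror standard practice for this problem family: the
  single-target recipe picks a node with LCC above 0.8 (falling back to the
  maximal-LCC node), the multi-target recipe samples 20% of the nodes from
  the top-40% LCC stratum; default constraints are `τ = 0.12`,
  `ω_b = 0.01`, `ω_c = 0.1`, no degree floor, and a budget of about 6% of
  the node count (single) or edge count (multi).  Generators retry with
  perturbed sub-seeds (bounded, warning) on degenerate draws — disconnected
  graphs or graphs without any clustering to intervene on.
* **Planted clustered instances** for the heuristic comparison are relaxed
  caveman graphs (cliques on a ring, edges rewired with probability 0.2):
  clique members start near-maximal LCC while distinct cliques sit several
  hops apart, the regime where proximity-blind pairing pays a degradation
  penalty.
* What the bed does **not** emulate: scale-free degree tails of large online
  networks, weighted or directed ties, temporal churn, and community overlap.
  Passing tests certify algorithmic correctness (bounds, exactness,
  constraint compliance, determinism) on small dense instances, not effect
  sizes on real social networks.

Test problem sizes are deliberately small — graphs of 8–30 nodes, budgets of
1–5 — because the exhaustive oracles (all edge sets of size ≤ 2 over the full
non-edge universe; brute-force enumeration up to `k = 3`) are what make the
correctness claims checkable at all; the algorithms themselves have no such
size restriction.

## Known limitations

* The single-target exactness guarantee is specific to threshold graphs; on
  general graphs the greedy carries no approximation guarantee (none can
  exist in polynomial time).
* The multi-target search never proposes edges leaving the target set, which
  can forgo better plans that recruit well-placed outsiders.
* Exact centrality recomputation after every committed edge is the dominant
  cost on large graphs; the package favors auditability over scale.
* Edge deletion is out of scope by design: removing existing ties would
  undermine established social support.
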