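# nild — network intervention by budgeted edge addition

`nild` computes **intervention edges** for social networks: new friendship
links that lower the *local clustering coefficient* (LCC) of one or more
targeted individuals without degrading the people around them.  A closed,
highly clustered ego network offers little fresh social input; adding a few
well-chosen links to structurally distant peers opens it up.  The package is
aimed at computational social scientists and behavioral-health researchers who
want reproducible, auditable link recommendations rather than ad-hoc
hand-picked ones.

## The optimization problems

For an undirected simple graph `G = (V, E)`, the LCC of a node `v` is

```
LCC_G(v) = |{(i, j) : i, j ∈ N_G(v), (i, j) ∈ E}| / C(d_G(v), 2)
```

(0 by convention when `d_G(v) < 2`).  Given a budget `k`, a degradation cap
`τ`, and centrality floors `ω_b`, `ω_c`, `ω_d`, the package solves

* **single target** `t`: add at most `k` edges incident to `t` minimizing
  `LCC_Ḡ(t)`,
* **multiple targets** `T`: add at most `k` edges minimizing
  `max_{t∈T} LCC_Ḡ(t)`,

subject to, on the augmented graph `Ḡ`:

1. `LCC_Ḡ(v) − LCC_G(v) ≤ τ` for **every** node `v` (cumulative, against the
   original graph),
2. `b_Ḡ(t) > ω_b`, 3. `c_Ḡ(t) > ω_c`, 4. `d_Ḡ(t) > ω_d` for every target
   (normalized betweenness, closeness, and degree floors).

Both problems are NP-hard and inapproximable, so the package ships greedy
algorithms with provable structure plus an exhaustive optimum for small
instances:

| algorithm | problem | idea |
|---|---|---|
| `crpd` | single | min-degree greedy with τ-pruning, re-selection of a pruned low-degree candidate (RNR), and blended betweenness/closeness/degree scoring while floors are unmet (MISS); exact on threshold graphs |
| `oisa` | multi | sweep of targeted LCC levels with closed-form minimum-edge bounds (EORE), poor-optionality-first pairing of high-LCC targets (PONF), and incremental LCC maintenance with a closed-form upper bound (ALC) |
| `bum` / `sim` | multi | greedy baselines: largest-LCC partner / farthest partner |
| `enum` | both | exhaustive optimum over all edge sets up to the budget (capped) |

## Worked example

Generate a seeded 16-node instance and open up its most clustered node:

```
$ nild gen --model erdos_renyi --n 16 --seed 3 --kind single \
       --out g.tsv --instance-out inst.yaml
wrote 16 nodes / 47 edges to g.tsv
wrote instance to inst.yaml

$ nild s --graph g.tsv --target 14 --k 3 --tau 0.12 --out plan.json
crpd: 3 edge(s), objective=0.2667, feasible=True
  + (14, 4)
  + (13, 14)
  + (14, 3)
```

Target `14` starts at LCC `0.667` (two thirds of its friend pairs already know
each other).  Three new links dilute its neighborhood to LCC `0.267` — the
`objective` line — while `feasible=True` certifies all four constraints: the
audit stored in `plan.json` shows the worst bystander's LCC rose by only
`0.036` (cap `0.12`), and the target's betweenness, closeness and degree all
sit above their floors (margins `+0.038`, `+0.525`, `+6`).  The same audit can
be reproduced later with `nild check --graph g.tsv --plan plan.json
--target 14 --k 3 --tau 0.12`.

Multi-target runs use a target file and select among algorithms:

```
nild m --graph g.tsv --targets targets.txt --k 4 --algo oisa --out plan.json
```

Everything is also available as a library (`nild.crpd`, `nild.oisa`,
`nild.bum`, `nild.sim`, `nild.enum_optimal`, `nild.make_instance`, …) working
on `networkx` graphs; see `docs/methods.md` for the model details and design
choices.

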