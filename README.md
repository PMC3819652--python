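# umcheck

Consistency checking and curation support for constraint-based metabolic
models.

Draft genome-scale metabolic reconstructions routinely contain
inconsistencies: reactions that can never carry flux (*blocked
reactions*) and dead-end *gap metabolites* that cannot reach a non-trivial
steady state. `umcheck` detects these defects, organises them into
*unconnected modules* that a curator can review one biochemical subsystem
at a time, uncovers the subtler *coenzyme pseudo-gap* situation, and
provides the downstream analyses used to validate a repaired model
(FBA, gene essentiality, minimal-medium prediction, reaction-subset
comparison). It is aimed at people building or curating genome-scale
models of, for example, reduced endosymbiont metabolisms, where manual
curation is still the norm.

## The method

Let `N` be the m x n stoichiometric matrix and `F = {v : N v = 0,
lb_j <= v_j <= ub_j}` the steady-state flux space. The core definitions:

* **Blocked reaction** — `j` is blocked iff `v_j = 0` for every `v` in
  `F`. Detected by solving, for each reaction, the two linear programs
  `min/max v_j over F` with every exchange flux opened to `[-M, M]`
  (the most permissive medium: anything blocked there is blocked under
  every medium); a reaction is blocked when both optima vanish.
* **Gap metabolite** — with `sigma_i = {j : N_ij != 0}`, metabolite `i`
  is a gap iff `sigma_i` is a subset of the blocked set. This one
  criterion covers root dead-ends *and* everything they silence, with no
  graph traversal heuristics.
* **Classification** — a gap with no admissible producing direction is
  root-non-produced (RNP); none consuming, root-non-consumed (RNC).
  Non-root gaps are downstream-non-produced (DNP) when a directed
  production path connects an RNP to them inside their module, and
  upstream-non-consumed (UNC) when they reach an RNC; ambiguous cases
  stay UNCLASSIFIED.
* **Unconnected module (UM)** — a connected component of the bipartite
  metabolite/reaction graph restricted to gaps and blocked reactions.
  Each UM is one coherent chunk of broken metabolism, reported with its
  dominant subsystem and RNP/RNC roots, and exportable as
  GraphML/GML/DOT for visual inspection.
* **Pseudo-gap** — a metabolite that is *not* a gap (it cycles in active
  reactions) yet blocks a pathway because a conserved moiety — a
  semi-positive left-null vector `y >= 0, y' N' = 0` of the unblocked
  column-scoped matrix — forbids its net production. Found by a sink
  test: temporarily drain the metabolite and see whether the blocked set
  shrinks.
* **Minimal medium** — the MILP `min sum_j y_j` over binary indicators
  on exchange fluxes with `v_j >= lb_j y_j` (so `y_j = 0` forbids
  uptake) and a positive biomass lower bound.
* **Reaction subsets** — groups of reactions with fixed flux ratios in
  every steady state, from proportional rows of an exact nullspace basis
  of the reduced (gap/blocked-free, biomass-relaxed) matrix; two models'
  decompositions are compared with the Jaccard index.

## Worked example

The bundled `fig2_network()` is the canonical pseudo-gap network: a
synthesis chain `A -> B -> C -> Cp -> D` feeding a cofactor pair D/D*
that only cycles (`D + S -> D* + P`, `D* + U -> D + W`).

```python
import umcheck as u

model, _ = u.fig2_network()
blocked, gaps = u.check_model(model)
print("blocked reactions:", sorted(blocked.blocked))
print("gap metabolites:", {m: gaps.classes[m] for m in sorted(gaps.gaps)})

graph = u.build_graph(model, blocked, gaps)
ums = u.find_ums(u.um_subgraph(graph, gaps, blocked), model, gaps)
print(u.um_table(ums).to_string(index=False))

findings = u.scan_pseudo_gaps(model, blocked, gaps)
for f in findings:
    print(f"pseudo-gap {f.metabolite_id}: sink frees {len(f.unblocks)} "
          f"reactions; moiety {sorted(f.relation.support)}")

repaired, delta = u.apply_repair(model, u.RepairAction("add_sink", "D"))
print("blocked after add_sink(D):", len(delta.blocked_after))
```

prints

```
blocked reactions: ['EX_A', 'v1', 'v2', 'v3', 'v4']
gap metabolites: {'A': 'UNCLASSIFIED', 'B': 'UNCLASSIFIED', 'C': 'UNCLASSIFIED', 'Cp': 'UNCLASSIFIED'}
 um subsystem  n_reactions  n_metabolites rnp rnc
  1         -            5              4   -   -
pseudo-gap D: sink frees 5 reactions; moiety ['D', 'Dstar']
pseudo-gap Dstar: sink frees 5 reactions; moiety ['D', 'Dstar']
blocked after add_sink(D): 0
```

The whole synthesis chain (including the uptake of A) is blocked and its
four intermediates are gaps, yet none is a root — no RNP/RNC exists, the
signature of a pseudo-gap cause. The scan pins the cause on the conserved
pair {D, D*}; granting either a drain (a sink, an exchange, or inclusion
in the biomass equation) unblocks all five reactions.

The same workflow is available from the shell:

```sh
umcheck fixtures --name fig2 --out fig2/
umcheck check fig2/ --out results/       # blocked.tsv, gaps.tsv
umcheck modules fig2/ --export results/graphs --format graphml --out results/
umcheck pseudogap fig2/ --out results/
```

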