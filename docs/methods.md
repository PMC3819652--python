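# Methods

## Model representation

A model is an ordered list of metabolites (rows) and reactions (columns)
with exact rational stoichiometric coefficients, per-reaction flux
bounds, a partition of the columns into internal reactions and exchange
fluxes, an optional biomass reaction and optional boolean
gene-protein-reaction (GPR) rules. Exchange fluxes are single-metabolite
pseudo-reactions written `A -> (outside)` with coefficient -1, so a
positive exchange flux is secretion and a negative one is uptake; a
medium is a set of bounds on exchange fluxes, and a metabolite is
available for uptake when its exchange lower bound is negative.

Coefficients are kept as `fractions.Fraction` so that the structural
analyses (nullspaces, conserved moieties, the brute-force oracles) run in
exact arithmetic; LP/MILP solving converts to floats. Infinite bounds in
input files are clamped to a configurable big bound `M` (default 1000
flux units) so every linear program has a finite optimum. Exchanges are
auto-detected as single-metabolite reactions when no explicit annotation
exists; an explicit TSV exchange sheet or SBML boundary-species
annotation wins over auto-detection.

## Blocked reactions and gaps

Blocked-reaction detection computes `min v_j` and `max v_j` over the
steady-state flux space for every reaction (scipy's HiGHS simplex,
primal/dual feasibility tolerances 1e-9) and declares `j` blocked when
both optima are below the zero threshold `eps = 1e-9`. The maximisation
runs first; when it already proves a nonzero flux the minimisation is
skipped, which cannot change the result. "Blocked under any medium" is
implemented by opening every exchange to `[-M, M]` before solving: this
most permissive medium minimises the blocked set, so membership there
implies membership under every medium. An explicitly supplied medium
replaces the bounds of the exchanges it lists.

Gap detection then needs no further optimisation: metabolite `i` is a
gap iff all reactions with a nonzero coefficient for `i` are blocked.
Metabolites appearing in no reaction at all are reported as gaps and
flagged as orphans.

Classification applies two stages. Root scan: `i` is RNP when no
reaction direction admissible under the bounds produces it — i.e. there
is no `j` with (`N_ij > 0` and `ub_j > 0`) or (`N_ij < 0` and
`lb_j < 0`) — and RNC symmetrically for consumption; reversible
reactions therefore participate through their admissible directions, not
a reversibility flag (a reversible consumer is also a potential
producer). Propagation: inside each unconnected module, a non-root gap
reachable from an RNP along directed production arcs is DNP, and one
that reaches an RNC along directed consumption arcs is UNC. A gap
matching both rules, or neither (as happens when the true cause is a
pseudo-gap, where no root exists), stays UNCLASSIFIED rather than being
guessed. Propagation is restricted to the gap's own module to avoid
cross-module artifacts. There is no universally agreed assignment rule
for networks with mixed roots; this two-stage formalisation with an
explicit UNCLASSIFIED fallback is this package's design choice.

## Unconnected modules

The network maps to a directed bipartite graph (arc metabolite->reaction
for consumption, reaction->metabolite for production; one arc per
nonzero coefficient, reversible reactions keeping their forward-written
arcs plus a flag). The subgraph induced by gaps and blocked reactions is
decomposed into weakly connected components — direction is ignored for
connectivity because a module rooted in a non-consumed metabolite has
all arcs pointing one way yet is a single unit of broken metabolism.
Exchange fluxes are nodes like any reaction and are counted in module
sizes. Modules are sorted by reaction count (descending, ties broken by
smallest member id) and numbered after sorting, so output is
deterministic. Each module reports its counts, RNP/RNC roots and the
most frequent non-empty subsystem annotation among its reactions ("-"
when absent).

## Pseudo-gaps and conserved moieties

Conserved moieties are the extreme rays of `{y >= 0 : y' N' = 0}` for a
column-scoped matrix `N'`. Enumeration uses the incremental
double-description method in exact rational arithmetic with the standard
combinatorial adjacency test; the same kernel, applied to the
(split-column) right cone, yields the elementary flux modes used by the
brute-force oracle. The default scope drops blocked columns first,
because a cofactor-pair moiety is typically broken by its own (blocked)
synthesis column and only conserved over the active subnetwork. Systems
wider than a configurable cap (default 120 columns after scoping) fall
back to a rational nullspace basis filtered for semi-positive vectors,
flagged as non-exhaustive in the result.

The pseudo-gap scan tests candidates with a temporary irreversible sink
(`met -> outside`, bounds `[0, M]`) on a copy of the model and reports a
finding whenever the recomputed blocked set shrinks, attaching the
number of freed reactions and any supporting moiety. Primary candidates
are non-gap metabolites adjacent to at least one blocked and one
unblocked reaction; the candidate set is extended with non-gap
metabolites sharing an unblocked-scope moiety with a primary candidate,
so both halves of a cofactor pair are reported even though one of them
touches no blocked reaction directly. This filter keeps the scan linear
in practice: a pure-gap cause is already reported by gap detection, and
a metabolite touching only unblocked reactions and no shared moiety
cannot unblock anything by sinking. The scan never mutates its input
(verified by fingerprint in the tests).

Repair actions are the elementary curation edits: add a sink or an
exchange, include a metabolite in the biomass equation (default
coefficient 1e-4 in flux-normalised units — an order-of-magnitude
placeholder for a trace biomass requirement, configurable), relax an
irreversibility, or add a bespoke reaction. Each application returns a
fresh model plus a delta report (blocked set and module count before and
after). Note that relaxing the irreversibility of a dead-end
metabolite's only reaction cannot unblock it — mass balance still pins
the flux to zero — it only changes the metabolite's root class; the
tests cover both this case and one where relaxation genuinely unblocks.

## Curation analyses

* **FBA** maximises (or minimises) a single reaction flux, by default
  the biomass reaction, over the flux space.
* **Knockouts**: for each gene, reactions whose GPR rule evaluates false
  with that gene deleted are bounded to zero and FBA is re-run; a gene
  is essential when the mutant optimum falls below 1% of wild type (the
  threshold is configurable; 1% cleanly separates "effectively zero
  growth" from numerically small but real growth at these model sizes).
  Genes absent from every GPR leave growth at wild type.
* **Minimal medium**: one binary `y_j` per exchange, linking constraint
  `v_j >= lb_j * y_j` (so `y_j = 0` only forbids uptake — secretion
  stays free), biomass bounded below by 10% of the wild-type optimum by
  default, objective `min sum y_j`, solved with scipy's HiGHS MILP. The
  MILP optimum certifies minimal cardinality.
* **Reaction subsets**: the stoichiometric matrix is reduced by deleting
  gap rows and blocked columns, removing the biomass column and granting
  each biomass reactant an independent irreversible drain (so the fixed
  biomass composition does not artificially couple the whole network);
  reactions whose rows in a nullspace basis of the reduced matrix are
  proportional form one subset, with the proportionality constants
  recorded as flux ratios relative to the first member. The kernel is
  exact (sympy rational nullspace) below 500 columns and an SVD
  nullspace with relative tolerance 1e-6 above. Only groups with at
  least two model reactions are reported; a negative ratio between two
  irreversible reactions flags the group as inconsistent.
* **Subset comparison**: all-pairs Jaccard index between two subset
  lists, greedy one-to-one matching on descending index, matched-pair
  counts reported at thresholds 1.0 and 0.75. Greedy matching is a
  documented choice; no canonical scheme exists for this report.
* **Model diff**: set differences of gene, reaction, exchange and
  biomass-component identifiers.

## Synthetic fixtures and oracles

The three reference networks encode the canonical defect types: a
missing producer (RNP root propagating DNP gaps downstream), a missing
consumer (RNC root, UNC gaps upstream), and a cofactor loop pseudo-gap.
Their planted truths (blocked sets, gap classes, module memberships,
pseudo-gaps) are fixed by construction and re-derived independently by
the oracles.

The random generator plants 0-5 such structures on an active backbone
(two open uptakes feeding internal chains consumed by a biomass
reaction). Planted modules are metabolite-disjoint from each other and
touch the backbone only through a shared attachment metabolite that is
itself never a gap, so the planted structures are provably the connected
components of the gap/blocked subgraph; metabolite and reaction order
are deterministically shuffled per seed so detector output cannot depend
on insertion order. Default sizes (1-3 reactions per planted chain,
backbone of a few reactions, big bound 1000) keep each model inside the
exact oracles' reach. The generator makes no attempt at genome-scale
topology statistics (degree distributions, currency-metabolite hubs), so
agreement on these fixtures demonstrates correctness of the detection
logic, not performance or numerical behaviour on genome-scale networks
— for those, the LP detector is the tool and the published model file is
the input.

Two oracles close the loop without touching the code paths they check:
blocked sets by double-description enumeration of all elementary flux
modes of the split network (a reaction is blocked iff no mode other than
its own forward/backward two-cycle uses it; exact arithmetic, capped at
24 split columns), and minimal media by exhaustive subset search over
exchanges (capped at 8), smallest cardinality first.

## Problem sizes and determinism

The shipped analyses run on deliberately small instances: 100 random
models of at most 12 reactions for the oracle-agreement battery, 50
seeded models for planted-module recovery, 200 random objectives for
subset proportionality. These sizes keep the exact oracles exhaustive
while exercising every code path; all randomness flows through a single
seed, and identical invocations produce identical outputs.

## Known limitations

* No gap-filling against universal reaction databases; the tool
  proposes and scores elementary repairs but does not search external
  reaction sets.
* No thermodynamic bounds, loopless FBA, flux sampling, double
  knockouts, or quadratic objectives.
* Double-description enumeration is exponential in the worst case; the
  caps above are deliberate, and genome-scale moiety audits should use
  the scoped (unblocked-only) matrix.
* The DNP/UNC propagation rule is a formalisation choice; networks with
  interleaved RNP and RNC roots can legitimately yield UNCLASSIFIED
  gaps, which is reported rather than resolved by guesswork.
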