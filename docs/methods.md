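# Methods

## Model and assumptions

`ecopgraph` treats ecosystem assembly as a process-network synthesis
problem. The ecosystem is a bipartite digraph over services (M-type nodes)
and functional units (O-type nodes); every input of a unit is *necessary*
(inputs are conjunctive), while a service produced by several units may be
provided by any non-empty subset of them (producers are disjunctive). The
framework is steady-state and purely structural: feasibility depends only
on connectivity, never on flow magnitudes, stoichiometric ratios, costs or
dynamics. Those are explicit non-goals, as are ranked/optimized structure
search and weighted (preference-elicited) criticality — the
`CriticalityReport` is the documented extension point for the latter.

Service roles are **declared**, not inferred. A declared-exogenous service
that some unit produces is a validation error (the exogeneity axiom SE2 is
a biconditional; silent reclassification would hide modelling mistakes). An
undeclared role defaults to `intermediate` with a warning. Roles are
exclusive: a service cannot be both exogenous and terminal. Node names are
case-sensitive, trimmed, and restricted to `[A-Za-z0-9_.-]+` so CSV/DOT/
GraphML outputs round-trip without quoting.

Two deliberately permissive choices, each emitting a warning rather than an
error: units with no inputs are allowed (one may model an energy source as
a unit rather than an exogenous service), and a unit may list the same
service as both input and output (self-recycling); such a service counts as
*produced* for SE2.

## Feasibility checking

`is_feasible_structure` evaluates, for a unit subset `U` with induced
service set `m`:

* **SE1** — every terminal service is in `m`;
* **SE2** — each service in `m` is exogenous iff no unit in `U` outputs it
  (so every non-exogenous induced service needs an included producer, and
  no exogenous service may be produced);
* **SE4** — every unit in `U` reaches a terminal service by breadth-first
  search over `unit → output service → consuming unit ∈ U` arcs;
* **SE5** — holds by construction, since `m` is always induced from `U`.

Outputs consumed by nobody are legal: a dangling non-terminal output simply
behaves as a *de facto* terminal component (e.g. prey biomass left
unconsumed when the predator is absent). Feasibility is **not** monotone
under unit addition — an added unit whose inputs are unproducible violates
SE2 — and the test suite pins this with an explicit counterexample.

## MSG: maximal structure generation

Phase 1 (*reduction*) deletes, to a fixpoint: non-exogenous services with
no surviving producer, units consuming a deleted service, units producing
an exogenous service, and services incident to no surviving unit. Every
deletion is forced (the node can occur in no feasible structure), which
makes the fixpoint unique; order-confluence is exercised in the tests by
shuffling the processing order. Phase 2 (*composition*) closes backward
from the terminal services — include every surviving producer of each
needed service, mark the included units' non-exogenous inputs as needed —
then drops included units that fail SE4 or lose a producer, and re-closes
until stable. Both phases are worklist-based and polynomial; recursion
depth never scales with the graph.

If some terminal service ends with no producer, the maximal structure is
**empty**, returned as a regular value with an explicit marker (`is_empty`,
`COLLAPSED` in the CLI): ecosystem collapse is a finding, not a failure.
Composition treats all terminal services as needed simultaneously, so
multi-product models are supported even though the shipped case study has
one. The defining property — the maximal structure equals the union of all
solution structures — is asserted against the enumeration on hundreds of
seeded random models.

## SSG: solution structure generation by decision mapping

Enumeration runs inside the maximal structure (the MSG pre-pass prunes
units that occur in no feasible structure). The search state holds the
included units, the *excluded* units, and the services pending a production
decision (initially the terminal services; selection is lexicographic by
name for reproducible traversal). Deciding service `s` branches over every
non-empty producer subset that (a) contains all already-included producers
of `s` and (b) avoids excluded units; producer-subset order is ascending
bitmask over name-sorted producers. Producers of `s` left out of the chosen
subset are excluded for the whole branch — this is the decision-mapping
discipline that makes later decisions consistent with earlier ones and
guarantees each structure is emitted on exactly one branch, with no
post-hoc deduplication. Newly included units queue their not-yet-decided,
non-exogenous inputs; a branch dies when a pending service has no
permissible producer. Because decisions are per-service and order-free,
cyclic dependency loops (pollination; the detritus → soil-nutrient loop)
enumerate correctly, and the cyclic case study serves as the regression
case.

With backward construction SE4 holds on every emitted leaf by an induction
on inclusion order; a full axiom sweep is nevertheless kept at emission as
a cheap safety assertion (a hit is reported as a warning and would indicate
a defect, never silently dropped). Emitted/pruned/expanded branch counts
are recorded and must account for every created search node.

Results are canonically ordered by unit-set size, then lexicographically on
sorted unit names, and labelled `S1..SN` in that order. These labels are
this package's own convention; published structure tables for the same
model may number the same set of structures differently, so comparisons
should be on unordered unit sets (the acceptance tests compare exactly
that). The enumeration cap defaults to 100 000 structures and *raises* on
overflow — a partial enumeration is never returned silently; an explicit
flag downgrades the overflow to a warning with `truncated=True`.

`brute_force` is the independent oracle: it tests all `2^|O|` subsets
against the axiom checker directly, guarded at 20 units. The core
correctness property of the package — decision mapping ≡ exhaustive subset
test — is asserted on 500 seeded random models (3–12 units) in the test
suite, alongside duplicate-freeness, the union property, and the knockout
counting identity.

## Criticality and knockout

`IC_i = N_i / N` is computed as an exact rational; class boundaries are
exact 0 (expendable) and 1 (indispensable), which is safe because no
floating point is involved until formatting. Formatting emits the exact
terminating decimal when the reduced denominator has only factors 2 and 5
(`12/20 → 0.6`, `20/20 → 1`) and rounds to four decimals otherwise, so
report files diff bit-exactly across runs. Units absent from the maximal
structure get `N_i = 0` and class expendable. An empty enumeration raises
`CollapsedEcosystemError` — criticality is never reported as 0/0. A
truncated enumeration is likewise refused (counts would be meaningless).

Expendability is strictly service-delivery-centric: a component with
`IC = 0` may still matter ecologically (e.g. a predator regulating
herbivore populations); such side effects are outside the index and are
not modelled.

`knockout(model, u)` removes the unit, drops services left incident to
nothing (with a warning), re-validates and re-enumerates. Survivor count
always equals `N − N_u` of the baseline — deleting a unit deletes exactly
the structures containing it — and this identity is tested exhaustively on
the case study and sampled on random models. Collapse (zero survivors, or
the terminal service vanishing with the unit) returns an explicit
collapsed marker instead of a report.

## Case-study fixture

The built-in model (9 services, 7 units) encodes the stylized
hunter-gatherer system described in module docstrings. Two reconstruction
choices were genuinely open, both on the carnivore: its `Habitat` input
(herbivores and carnivores shelter in vegetation) and its `Detritus` output
(everything decomposes). Enumeration is insensitive to both — habitat and a
detritus source are present in every viable structure — so either arc can
be toggled without changing the 20-structure table; the fixture ships with
both present. Humans are *not* a functional unit: society is an external
consumer, represented only by the terminal service `Food_for_humans`.
Reproducing the full published 20-row structure table from this wiring is
itself the validation that the reconstruction is right (the test suite
asserts set equality of all 20 unit sets). One published description of the
minimal structure contradicts the structure table on whether Plant2 is
excluded; the table (Plant2 present — it is the only food source for
humans there) is followed, and the other wording treated as an erratum.
A product service that is *also* declared exogenous is forbidden (roles are
exclusive); the source material is silent on this corner, and forbidding it
keeps SE1/SE2 from contradicting each other.

## Random model generator

`random_model(n_units, n_services, seed, density)` emulates small P-graph
problems for property testing: one exogenous and one terminal service,
arcs wired by independent inclusion at the given density (default 0.3, a
sparsity typical of the interaction lists the case study is built from),
then minimally repaired — producing arcs to the exogenous service dropped,
every unit given at least one output, orphaned services attached as inputs.
It guarantees *validity*, not feasibility: models with zero viable
structures are legitimate outputs and exercise the collapse paths. It makes
no attempt to emulate real food-web topology (degree distributions, trophic
levels, modularity), so passing property tests demonstrate algorithmic
correctness on arbitrary bipartite structures, not ecological realism of
any particular network. Determinism: identical arguments give identical
models (hash-checked); the suite sizes models at ≤ 12 units so the
exhaustive oracle stays at ≤ 4096 subsets per model and the full property
battery completes in well under a minute.

## Numerical and formatting conventions

All iteration over node sets is name-sorted; model-file declaration order
is preserved and defines table column order. Writers emit UTF-8 with `\n`
newlines and deterministic node/edge ordering, so reruns are byte-identical
(asserted in the tests). The membership CSV uses 0/1 cells rather than
check marks, with `N_i` and `IC_i` footer rows. The CLI exits 0 on success
including legitimate empty results (explicit `COLLAPSED` marker), 1 on
validation errors, 2 on usage errors, and echoes the model content hash,
tool version and enumeration cap on stderr so runs are self-describing.

## Known limitations

* The enumeration cap bounds memory but structure counts grow exponentially
  in producer redundancy; models far beyond ~20–25 units with heavy
  redundancy need the cap raised and patience, or are out of scope.
* No importer exists for the Windows P-graph studio's proprietary project
  format or spreadsheet macro files; models are authored in the YAML/JSON
  schema.
* Structure labels are canonical to this package, not to any external
  tool's internal ordering; compare unit sets, not labels.
* Resilience/brittleness metrics beyond the criticality index, flow-rate
  optimization and dynamic modelling are out of scope by design.
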