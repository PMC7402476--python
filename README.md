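# ecopgraph

Structural analysis of socio-ecological networks with **process graphs
(P-graphs)**: rigorous assembly of an ecosystem network from local
interaction knowledge, complete enumeration of every combinatorially
feasible sub-network, and a criticality index for identifying keystone
components.

## Who this is for

Ecological modellers who know the *local* properties of ecosystem
components — what each species or compartment needs and provides — and want
the *global* network consequences derived algorithmically instead of by
heuristic assembly: which networks are structurally viable, which
components are irreplaceable, and what happens when one goes extinct.

## The model

An ecosystem is a bipartite digraph with two disjoint node sets:

* **M-type nodes** — ecosystem *services* (habitat, pollination, food
  pools, soil nutrients, …), each tagged `raw` (exogenous, entering across
  the system boundary, e.g. sunlight), `product` (terminal, leaving the
  boundary for human use) or `intermediate`;
* **O-type nodes** — ecosystem *functional units* (species or
  compartments), each with a set of required input services and provided
  output services. Arcs never link two units directly, so multiple
  simultaneous relationship types (trophic, shelter, pollination, …)
  coexist in one graph.

A *structure* is a unit subset plus its induced services. It is
**combinatorially feasible** when (SE1) every terminal service is
represented, (SE2) a service is exogenous iff no included unit produces it,
(SE3) every unit is well defined, (SE4) every included unit has a directed
path to a terminal service, and (SE5) every service is incident to an
included unit. Feasibility is purely structural — no flow rates.

Three computations are provided:

* **MSG** (maximal structure generation) — the union of all feasible
  structures, in polynomial time (`maximal_structure`);
* **SSG** (solution structure generation) — duplicate-free enumeration of
  *all* feasible structures by decision mapping (`enumerate_structures`),
  with an independent brute-force oracle (`brute_force`);
* **criticality** — for unit *i*, `IC_i = N_i / N`, the fraction of the
  `N` feasible structures containing it. `IC_i = 1`: indispensable
  (keystone candidate); `IC_i = 0`: expendable; otherwise intermediate.
  `knockout` removes a unit and re-enumerates to probe extinction effects.

## Worked example

The built-in case study is a stylized hunter-gatherer ecosystem: three
plants, two herbivores, a carnivore and soil microbes, with sunlight as the
sole exogenous service and food extracted by humans as the sole terminal
service.

```python
from ecopgraph import case_study_model, enumerate_structures, criticality

model = case_study_model()          # 9 services, 7 functional units
result = enumerate_structures(model)
print(result.count)                 # 20
print(criticality(result, model).to_frame().to_string(index=False))
```

```
         unit  N_i IC_i         class
       Plant1   12  0.6  intermediate
       Plant2   16  0.8  intermediate
       Plant3   12  0.6  intermediate
   Herbivore1   20    1 indispensable
   Herbivore2   10  0.5  intermediate
    Carnivore   10  0.5  intermediate
Soil_microbes   20    1 indispensable
```

Twenty structures are viable. Herbivore1 and Soil_microbes appear in all of
them — they are the sole providers of pollination and soil nutrients, so
their loss collapses the system. The carnivore appears in exactly half: it
has no arc to the human food supply, so every viable network works with or
without it.

```python
from ecopgraph import knockout
survivors, report = knockout(model, "Carnivore")
print(survivors.count)   # 10
survivors, report = knockout(model, "Herbivore1")
print(report)            # None — ecosystem collapsed (0 structures)
```

The same analyses are available from a shell:

```sh
ecopgraph demo case.yaml                      # write the case-study model
ecopgraph ssg case.yaml --csv table.csv       # 20 structures + N_i/IC_i rows
ecopgraph criticality case.yaml
ecopgraph knockout case.yaml --unit Herbivore1   # prints COLLAPSED
ecopgraph msg case.yaml --dot graph.dot --graphml graph.graphml
```

Models are plain YAML/JSON documents (see
`src/ecopgraph/data/case_study.yaml` for the schema).

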