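"""Maximal Structure Generation (MSG).

The maximal structure of a P-graph problem is the union of all
combinatorially feasible structures. MSG computes it in polynomial time in
two phases:

1. **Reduction** — iteratively delete nodes that cannot occur in any
   feasible structure: non-exogenous services with no surviving producer,
   units that consume a deleted service, units that would produce an
   exogenous service (axiom SE2), and services left incident to no unit
   (axiom SE5). The fixpoint is independent of deletion order.

2. **Composition** — starting from the terminal services, include every
   surviving producer of each needed service, mark the included units'
   non-exogenous inputs as needed, and close; then drop units with no path
   to a terminal service (axiom SE4) and re-close until stable.

An ecosystem with no viable structure yields an *empty* maximal structure;
this is a regular result (ecosystem collapse), not an error.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable

from .model import (
    EcosystemModel,
    RAW,
    Structure,
    has_path_to_product,
)

__all__ = ["Removal", "MsgTrace", "reduce_model", "maximal_structure"]


@dataclass(frozen=True)
class Removal:
    """Why one node was removed: the axiom it would break, and in which phase."""

    axiom_id: str
    phase: str  # "reduction" | "composition"
    detail: str


@dataclass
class MsgTrace:
    """Record of every node MSG excluded, each with exactly one reason."""

    removed_units: dict[str, Removal] = field(default_factory=dict)
    removed_services: dict[str, Removal] = field(default_factory=dict)

    def drop_unit(self, name: str, axiom_id: str, phase: str, detail: str) -> None:
        self.removed_units.setdefault(name, Removal(axiom_id, phase, detail))

    def drop_service(self, name: str, axiom_id: str, phase: str, detail: str) -> None:
        self.removed_services.setdefault(name, Removal(axiom_id, phase, detail))


def reduce_model(
    model: EcosystemModel, rng: random.Random | None = None
) -> tuple[EcosystemModel, MsgTrace]:
    """Reduction phase: strip nodes that can belong to no feasible structure.

    ``rng`` shuffles the per-pass processing order; the fixpoint is
    order-confluent, so the result is identical for every ``rng`` (this is
    asserted by the test suite, which is how we know shuffling is safe to
    expose). The returned model may legitimately be empty; it is *not*
    re-validated, since e.g. a terminal service can disappear entirely.
    """
    trace = MsgTrace()
    units = set(model.units)
    services = set(model.services)
    raw = set(model.raw_services)

    def order(names: Iterable[str]) -> list[str]:
        out = sorted(names)
        if rng is not None:
            rng.shuffle(out)
        return out

    # Units producing an exogenous service contradict SE2 outright.
    for u in order(units):
        made_raw = sorted(model.units[u].outputs & raw)
        if made_raw:
            units.discard(u)
            trace.drop_unit(
                u, "SE2", "reduction", f"produces exogenous service(s) {made_raw}"
            )

    changed = True
    while changed:
        changed = False
        for s in order(services):
            if s in raw:
                continue
            producers = [p for p in model.producers_of(s) if p in units]
            if not producers:
                # Only unproducible *inputs* doom their consumers; a service
                # that nothing surviving touches falls to the SE5 rule below.
                consumers = [c for c in model.consumers_of(s) if c in units]
                if consumers:
                    services.discard(s)
                    trace.drop_service(
                        s, "SE2", "reduction", "no surviving producer"
                    )
                    for c in order(consumers):
                        units.discard(c)
                        trace.drop_unit(
                            c,
                            "SE2",
                            "reduction",
                            f"consumes unproducible service {s!r}",
                        )
                    changed = True
        for s in order(services):
            incident = [
                n
                for n in (*model.producers_of(s), *model.consumers_of(s))
                if n in units
            ]
            if not incident:
                services.discard(s)
                trace.drop_service(s, "SE5", "reduction", "incident to no surviving unit")
                changed = True

    reduced = EcosystemModel(
        [model.services[s] for s in model.services if s in services],
        [model.units[u] for u in model.units if u in units],
    )
    return reduced, trace


def maximal_structure(
    model: EcosystemModel,
    rng: random.Random | None = None,
    return_trace: bool = False,
):
    """Compose the maximal structure: the union of all feasible structures.

    Returns an empty :class:`~ecopgraph.model.Structure` when some terminal
    service cannot be produced at all (collapsed ecosystem). With
    ``return_trace=True``, also returns the :class:`MsgTrace` explaining
    every exclusion.
    """
    reduced, trace = reduce_model(model, rng=rng)
    products = list(model.product_services)
    candidates = set(reduced.units)

    while True:
        # Backward closure from the terminal services.
        included: set[str] = set()
        needed: list[str] = sorted(products)
        seen_needed = set(needed)
        collapsed = False
        while needed:
            s = needed.pop()
            producers = [
                p for p in model.producers_of(s) if p in candidates
            ] if s in model.services else []
            if not producers and s in set(products):
                collapsed = True
                break
            for p in producers:
                if p in included:
                    continue
                included.add(p)
                for t in sorted(model.units[p].inputs):
                    role = model.services[t].role if t in model.services else None
                    if role != RAW and t not in seen_needed:
                        seen_needed.add(t)
                        needed.append(t)
        if collapsed:
            empty = Structure(frozenset(), frozenset())
            return (empty, trace) if return_trace else empty

        dropped = False
        for u in sorted(included):
            if not has_path_to_product(model, included, u):
                candidates.discard(u)
                trace.drop_unit(
                    u, "SE4", "composition", "no path to a terminal service"
                )
                dropped = True
            else:
                for t in model.units[u].inputs:
                    role = model.services[t].role if t in model.services else None
                    if role != RAW and not any(
                        p in included for p in model.producers_of(t)
                    ):
                        candidates.discard(u)
                        trace.drop_unit(
                            u,
                            "SE2",
                            "composition",
                            f"input {t!r} unproducible within the composition",
                        )
                        dropped = True
                        break
        if not dropped:
            for u in sorted(candidates - included):
                trace.drop_unit(
                    u, "SE4", "composition", "not needed by any terminal service chain"
                )
            result = Structure.from_units(model, included)
            return (result, trace) if return_trace else result
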