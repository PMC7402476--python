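"""Domain types and feasibility rules for socio-ecological process graphs.

A process graph (P-graph) is a directed bipartite graph with two disjoint
node classes: M-type nodes representing ecosystem services (materials, in
the original process-engineering setting) and O-type nodes representing
ecosystem functional units (species or compartments; operating units in
engineering). Arcs connect only services to units and units to services.

Services carry one of three roles:

``raw``
    exogenous — the service enters across the system boundary and is never
    produced by any unit inside it (e.g. sunlight);
``product``
    terminal — the service leaves the boundary for external (human) use;
``intermediate``
    produced and consumed entirely within the network.

A *structure* is a subset of the functional units together with the service
set it induces. Combinatorial feasibility of a structure is judged purely on
connectivity, by five axioms:

SE1
    every terminal service is represented in the structure;
SE2
    a service in the structure is exogenous if and only if it is not an
    output of any included unit;
SE3
    every included unit is one of the well-defined units of the model;
SE4
    every included unit has a directed path to some terminal service;
SE5
    every service in the structure is an input or output of at least one
    included unit.

Flow rates, stoichiometry and costs are out of scope: feasibility here is
structural only.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

__all__ = [
    "RAW",
    "INTERMEDIATE",
    "PRODUCT",
    "ROLES",
    "ServiceNode",
    "UnitNode",
    "EcosystemModel",
    "Structure",
    "ModelViolation",
    "ModelError",
    "ModelWarning",
    "build_model",
    "producers_of",
    "consumers_of",
    "has_path_to_product",
    "is_feasible_structure",
]

RAW = "raw"
INTERMEDIATE = "intermediate"
PRODUCT = "product"
ROLES = frozenset({RAW, INTERMEDIATE, PRODUCT})

_NAME_RE = re.compile(r"^[A-Za-z0-9_.-]+$")


class ModelWarning(UserWarning):
    """Non-fatal modelling oddity (empty input set, self-recycling unit)."""


@dataclass(frozen=True)
class ModelViolation:
    """One axiom or validation failure.

    ``axiom_id`` is one of ``SE1``..``SE5`` for the feasibility axioms, or
    ``NAME`` / ``REF`` for naming and dangling-reference problems. ``nodes``
    lists the offending node names, sorted.
    """

    axiom_id: str
    message: str
    nodes: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.axiom_id}] {self.message}"


class ModelError(ValueError):
    """Raised when a model or query fails validation.

    Carries the complete list of :class:`ModelViolation` so callers can
    report every problem at once instead of fixing them one by one.
    """

    def __init__(self, violations: Iterable[ModelViolation]):
        self.violations = tuple(violations)
        super().__init__("; ".join(str(v) for v in self.violations))


@dataclass(frozen=True)
class ServiceNode:
    """An M-type node: one ecosystem service."""

    name: str
    role: str = INTERMEDIATE


@dataclass(frozen=True)
class UnitNode:
    """An O-type node: one ecosystem functional unit.

    ``inputs`` are the services the unit requires (all of them — inputs to a
    unit are necessary, not alternatives); ``outputs`` are the services it
    provides.
    """

    name: str
    inputs: frozenset[str]
    outputs: frozenset[str]

    def __init__(self, name: str, inputs: Iterable[str] = (), outputs: Iterable[str] = ()):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "inputs", frozenset(inputs))
        object.__setattr__(self, "outputs", frozenset(outputs))


class EcosystemModel:
    """A socio-ecological P-graph problem: services M, units O, arcs.

    Instances are normally created through :func:`build_model`, which
    validates the whole model and raises :class:`ModelError` with every
    violation found. The constructor itself performs no validation (the
    maximal-structure reduction needs to hold intermediate node sets that a
    full model would reject).

    Insertion order of services and units is preserved; it defines the
    column order of exported tables. All other iteration is name-sorted for
    run-to-run determinism.
    """

    def __init__(self, services: Iterable[ServiceNode], units: Iterable[UnitNode]):
        self.services: dict[str, ServiceNode] = {s.name: s for s in services}
        self.units: dict[str, UnitNode] = {u.name: u for u in units}
        self._producers: dict[str, tuple[str, ...]] = {name: () for name in self.services}
        self._consumers: dict[str, tuple[str, ...]] = {name: () for name in self.services}
        prod: dict[str, list[str]] = {name: [] for name in self.services}
        cons: dict[str, list[str]] = {name: [] for name in self.services}
        for u in self.units.values():
            for s in u.outputs:
                prod.setdefault(s, []).append(u.name)
            for s in u.inputs:
                cons.setdefault(s, []).append(u.name)
        self._producers = {s: tuple(sorted(names)) for s, names in prod.items()}
        self._consumers = {s: tuple(sorted(names)) for s, names in cons.items()}

    # -- derived node classes -------------------------------------------------

    @property
    def raw_services(self) -> tuple[str, ...]:
        """Names of exogenous services (the set R), in declaration order."""
        return tuple(s.name for s in self.services.values() if s.role == RAW)

    @property
    def product_services(self) -> tuple[str, ...]:
        """Names of terminal services (the set P), in declaration order."""
        return tuple(s.name for s in self.services.values() if s.role == PRODUCT)

    def producers_of(self, service: str) -> tuple[str, ...]:
        """Units whose outputs contain *service*, name-sorted."""
        self._require_service(service)
        return self._producers[service]

    def consumers_of(self, service: str) -> tuple[str, ...]:
        """Units whose inputs contain *service*, name-sorted."""
        self._require_service(service)
        return self._consumers[service]

    def induced_services(self, unit_subset: Iterable[str]) -> frozenset[str]:
        """The service set induced by a unit subset (union of their arcs)."""
        out: set[str] = set()
        for name in unit_subset:
            u = self._require_unit(name)
            out |= u.inputs
            out |= u.outputs
        return frozenset(out)

    def fingerprint(self) -> str:
        """Stable content hash of the model (sha256 of a canonical document)."""
        doc = {
            "services": sorted((s.name, s.role) for s in self.services.values()),
            "units": sorted(
                (u.name, sorted(u.inputs), sorted(u.outputs)) for u in self.units.values()
            ),
        }
        blob = json.dumps(doc, separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- validation -----------------------------------------------------------

    def validate(self) -> tuple[list[ModelViolation], list[str]]:
        """Check whole-model invariants; return (violations, warnings)."""
        violations: list[ModelViolation] = []
        warns: list[str] = []

        seen: set[str] = set()
        for name in list(self.services) + list(self.units):
            if name in seen:
                violations.append(
                    ModelViolation("NAME", f"duplicate node name {name!r}", (name,))
                )
            seen.add(name)
        for name in seen:
            if not _NAME_RE.match(name):
                violations.append(
                    ModelViolation(
                        "NAME",
                        f"invalid node name {name!r} (allowed: letters, digits, _ . -)",
                        (name,),
                    )
                )
        for s in self.services.values():
            if s.role not in ROLES:
                violations.append(
                    ModelViolation(
                        "NAME", f"service {s.name!r} has unknown role {s.role!r}", (s.name,)
                    )
                )

        for u in sorted(self.units.values(), key=lambda u: u.name):
            for s in sorted(u.inputs | u.outputs):
                if s not in self.services:
                    violations.append(
                        ModelViolation(
                            "REF",
                            f"unit {u.name!r} references undeclared service {s!r}",
                            tuple(sorted((u.name, s))),
                        )
                    )
            if not u.outputs:
                violations.append(
                    ModelViolation(
                        "SE4",
                        f"unit {u.name!r} has no outputs and can never reach a terminal service",
                        (u.name,),
                    )
                )
            if not u.inputs:
                warns.append(f"unit {u.name!r} has no inputs (pure source unit)")
            overlap = u.inputs & u.outputs
            if overlap:
                warns.append(
                    f"unit {u.name!r} lists {sorted(overlap)} as both input and output "
                    "(self-recycling)"
                )

        if not self.product_services:
            violations.append(
                ModelViolation("SE1", "model declares no terminal (product) service", ())
            )
        for s in self.raw_services:
            made_by = tuple(n for n in self._producers.get(s, ()) if n in self.units)
            if made_by:
                violations.append(
                    ModelViolation(
                        "SE2",
                        f"exogenous service {s!r} is produced by unit(s) {', '.join(made_by)}",
                        tuple(sorted((s,) + made_by)),
                    )
                )
        for s in sorted(self.services):
            if not self._producers.get(s) and not self._consumers.get(s):
                violations.append(
                    ModelViolation(
                        "SE5", f"service {s!r} is not incident to any unit", (s,)
                    )
                )
                if self.services[s].role == PRODUCT:
                    # An orphan terminal service can never be represented in
                    # any structure; a consumed-but-unproduced terminal is
                    # legal at model level (it yields a collapsed ecosystem).
                    violations.append(
                        ModelViolation(
                            "SE1",
                            f"terminal service {s!r} is unreachable: no unit touches it",
                            (s,),
                        )
                    )
        return violations, warns

    # -- helpers --------------------------------------------------------------

    def _require_service(self, name: str) -> ServiceNode:
        try:
            return self.services[name]
        except KeyError:
            raise ModelError(
                [ModelViolation("REF", f"unknown service {name!r}", (name,))]
            ) from None

    def _require_unit(self, name: str) -> UnitNode:
        try:
            return self.units[name]
        except KeyError:
            raise ModelError(
                [ModelViolation("REF", f"unknown unit {name!r}", (name,))]
            ) from None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EcosystemModel(|M|={len(self.services)}, |O|={len(self.units)})"


@dataclass(frozen=True, eq=False)
class Structure:
    """One candidate network: a unit subset plus its induced services.

    The service set is always derived from the unit set (axiom SE5); two
    structures are equal iff their unit sets are equal.
    """

    units: frozenset[str]
    services: frozenset[str]

    @classmethod
    def from_units(cls, model: EcosystemModel, units: Iterable[str]) -> "Structure":
        unit_set = frozenset(units)
        return cls(unit_set, model.induced_services(unit_set))

    @property
    def is_empty(self) -> bool:
        return not self.units

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        """Canonical ordering key: size, then lexicographic on sorted names."""
        return (len(self.units), tuple(sorted(self.units)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.units == other.units

    def __hash__(self) -> int:
        return hash(self.units)

    def __contains__(self, unit: str) -> bool:
        return unit in self.units

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.units))

    def __len__(self) -> int:
        return len(self.units)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Structure({{{', '.join(sorted(self.units))}}})"


def build_model(
    services: Iterable[ServiceNode | Mapping | tuple],
    units: Iterable[UnitNode | Mapping | tuple],
) -> EcosystemModel:
    """Assemble and validate an :class:`EcosystemModel`.

    Accepts :class:`ServiceNode` / :class:`UnitNode` instances, mappings with
    the same field names, or ``(name, role)`` / ``(name, inputs, outputs)``
    tuples. Raises :class:`ModelError` carrying *every* violation found;
    non-fatal oddities are emitted as :class:`ModelWarning`.
    """
    svc = [_coerce_service(s) for s in services]
    uts = [_coerce_unit(u) for u in units]
    # Duplicates must be caught before the name-keyed model collapses them.
    violations: list[ModelViolation] = []
    seen: set[str] = set()
    for name in [s.name for s in svc] + [u.name for u in uts]:
        if name in seen:
            violations.append(
                ModelViolation("NAME", f"duplicate node name {name!r}", (name,))
            )
        seen.add(name)
    model = EcosystemModel(svc, uts)
    more, warns = model.validate()
    violations.extend(more)
    for w in warns:
        warnings.warn(w, ModelWarning, stacklevel=2)
    if violations:
        raise ModelError(violations)
    return model


def _coerce_service(s) -> ServiceNode:
    if isinstance(s, ServiceNode):
        return s
    if isinstance(s, Mapping):
        return ServiceNode(str(s["name"]).strip(), str(s.get("role", INTERMEDIATE)))
    name, role = s
    return ServiceNode(str(name).strip(), str(role))


def _coerce_unit(u) -> UnitNode:
    if isinstance(u, UnitNode):
        return u
    if isinstance(u, Mapping):
        return UnitNode(
            str(u["name"]).strip(),
            [str(x).strip() for x in u.get("inputs", ())],
            [str(x).strip() for x in u.get("outputs", ())],
        )
    name, inputs, outputs = u
    return UnitNode(str(name).strip(), inputs, outputs)


def producers_of(model: EcosystemModel, service: str) -> set[str]:
    """Units of *model* that produce *service* (empty for exogenous services)."""
    return set(model.producers_of(service))


def consumers_of(model: EcosystemModel, service: str) -> set[str]:
    """Units of *model* that consume *service*."""
    return set(model.consumers_of(service))


def has_path_to_product(
    model: EcosystemModel, unit_subset: Iterable[str], unit: str
) -> bool:
    """Whether *unit* reaches some terminal service within *unit_subset*.

    Breadth-first reachability on the bipartite digraph restricted to the
    subset: arcs run unit -> each output service, and service -> each unit in
    the subset consuming it (axiom SE4).
    """
    subset = frozenset(unit_subset)
    model._require_unit(unit)
    products = set(model.product_services)
    seen_services: set[str] = set()
    queue: deque[str] = deque([unit])
    seen_units = {unit}
    while queue:
        u = queue.popleft()
        for s in sorted(model.units[u].outputs):
            if s in products:
                return True
            if s in seen_services:
                continue
            seen_services.add(s)
            for v in model.consumers_of(s):
                if v in subset and v not in seen_units:
                    seen_units.add(v)
                    queue.append(v)
    return False


def is_feasible_structure(
    model: EcosystemModel, unit_subset: Iterable[str]
) -> tuple[bool, list[ModelViolation]]:
    """Check the feasibility axioms for a unit subset of *model*.

    Returns ``(True, [])`` when the induced structure satisfies SE1-SE5, else
    ``(False, violations)`` listing every violated axiom. Outputs consumed by
    no included unit are permitted: a dangling output is simply reclassified
    as terminal-like and does not break feasibility.
    """
    subset = frozenset(unit_subset)
    unknown = sorted(n for n in subset if n not in model.units)
    if unknown:
        raise ModelError(
            [ModelViolation("REF", f"unknown unit {n!r}", (n,)) for n in unknown]
        )

    induced = model.induced_services(subset)
    violations: list[ModelViolation] = []

    produced: set[str] = set()
    for name in subset:
        produced |= model.units[name].outputs

    missing_products = sorted(set(model.product_services) - induced)
    if missing_products:
        violations.append(
            ModelViolation(
                "SE1",
                "terminal service(s) absent from the structure: "
                + ", ".join(missing_products),
                tuple(missing_products),
            )
        )

    bad_se2: list[str] = []
    for s in sorted(induced):
        role = model.services[s].role if s in model.services else INTERMEDIATE
        if role == RAW:
            if s in produced:
                bad_se2.append(s)
        else:
            if s not in produced:
                bad_se2.append(s)
    if bad_se2:
        violations.append(
            ModelViolation(
                "SE2",
                "exogenous/produced mismatch for service(s): " + ", ".join(bad_se2),
                tuple(bad_se2),
            )
        )

    stranded = sorted(
        u for u in subset if not has_path_to_product(model, subset, u)
    )
    if stranded:
        violations.append(
            ModelViolation(
                "SE4",
                "unit(s) with no path to a terminal service: " + ", ".join(stranded),
                tuple(stranded),
            )
        )

    # SE5 holds by construction: the service set is induced from the units.
    return (not violations, violations)
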