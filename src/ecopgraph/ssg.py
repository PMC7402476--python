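"""Solution Structure Generation (SSG).

SSG enumerates every combinatorially feasible structure of a P-graph
problem exactly once, by *decision mapping*: working backward from the
terminal services, each service awaiting a production decision is assigned
one non-empty subset of its candidate producer units. Units producing a
decided service but left out of its chosen subset are excluded from the
whole branch, which is what guarantees consistency across decisions (a
structure is emitted on exactly one branch) and makes the enumeration
duplicate-free without any post-hoc comparison of structures.

Cycles are first-class: a decision never assumes the producers of a service
were decided before its consumers, so mutualistic loops (pollination,
detritus/nutrient recycling) enumerate correctly.

:func:`brute_force` is a deliberately independent oracle: it tests all
``2^|O|`` unit subsets directly against the feasibility axioms and shares no
code path with the decision mapping beyond the axiom checker itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import (
    EcosystemModel,
    ModelError,
    ModelViolation,
    RAW,
    Structure,
    is_feasible_structure,
)
from .msg import maximal_structure

__all__ = [
    "DecisionState",
    "EnumerationResult",
    "TruncationError",
    "enumerate_structures",
    "brute_force",
]

DEFAULT_MAX_STRUCTURES = 100_000


class TruncationError(RuntimeError):
    """Enumeration would exceed the structure cap; no partial answer is returned."""


@dataclass(frozen=True)
class DecisionState:
    """One node of the decision-mapping search tree (exposed for inspection).

    ``decided`` maps each service already assigned a production decision to
    the chosen producer subset; ``included``/``excluded`` partition the units
    committed so far; ``pending`` holds services still awaiting a decision.
    """

    decided: dict[str, frozenset[str]]
    included: frozenset[str]
    excluded: frozenset[str]
    pending: tuple[str, ...]


@dataclass
class EnumerationResult:
    """All solution structures of a model, canonically ordered.

    Structures are sorted by unit-set size then lexicographically on sorted
    unit names; labels ``S1..SN`` follow that order. ``truncated`` is only
    ever True when truncation was explicitly downgraded to a warning.
    """

    structures: tuple[Structure, ...]
    model_fingerprint: str
    truncated: bool = False
    stats: dict[str, int] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.structures)

    def labels(self) -> dict[str, Structure]:
        """Map canonical labels S1..SN to structures."""
        return {f"S{i + 1}": s for i, s in enumerate(self.structures)}

    def unit_sets(self) -> set[frozenset[str]]:
        return {s.units for s in self.structures}

    def occurrences(self, unit: str) -> int:
        """N_i: the number of structures whose unit set contains *unit*."""
        return sum(1 for s in self.structures if unit in s.units)

    def __iter__(self):
        return iter(self.structures)

    def __len__(self) -> int:
        return len(self.structures)


def _canonical(structures) -> tuple[Structure, ...]:
    return tuple(sorted(set(structures), key=lambda s: s.sort_key()))


def enumerate_structures(
    model: EcosystemModel,
    max_structures: int = DEFAULT_MAX_STRUCTURES,
    truncate_ok: bool = False,
) -> EnumerationResult:
    """Enumerate every feasible structure of *model* exactly once.

    The enumeration runs inside the maximal structure (an MSG pre-pass), so
    units that occur in no feasible structure are never branched on. If the
    count would exceed ``max_structures``, raises :class:`TruncationError`
    unless ``truncate_ok``, in which case a warning is emitted and the
    partial result is flagged ``truncated=True``.
    """
    if max_structures < 1:
        raise ValueError("max_structures must be positive")
    maximal = maximal_structure(model)
    stats = {"emitted": 0, "pruned": 0, "branches": 0, "popped": 0, "expanded": 0}
    if maximal.is_empty:
        return EnumerationResult((), model.fingerprint(), False, stats)

    allowed = maximal.units
    producers = {
        s: tuple(p for p in model.producers_of(s) if p in allowed)
        for s in sorted(maximal.services)
    }
    raw = {s for s in maximal.services if model.services[s].role == RAW}
    products = tuple(sorted(model.product_services))

    found: list[frozenset[str]] = []
    truncated = False

    # Iterative depth-first traversal. Each stack entry mirrors a
    # DecisionState: committed units, excluded units, services awaiting a
    # decision, and every service ever queued (decided or pending) so a
    # service is decided at most once per branch.
    stack: list[
        tuple[frozenset[str], frozenset[str], tuple[str, ...], frozenset[str]]
    ] = [(frozenset(), frozenset(), products, frozenset(products))]
    while stack:
        included, excluded, pending, seen = stack.pop()
        stats["popped"] += 1
        if not pending:
            ok, viol = is_feasible_structure(model, included)  # SE4 safety sweep
            if not ok:
                # Unreachable by construction of the decision mapping; a hit
                # here would indicate a defect, so it is logged, not hidden.
                warnings.warn(
                    f"decision mapping emitted an infeasible structure: {viol}",
                    RuntimeWarning,
                )
                stats["pruned"] += 1
                continue
            stats["emitted"] += 1
            found.append(included)
            if len(found) > max_structures:
                if truncate_ok:
                    warnings.warn(
                        f"enumeration truncated at {max_structures} structures",
                        RuntimeWarning,
                    )
                    found.pop()
                    truncated = True
                    break
                raise TruncationError(
                    f"more than {max_structures} solution structures; "
                    "raise max_structures to enumerate them all"
                )
            continue

        # Lexicographic pending-service selection: reproducible traversal.
        s = min(pending)
        rest = tuple(t for t in pending if t != s)
        cands = tuple(p for p in producers[s] if p not in excluded)
        must = frozenset(p for p in cands if p in included)
        free = tuple(p for p in cands if p not in included)
        if not cands:
            stats["pruned"] += 1
            continue

        # Branch over every producer subset consistent with prior decisions:
        # supersets of `must`, drawn from `cands`, non-empty. Bitmask order is
        # ascending over the name-sorted free producers; pushed in reverse so
        # the depth-first pop visits masks in ascending order.
        branches = []
        for mask in range(1 << len(free)):
            chosen = must | {free[i] for i in range(len(free)) if mask >> i & 1}
            if not chosen:
                continue
            new_units = chosen - included
            new_excluded = excluded | (frozenset(producers[s]) - chosen)
            new_pending = list(rest)
            queued = set(seen)
            for u in sorted(new_units):
                for t in sorted(model.units[u].inputs):
                    # Already-decided services stay consistent through the
                    # exclusion set; only genuinely new ones are queued.
                    if t in raw or t in queued:
                        continue
                    queued.add(t)
                    new_pending.append(t)
            branches.append(
                (
                    included | new_units,
                    new_excluded,
                    tuple(new_pending),
                    frozenset(queued),
                )
            )
        if branches:
            stats["expanded"] += 1
        else:
            stats["pruned"] += 1
        stats["branches"] += len(branches)
        stack.extend(reversed(branches))

    structures = _canonical(Structure.from_units(model, u) for u in found)
    if len(structures) != len(found):  # pragma: no cover - duplicate = defect
        warnings.warn("decision mapping emitted duplicate structures", RuntimeWarning)
    return EnumerationResult(structures, model.fingerprint(), truncated, stats)


def brute_force(model: EcosystemModel, max_units: int = 20) -> EnumerationResult:
    """Oracle enumeration: test every unit subset against the axioms.

    Exponential in ``|O|`` by design; guarded at ``max_units`` (default 20,
    i.e. about a million subsets) to keep accidental misuse desk-scale.
    """
    names = sorted(model.units)
    if len(names) > max_units:
        raise ModelError(
            [
                ModelViolation(
                    "REF",
                    f"brute force refused: {len(names)} units > guard of {max_units}",
                    (),
                )
            ]
        )
    feasible = []
    for mask in range(1 << len(names)):
        subset = frozenset(names[i] for i in range(len(names)) if mask >> i & 1)
        ok, _ = is_feasible_structure(model, subset)
        if ok:
            feasible.append(Structure.from_units(model, subset))
    return EnumerationResult(
        _canonical(feasible),
        model.fingerprint(),
        False,
        {"emitted": len(feasible), "tested": 1 << len(names)},
    )
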