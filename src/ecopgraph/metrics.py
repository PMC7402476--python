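"""Criticality index, component classification and knockout analysis.

For functional unit *i*, the criticality index is

    IC_i = N_i / N

where ``N_i`` is the number of solution structures containing the unit and
``N`` the total number of solution structures. ``IC_i = 1`` marks an
indispensable unit (present in every viable network — a keystone
candidate); ``IC_i = 0`` marks an expendable one, at least from the
standpoint of delivering the terminal ecosystem services; anything in
between is of intermediate criticality.

Indices are kept as exact rationals internally; formatting emits the exact
terminating decimal where one exists (all ratios of small integer counts in
practice) and rounds to four decimals otherwise, so reports diff cleanly.

Knockout analysis removes one unit (an extinction event), re-enumerates,
and reports either the surviving structures or ecosystem collapse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .model import EcosystemModel, ModelError, ModelWarning, build_model
from .ssg import DEFAULT_MAX_STRUCTURES, EnumerationResult, enumerate_structures

__all__ = [
    "EXPENDABLE",
    "INTERMEDIATE_CLASS",
    "INDISPENSABLE",
    "CollapsedEcosystemError",
    "CriticalityRow",
    "CriticalityReport",
    "criticality",
    "knockout",
    "structure_table",
    "format_ratio",
]

EXPENDABLE = "expendable"
INTERMEDIATE_CLASS = "intermediate"
INDISPENSABLE = "indispensable"


class CollapsedEcosystemError(ValueError):
    """Criticality is undefined over zero viable structures (never 0/0)."""


def format_ratio(value: Fraction, places: int = 4) -> str:
    """Exact decimal string where the ratio terminates, else rounded.

    A rational terminates in decimal iff its reduced denominator has no
    prime factor other than 2 and 5; integer counts over structure totals
    like 12/20 always do (``'0.6'``), and ``20/20`` prints as ``'1'``.
    """
    den = value.denominator
    two = five = 0
    while den % 2 == 0:
        den //= 2
        two += 1
    while den % 5 == 0:
        den //= 5
        five += 1
    if den == 1:
        digits = max(two, five)
        scaled = value.numerator * 10**digits // value.denominator
        if digits == 0:
            return str(scaled)
        text = f"{scaled:0{digits + 1}d}"
        return f"{text[:-digits]}.{text[-digits:]}"
    return f"{float(value):.{places}f}"


@dataclass(frozen=True)
class CriticalityRow:
    unit: str
    n_i: int
    ic: Fraction
    classification: str


@dataclass(frozen=True)
class CriticalityReport:
    """Per-unit occurrence counts N_i and criticality indices IC_i."""

    n_total: int
    rows: tuple[CriticalityRow, ...]

    def __getitem__(self, unit: str) -> CriticalityRow:
        for row in self.rows:
            if row.unit == unit:
                return row
        raise KeyError(unit)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per unit with N_i, IC_i and classification."""
        return pd.DataFrame(
            {
                "unit": [r.unit for r in self.rows],
                "N_i": [r.n_i for r in self.rows],
                "IC_i": [format_ratio(r.ic) for r in self.rows],
                "class": [r.classification for r in self.rows],
            }
        )

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False, lineterminator="\n")


def _classify(ic: Fraction) -> str:
    # Exact boundaries: IC is a ratio of integers, so 0 and 1 are exact.
    if ic == 0:
        return EXPENDABLE
    if ic == 1:
        return INDISPENSABLE
    return INTERMEDIATE_CLASS


def criticality(result: EnumerationResult, model: EcosystemModel) -> CriticalityReport:
    """Compute IC_i = N_i / N for every unit of *model*.

    Units absent from every structure (hence from the maximal structure)
    get N_i = 0 and are classified expendable. Raises
    :class:`CollapsedEcosystemError` when the enumeration is empty, and
    refuses truncated enumerations (counts would be meaningless).
    """
    if result.truncated:
        raise ValueError("criticality requires a complete (untruncated) enumeration")
    if result.count == 0:
        raise CollapsedEcosystemError(
            "criticality undefined for a collapsed ecosystem (no viable structure)"
        )
    n = result.count
    rows = []
    for unit in model.units:  # model-file order
        n_i = result.occurrences(unit)
        rows.append(CriticalityRow(unit, n_i, Fraction(n_i, n), _classify(Fraction(n_i, n))))
    return CriticalityReport(n, tuple(rows))


def knockout(
    model: EcosystemModel,
    unit: str,
    max_structures: int = DEFAULT_MAX_STRUCTURES,
) -> tuple[EnumerationResult, CriticalityReport | None]:
    """Remove *unit* from the model (extinction) and re-enumerate.

    Services left incident to no remaining unit are dropped with a warning.
    Returns the surviving enumeration plus a fresh criticality report, or
    ``None`` in place of the report when the ecosystem collapses (zero
    surviving structures). The surviving count always equals the baseline
    ``N - N_unit`` — removing a unit deletes exactly the structures that
    contained it.
    """
    model._require_unit(unit)
    surviving_units = [u for name, u in model.units.items() if name != unit]
    incident: set[str] = set()
    for u in surviving_units:
        incident |= u.inputs
        incident |= u.outputs
    orphaned = [s for s in model.services if s not in incident]
    if orphaned:
        warnings.warn(
            f"knockout of {unit!r} orphans service(s) {orphaned}; removed",
            ModelWarning,
        )
    services = [s for name, s in model.services.items() if name in incident]
    try:
        reduced = build_model(services, surviving_units)
    except ModelError as err:
        # Collapse can be structural at the model level too, e.g. the sole
        # producer of the terminal service vanished and the service with it.
        if all(v.axiom_id in {"SE1", "SE5"} for v in err.violations):
            empty = EnumerationResult((), model.fingerprint(), False, {})
            return empty, None
        raise
    result = enumerate_structures(reduced, max_structures=max_structures)
    if result.count == 0:
        return result, None
    return result, criticality(result, reduced)


def structure_table(result: EnumerationResult, model: EcosystemModel) -> pd.DataFrame:
    """Membership matrix: structures x units, with N_i and IC_i footer rows.

    Rows are structures in canonical order labelled S1..SN; columns are the
    units of the maximal structure (the union of all solution structures) in
    model-file order, falling back to all model units when the enumeration
    is empty. Cells are 0/1.
    """
    in_any: set[str] = set()
    for s in result.structures:
        in_any |= s.units
    columns = [u for u in model.units if u in in_any] if in_any else list(model.units)

    body = {
        f"S{i + 1}": [int(u in s.units) for u in columns]
        for i, s in enumerate(result.structures)
    }
    frame = pd.DataFrame.from_dict(body, orient="index", columns=columns).astype(object)
    n_i = [result.occurrences(u) for u in columns]
    frame.loc["N_i"] = n_i
    if result.count > 0:
        frame.loc["IC_i"] = [
            format_ratio(Fraction(v, result.count)) for v in n_i
        ]
    frame.index.name = "structure"
    return frame
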