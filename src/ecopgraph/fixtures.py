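"""Built-in models: the stylized hunter-gatherer case study and a seeded
random model generator for property testing.

The case study is a small socio-ecological system: three plant types, two
herbivores, one carnivore and soil microbes, with sunlight entering as the
single exogenous service and food extracted by a human population as the
single terminal service. Humans are deliberately *not* a functional unit —
society sits outside the boundary as an external consumer — and the
carnivore has no arc to the human food supply, which is why it turns out to
be structurally expendable.

Local interactions encoded per unit:

* Plant1 needs sunlight, soil nutrients and pollination; provides food for
  Herbivore1, habitat, and detritus.
* Plant2 likewise; provides food for both herbivores and for humans, plus
  habitat and detritus.
* Plant3 likewise; provides food for Herbivore2 and humans, plus detritus
  (no habitat contribution).
* Herbivore1 needs its food plus habitat; provides pollination, food for
  the carnivore, and detritus.
* Herbivore2 needs its food plus habitat; provides food for humans and the
  carnivore, and detritus.
* Carnivore needs prey and habitat; contributes detritus. The habitat input
  and detritus output are the two modelling choices least pinned down by
  the narrative; enumeration results are insensitive to both (habitat and a
  detritus source are present in every viable structure), so either may be
  toggled without changing the structure table.
* Soil microbes decompose detritus into soil nutrients.

The network is cyclic (pollination: plants <-> Herbivore1; the
detritus/soil-nutrient loop), which makes it a good regression case for the
decision-mapping enumeration.
"""

from __future__ import annotations

import random

from .model import EcosystemModel, ServiceNode, UnitNode, build_model

__all__ = ["CASE_STUDY_SERVICES", "CASE_STUDY_UNITS", "case_study_model", "random_model"]


CASE_STUDY_SERVICES: tuple[tuple[str, str], ...] = (
    ("Sun", "raw"),
    ("Soil_nutrients", "intermediate"),
    ("Pollination", "intermediate"),
    ("Habitat", "intermediate"),
    ("Detritus", "intermediate"),
    ("Food_for_Herbivore1", "intermediate"),
    ("Food_for_Herbivore2", "intermediate"),
    ("Food_for_Carnivore", "intermediate"),
    ("Food_for_humans", "product"),
)

CASE_STUDY_UNITS: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    (
        "Plant1",
        ("Sun", "Soil_nutrients", "Pollination"),
        ("Food_for_Herbivore1", "Habitat", "Detritus"),
    ),
    (
        "Plant2",
        ("Sun", "Soil_nutrients", "Pollination"),
        ("Food_for_Herbivore1", "Food_for_Herbivore2", "Food_for_humans", "Habitat", "Detritus"),
    ),
    (
        "Plant3",
        ("Sun", "Soil_nutrients", "Pollination"),
        ("Food_for_Herbivore2", "Food_for_humans", "Detritus"),
    ),
    (
        "Herbivore1",
        ("Food_for_Herbivore1", "Habitat"),
        ("Pollination", "Food_for_Carnivore", "Detritus"),
    ),
    (
        "Herbivore2",
        ("Food_for_Herbivore2", "Habitat"),
        ("Food_for_humans", "Food_for_Carnivore", "Detritus"),
    ),
    (
        "Carnivore",
        ("Food_for_Carnivore", "Habitat"),
        ("Detritus",),
    ),
    (
        "Soil_microbes",
        ("Detritus",),
        ("Soil_nutrients",),
    ),
)


def case_study_model() -> EcosystemModel:
    """The stylized hunter-gatherer ecosystem: 9 services, 7 units.

    Its full enumeration yields exactly 20 solution structures; Herbivore1
    and Soil_microbes occur in all of them (sole providers of pollination
    and soil nutrients respectively), while the carnivore occurs in half.
    """
    return build_model(
        [ServiceNode(n, r) for n, r in CASE_STUDY_SERVICES],
        [UnitNode(n, i, o) for n, i, o in CASE_STUDY_UNITS],
    )


def random_model(
    n_units: int,
    n_services: int,
    seed: int,
    density: float = 0.3,
) -> EcosystemModel:
    """Seeded random P-graph model, always valid, not always feasible.

    One service is designated exogenous and one terminal; each unit's input
    and output sets are wired by independent inclusion at the given arc
    density, then minimally repaired: producing arcs to the exogenous
    service are dropped, every unit gets at least one output, and orphaned
    services are attached as an input of some unit. Determinism: the same
    ``(n_units, n_services, seed, density)`` always returns an identical
    model. The generator guarantees model validity only — zero viable
    structures is a legitimate outcome.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if n_services < 2:
        raise ValueError("n_services must be >= 2 (one raw, one product)")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")

    rng = random.Random(seed)
    names = [f"m{i}" for i in range(n_services)]
    roles = {names[0]: "raw", names[1]: "product"}
    services = [ServiceNode(n, roles.get(n, "intermediate")) for n in names]

    producible = names[1:]  # never produce the exogenous service
    units = []
    for j in range(n_units):
        inputs = {s for s in names if rng.random() < density}
        outputs = {s for s in producible if rng.random() < density}
        if not outputs:
            outputs = {rng.choice(producible)}
        units.append((f"u{j}", inputs, outputs))

    incident: set[str] = set()
    for _, i, o in units:
        incident |= i | o
    for s in names:
        if s not in incident:  # repair SE5: attach as an input somewhere
            j = rng.randrange(n_units)
            name, i, o = units[j]
            units[j] = (name, i | {s}, o)

    return build_model(services, [UnitNode(n, i, o) for n, i, o in units])
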