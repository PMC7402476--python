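"""Model validation, adjacency accessors and the feasibility axioms."""

from __future__ import annotations

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from ecopgraph import (
    EcosystemModel,
    ModelError,
    ModelWarning,
    ServiceNode,
    Structure,
    UnitNode,
    build_model,
    consumers_of,
    has_path_to_product,
    is_feasible_structure,
    producers_of,
)
from ecopgraph.io_formats import to_networkx

from conftest import quiet_random_model


def axioms(violations):
    return {v.axiom_id for v in violations}


class TestBuildModel:
    def test_case_study_is_valid(self, case_model):
        assert len(case_model.services) == 9
        assert len(case_model.units) == 7
        assert case_model.raw_services == ("Sun",)
        assert case_model.product_services == ("Food_for_humans",)

    def test_empty_unit_list_reports_orphan_product(self):
        with pytest.raises(ModelError) as err:
            build_model([ServiceNode("Food", "product")], [])
        assert axioms(err.value.violations) == {"SE1", "SE5"}

    def test_raw_service_as_output_is_se2(self):
        with pytest.raises(ModelError) as err:
            build_model(
                [ServiceNode("Sun", "raw"), ServiceNode("Food", "product")],
                [UnitNode("Plant1", ["Sun"], ["Food", "Sun"])],
            )
        (v,) = [v for v in err.value.violations if v.axiom_id == "SE2"]
        assert "Sun" in v.nodes and "Plant1" in v.nodes

    @pytest.mark.parametrize(
        "services, units, expected",
        [
            # duplicate name across namespaces
            (
                [("X", "product"), ("X", "raw")],
                [("u", ["X"], ["X"])],
                "NAME",
            ),
            # dangling reference
            (
                [("P", "product")],
                [("u", ["Ghost"], ["P"])],
                "REF",
            ),
            # no terminal service declared
            (
                [("A", "intermediate")],
                [("u", [], ["A"])],
                "SE1",
            ),
            # unit with no outputs can never reach a terminal service
            (
                [("P", "product"), ("A", "intermediate")],
                [("u", [], ["P"]), ("v", ["A"], [])],
                "SE4",
            ),
        ],
    )
    def test_violation_axioms(self, services, units, expected):
        import warnings

        with pytest.raises(ModelError) as err:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ModelWarning)
                build_model(services, units)
        assert expected in axioms(err.value.violations)

    def test_all_violations_reported_at_once(self):
        with pytest.raises(ModelError) as err:
            build_model(
                [("Sun", "raw")],
                [("u", ["Nothing"], ["Sun"])],
            )
        assert {"SE1", "SE2", "REF"} <= axioms(err.value.violations)

    def test_source_unit_and_self_recycling_warn_but_pass(self):
        with pytest.warns(ModelWarning):
            model = build_model(
                [("P", "product"), ("A", "intermediate")],
                [("source", [], ["A"]), ("loop", ["A", "P"], ["P"])],
            )
        assert set(model.units) == {"source", "loop"}


class TestAccessors:
    @pytest.mark.parametrize(
        "service, expected",
        [
            ("Food_for_humans", {"Plant2", "Plant3", "Herbivore2"}),
            ("Soil_nutrients", {"Soil_microbes"}),
            ("Sun", set()),
        ],
    )
    def test_producers_of(self, case_model, service, expected):
        assert producers_of(case_model, service) == expected

    def test_producers_of_unknown_service(self, case_model):
        with pytest.raises(ModelError) as err:
            producers_of(case_model, "Magic")
        assert axioms(err.value.violations) == {"REF"}

    def test_consumers_of(self, case_model):
        assert consumers_of(case_model, "Detritus") == {"Soil_microbes"}
        assert consumers_of(case_model, "Habitat") == {
            "Herbivore1",
            "Herbivore2",
            "Carnivore",
        }


class TestPathToProduct:
    def test_carnivore_reaches_food_via_detritus_loop(self, case_model):
        # Carnivore -> Detritus -> Soil_microbes -> Soil_nutrients -> plants
        # -> Food_for_humans: an indirect, cyclic route.
        assert has_path_to_product(case_model, set(case_model.units), "Carnivore")

    def test_direct_output_is_a_one_arc_path(self, case_model):
        assert has_path_to_product(case_model, {"Plant2"}, "Plant2")

    def test_dead_end_unit_has_no_path(self):
        with pytest.warns(ModelWarning):
            model = build_model(
                [("P", "product"), ("Dead", "intermediate")],
                [("ok", [], ["P"]), ("x", [], ["Dead"])],
            )
        assert not has_path_to_product(model, {"x"}, "x")

    def test_unknown_unit_is_ref_error(self, case_model):
        with pytest.raises(ModelError):
            has_path_to_product(case_model, {"Nobody"}, "Nobody")


class TestFeasibility:
    def test_minimal_structure_is_feasible(self, case_model):
        ok, violations = is_feasible_structure(
            case_model, {"Plant2", "Herbivore1", "Soil_microbes"}
        )
        assert ok and not violations

    @pytest.mark.parametrize(
        "subset, expected_axiom",
        [
            (set(), "SE1"),  # empty structure lacks the terminal service
            ({"Plant1", "Herbivore1", "Soil_microbes"}, "SE1"),  # nobody feeds humans
            ({"Plant3", "Herbivore1", "Soil_microbes"}, "SE2"),  # H1's food unproduced
        ],
    )
    def test_infeasible_subsets_name_the_axiom(self, case_model, subset, expected_axiom):
        ok, violations = is_feasible_structure(case_model, subset)
        assert not ok
        assert expected_axiom in axioms(violations)

    def test_unknown_unit_raises_ref(self, case_model):
        with pytest.raises(ModelError):
            is_feasible_structure(case_model, {"Plant1", "Bigfoot"})

    def test_matches_independent_axiom_check_on_random_pairs(self):
        """Feasibility agrees with a from-scratch axiom check (networkx
        reachability for SE4, direct set logic for SE1/SE2) on >=1000
        random (model, subset) pairs."""
        rng = random.Random(20240)
        checked = 0
        for seed in range(60):
            model = quiet_random_model(3 + seed % 6, 4 + seed % 5, seed=seed, density=0.35)
            names = sorted(model.units)
            for _ in range(20):
                subset = frozenset(n for n in names if rng.random() < 0.5)
                ok, _violations = is_feasible_structure(model, subset)
                assert ok == _reference_feasible(model, subset)
                checked += 1
        assert checked >= 1000

    def test_relabeling_invariance(self, case_model):
        """Feasibility only depends on the graph shape, not unit names."""
        rng = random.Random(7)
        units = sorted(case_model.units)
        relabel = dict(zip(units, rng.sample([f"u{i}" for i in range(len(units))], len(units))))
        permuted = build_model(
            list(case_model.services.values()),
            [
                UnitNode(relabel[u.name], u.inputs, u.outputs)
                for u in case_model.units.values()
            ],
        )
        for subset in [
            {"Plant2", "Herbivore1", "Soil_microbes"},
            {"Plant3", "Herbivore1", "Soil_microbes"},
            set(case_model.units),
        ]:
            ok1, _ = is_feasible_structure(case_model, subset)
            ok2, _ = is_feasible_structure(permuted, {relabel[u] for u in subset})
            assert ok1 == ok2

    def test_dangling_outputs_are_legal_and_inert(self):
        """A unit output consumed by nobody (and not terminal) neither helps
        nor hurts feasibility."""
        base_units = [
            ("maker", ["Raw"], ["P", "Extra"]),  # Extra dangles
        ]
        with_dangle = build_model(
            [("Raw", "raw"), ("P", "product"), ("Extra", "intermediate")],
            base_units,
        )
        without = build_model(
            [("Raw", "raw"), ("P", "product")],
            [("maker", ["Raw"], ["P"])],
        )
        assert is_feasible_structure(with_dangle, {"maker"})[0]
        assert is_feasible_structure(without, {"maker"})[0]

    def test_feasibility_is_not_monotone(self):
        """Supersets of a feasible structure can be infeasible: an added
        unit whose input has no producer breaks the exogeneity axiom."""
        model = build_model(
            [
                ("R", "raw"),
                ("P", "product"),
                ("X", "intermediate"),
            ],
            [
                ("a", ["R"], ["P"]),
                ("b", ["X"], ["P"]),  # X has no producer anywhere
            ],
        )
        assert is_feasible_structure(model, {"a"})[0]
        ok, violations = is_feasible_structure(model, {"a", "b"})
        assert not ok and "SE2" in axioms(violations)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), subset_seed=st.integers(0, 10_000))
def test_feasibility_permutation_property(seed, subset_seed):
    """Relabeling units never changes feasibility of the relabeled subset."""
    model = quiet_random_model(4 + seed % 5, 4 + seed % 4, seed=seed, density=0.4)
    names = sorted(model.units)
    rng = random.Random(subset_seed)
    subset = frozenset(n for n in names if rng.random() < 0.5)
    relabel = dict(zip(names, rng.sample([f"z{i}" for i in range(len(names))], len(names))))
    permuted = EcosystemModel(
        list(model.services.values()),
        [UnitNode(relabel[u.name], u.inputs, u.outputs) for u in model.units.values()],
    )
    ok1, _ = is_feasible_structure(model, subset)
    ok2, _ = is_feasible_structure(permuted, {relabel[n] for n in subset})
    assert ok1 == ok2


def _reference_feasible(model, subset) -> bool:
    """Independent axiom check used only as a test oracle.

    SE1/SE2 by direct set logic; SE4 by networkx reachability on the
    restricted bipartite digraph.
    """
    induced = set()
    produced = set()
    for u in subset:
        induced |= model.units[u].inputs | model.units[u].outputs
        produced |= model.units[u].outputs
    if not set(model.product_services) <= induced:
        return False
    for s in induced:
        is_raw = model.services[s].role == "raw"
        if is_raw and s in produced:
            return False
        if not is_raw and s not in produced:
            return False
    g = to_networkx(model, Structure.from_units(model, subset))
    products = set(model.product_services) & set(g.nodes)
    for u in subset:
        reachable = nx.descendants(g, u)
        if not reachable & products:
            return False
    return True
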