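"""Implied independencies, minimal separators and adjustment sets."""

import itertools

import networkx as nx
import numpy as np
import pytest

import cpcausal as cp
from cpcausal.errors import GraphQueryError, NotIdentifiableError

from conftest import EXPECTED_STATEMENTS, random_dag


@pytest.fixture
def confounded():
    # X <- C -> Y with direct X -> Y
    return cp.CausalGraph("XCY", [("C", "X"), ("C", "Y"), ("X", "Y")])


@pytest.fixture
def mediated():
    # X -> M -> Y with direct X -> Y
    return cp.CausalGraph("XMY", [("X", "M"), ("M", "Y"), ("X", "Y")])


class TestCIStatement:
    def test_unordered_pair_canonicalized(self):
        a = cp.CIStatement("B", "A", frozenset({"C"}))
        b = cp.CIStatement("A", "B", {"C"})
        assert a == b and a.x == "A"

    def test_rendering(self):
        s = cp.CIStatement("X", "Y", {"B", "A"})
        assert str(s) == "X _||_ Y | A, B"
        assert str(cp.CIStatement("X", "Y")) == "X _||_ Y"

    def test_invalid_statements_rejected(self):
        with pytest.raises(GraphQueryError):
            cp.CIStatement("X", "X")
        with pytest.raises(GraphQueryError):
            cp.CIStatement("X", "Y", {"X"})


class TestMinimalSeparator:
    def test_chain_and_empty_separator(self):
        chain = cp.CausalGraph("ABC", [("A", "B"), ("B", "C")])
        assert cp.minimal_separator(chain, "A", "C", {"B"}) == {"B"}
        coll = cp.CausalGraph("ABC", [("A", "B"), ("C", "B")])
        assert cp.minimal_separator(coll, "A", "C", {"B"}) == frozenset()

    def test_adjacent_pair_is_an_error(self, graph):
        with pytest.raises(GraphQueryError, match="adjacent"):
            cp.minimal_separator(graph, "GDI", "GMFM")

    def test_no_observed_separator_returns_none(self):
        g = cp.CausalGraph("ALB", [("L", "A"), ("L", "B")], latent="L")
        assert cp.minimal_separator(g, "A", "B") is None

    def test_contracture_torsion_separator_matches_reported_set(self, graph):
        sep = cp.minimal_separator(graph, "HipExt", "TibRot")
        assert sep == {"Age", "DMC", "SCALE", "Spasticity", "Strength"}

    def test_separator_is_minimal(self, graph):
        for x, y in [("HipExt", "TibRot"), ("TibRot", "GMFM")]:
            sep = cp.minimal_separator(graph, x, y)
            assert graph.d_separated(x, y, sep)
            for v in sep:
                assert not graph.d_separated(x, y, sep - {v})


class TestImpliedIndependencies:
    def test_chain_missing_edge_basis(self):
        chain = cp.CausalGraph("ABC", [("A", "B"), ("B", "C")])
        assert cp.implied_independencies(chain) == [
            cp.CIStatement("A", "C", {"B"})
        ]

    def test_latent_confounding_yields_no_statement(self):
        g = cp.CausalGraph("ALB", [("L", "A"), ("L", "B")], latent="L")
        assert cp.implied_independencies(g) == []

    def test_impairment_model_implies_exactly_eleven(self, graph):
        statements = cp.implied_independencies(graph)
        assert len(statements) == 11
        assert statements == EXPECTED_STATEMENTS

    def test_statements_verified_by_independent_implementation(self, graph):
        # the dense model exceeds the path oracle's budget, so the external
        # cross-check is an independently implemented d-separation routine
        nxg = graph.to_networkx()
        for s in cp.implied_independencies(graph):
            assert nx.is_d_separator(nxg, {s.x}, {s.y}, set(s.given))

    def test_statements_on_random_graphs_confirmed_by_path_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            g = random_dag(rng, int(rng.integers(3, 8)), latent_frac=0.3)
            if len(g.observed) < 2:
                continue
            for s in cp.implied_independencies(g):
                assert g.d_separated_bruteforce(s.x, s.y, s.given)
                for v in s.given:  # minimality of each separator
                    assert not g.d_separated(s.x, s.y, s.given - {v})

    def test_full_enumeration_contains_the_basis(self):
        chain = cp.CausalGraph("ABCD", [("A", "B"), ("B", "C"), ("C", "D")])
        basis = set(cp.implied_independencies(chain))
        everything = set(cp.enumerate_all_independencies(chain))
        assert basis <= everything
        assert cp.CIStatement("A", "D", {"B"}) in everything


class TestVerifyAdjustment:
    def test_confounder_must_be_adjusted(self, confounded):
        assert cp.verify_adjustment(confounded, "X", "Y", {"C"}, "total")
        assert not cp.verify_adjustment(confounded, "X", "Y", set(), "total")

    def test_mediator_adjustment_destroys_total_effect(self, mediated):
        assert not cp.verify_adjustment(mediated, "X", "Y", {"M"}, "total")
        assert cp.verify_adjustment(mediated, "X", "Y", set(), "total")

    def test_mediator_required_for_direct_effect(self, mediated):
        assert cp.verify_adjustment(mediated, "X", "Y", {"M"}, "direct")
        assert not cp.verify_adjustment(mediated, "X", "Y", set(), "direct")

    def test_strength_total_adjustment_needs_age(self, graph):
        z = {"SCALE", "DMC", "Spasticity", "Age"}
        assert cp.verify_adjustment(graph, "Strength", "GMFM", z, "total")
        # SCALE and DMC are colliders of age and latent motor control:
        # conditioning on them without age opens a non-causal path
        assert not cp.verify_adjustment(
            graph, "Strength", "GMFM", z - {"Age"}, "total"
        )

    def test_latent_in_adjustment_set_is_an_error(self, graph):
        with pytest.raises(GraphQueryError, match="latent"):
            cp.verify_adjustment(graph, "Strength", "GMFM", {"MC"}, "total")


class TestAdjustmentSets:
    def test_unconfounded_pair_gets_empty_set(self):
        g = cp.CausalGraph("XY", [("X", "Y")])
        res = cp.adjustment_sets(g, "X", "Y", "total")
        assert res.sets == [frozenset()] and res.chosen == frozenset()

    def test_gait_pattern_set_is_its_shared_parents(self, graph):
        res = cp.adjustment_sets(graph, "GDI", "GMFM", "total")
        assert res.chosen == {
            "Age", "DMC", "SCALE", "Spasticity", "Strength",
            "AnkleDF", "KneeExt", "Popliteal", "HipExt",
        }

    def test_gait_pattern_total_equals_direct(self, graph):
        total = cp.adjustment_sets(graph, "GDI", "GMFM", "total")
        direct = cp.adjustment_sets(graph, "GDI", "GMFM", "direct")
        assert total.chosen == direct.chosen
        assert total.sets == direct.sets

    def test_every_returned_set_is_valid_and_minimal(self, graph):
        for exposure in ("Strength", "Spasticity", "TibRot", "Age"):
            res = cp.adjustment_sets(graph, exposure, "GMFM", "total")
            assert res.chosen in res.sets
            for z in res.sets:
                assert cp.verify_adjustment(graph, exposure, "GMFM", z, "total")
                for v in z:
                    assert not cp.verify_adjustment(
                        graph, exposure, "GMFM", z - {v}, "total"
                    )

    def test_unidentifiable_effect_raises(self):
        g = cp.CausalGraph("XLY", [("L", "X"), ("L", "Y"), ("X", "Y")],
                           latent="L")
        with pytest.raises(NotIdentifiableError, match="not.*identifiable"):
            cp.adjustment_sets(g, "X", "Y", "total")


class TestOpenNonCausalPath:
    def test_age_is_effectively_a_root_exposure(self, graph):
        assert not cp.has_open_noncausal_path(graph, "Age", "GMFM")

    def test_all_other_exposures_are_confounded(self, graph, config):
        for exposure in config.exposures:
            if exposure == "Age":
                continue
            assert cp.has_open_noncausal_path(graph, exposure, "GMFM")
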