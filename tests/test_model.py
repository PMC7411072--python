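"""Core bipartite graph model: insertion contracts, degrees, validation."""

import pytest
from hypothesis import given, settings, strategies as st

from wholecellnet import CellNetwork, MoleculeNode, ReactionNode, RoleEdge
from wholecellnet.errors import DuplicateIdError, NetworkError, UnknownIdError

from conftest import make_molecule


class TestAddMolecule:
    def test_single_insertion(self):
        net = CellNetwork().add_molecule(make_molecule("ATP[c]"))
        assert (net.n_molecules, net.n_reactions, net.n_edges) == (1, 0, 0)

    def test_duplicate_id_rejected_with_name(self):
        net = CellNetwork().add_molecule(make_molecule("ATP[c]"))
        with pytest.raises(DuplicateIdError, match="ATP\\[c\\]"):
            net.add_molecule(make_molecule("ATP[c]"))

    def test_compartments_are_distinct_nodes(self):
        net = CellNetwork()
        net.add_molecule(make_molecule("ATP[c]"))
        net.add_molecule(make_molecule("ATP[e]", compartment="e"))
        assert net.n_molecules == 2

    def test_bad_category_and_compartment_rejected(self):
        with pytest.raises(NetworkError):
            MoleculeNode("x", "x", "not_a_category", "c")
        with pytest.raises(NetworkError):
            MoleculeNode("x", "x", "metabolite", "nucleus")


class TestAddReaction:
    def test_enzymatic_reaction_edge_roles(self, toy_net):
        parts = toy_net.reaction_parts("RX_toy")
        assert len(parts["reactant"]) == 2
        assert len(parts["product"]) == 1
        assert len(parts["modifier"]) == 1
        assert toy_net.n_edges == 4

    def test_tetramer_stoichiometry(self):
        net = CellNetwork()
        for mid in ("alpha[c]", "beta[c]", "cplx[c]"):
            net.add_molecule(make_molecule(mid, category="protein_monomer"))
        net.add_reaction_with_edges(
            ReactionNode("RX_tet", "tetramer formation", "Macromolecular Complexation"),
            reactants=[("alpha[c]", 2), ("beta[c]", 2)],
            products=[("cplx[c]", 1)],
        )
        weights = sorted(w for _, w in net.reaction_parts("RX_tet")["reactant"])
        assert weights == [2, 2]

    def test_transport_three_edges(self):
        net = CellNetwork()
        net.add_molecule(make_molecule("Mol[e]", compartment="e"))
        net.add_molecule(make_molecule("Mol[c]"))
        net.add_molecule(make_molecule("Transporter[m]", compartment="m", category="protein_monomer"))
        net.add_reaction_with_edges(
            ReactionNode("RX_tr", "transport", "Transmembrane Transport"),
            reactants=[("Mol[e]", 1)],
            products=[("Mol[c]", 1)],
            modifiers=["Transporter[m]"],
        )
        assert net.n_edges == 3

    def test_unknown_molecule_and_bad_weight(self):
        net = CellNetwork().add_molecule(make_molecule("A[c]"))
        with pytest.raises(UnknownIdError, match="B\\[c\\]"):
            net.add_reaction_with_edges(
                ReactionNode("R", "r", "Metabolism"), reactants=[("B[c]", 1)]
            )
        with pytest.raises(NetworkError):
            net.add_reaction_with_edges(
                ReactionNode("R", "r", "Metabolism"), reactants=[("A[c]", 0)]
            )


class TestDegree:
    def test_fig_toy_degrees(self, toy_net):
        assert toy_net.degree("Enz[c]") == 1
        assert toy_net.degree("Met3[c]", mode="in") == 1
        assert toy_net.degree("Met3[c]", mode="out") == 0
        assert toy_net.degree("RX_toy") == 4

    def test_role_filter(self, toy_net):
        assert toy_net.degree("RX_toy", roles={"modifier"}) == 1
        assert toy_net.degree("RX_toy", roles={"reactant"}) == 2

    def test_in_plus_out_equals_all(self, toy_net):
        for node in list(toy_net.molecules) + list(toy_net.reactions):
            assert toy_net.degree(node) == toy_net.degree(node, "in") + toy_net.degree(node, "out")

    def test_unknown_node(self, toy_net):
        with pytest.raises(UnknownIdError):
            toy_net.degree("nope")


class TestComponents:
    def test_toy_single_component(self, toy_net):
        comps = toy_net.connected_components()
        assert len(comps) == 1 and len(comps[0]) == 5

    def test_disjoint_reactions_two_components(self, toy_net):
        toy_net.add_molecule(make_molecule("X[c]"))
        toy_net.add_molecule(make_molecule("Y[c]"))
        toy_net.add_reaction_with_edges(
            ReactionNode("RX2", "r2", "Metabolism"), reactants=[("X[c]", 1)], products=[("Y[c]", 1)]
        )
        assert len(toy_net.connected_components()) == 2

    def test_empty_network(self):
        assert CellNetwork().connected_components() == []


class TestValidate:
    def test_valid_toy_empty_report(self, toy_net):
        assert toy_net.validate().ok

    def test_molecule_molecule_edge_flagged(self, toy_net):
        toy_net.edges.append(RoleEdge("Met1[c]", "Met2[c]", "reactant", 1))
        violations = toy_net.validate().violations
        assert sum("bipartiteness" in v for v in violations) == 1

    def test_reaction_without_inputs_flagged(self):
        net = CellNetwork.from_parts(
            [make_molecule("P[c]")],
            [ReactionNode("R0", "spontaneous generation", "Metabolism")],
            [RoleEdge("R0", "P[c]", "product", 1)],
        )
        assert any("no reactant or modifier" in v for v in net.validate().violations)

    def test_dangling_edge_flagged(self, toy_net):
        toy_net.edges.append(RoleEdge("ghost[c]", "RX_toy", "reactant", 1))
        assert any("dangling" in v for v in toy_net.validate().violations)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 9), st.integers(0, 9)), max_size=25))
def test_mutations_preserve_bipartiteness_and_edge_count(ops):
    """Arbitrary add sequences never create molecule-molecule edges and keep
    the edge count equal to the sum of role list lengths over reactions."""
    net = CellNetwork()
    for i in range(10):
        net.add_molecule(make_molecule(f"M{i}[c]"))
    expected_edges = 0
    for k, (a, b, c) in enumerate(ops):
        reactants = [(f"M{a}[c]", 1.0)]
        products = [(f"M{b}[c]", 2.0)]
        modifiers = [f"M{c}[c]"]
        net.add_reaction_with_edges(
            ReactionNode(f"R{k}", "r", "Metabolism"), reactants, products, modifiers
        )
        expected_edges += 3
    assert net.validate().ok
    assert net.n_edges == expected_edges
    for e in net.edges:
        assert (e.source in net.molecules) != (e.target in net.molecules)
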