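"""Network assembly: closure fixpoint, integrity, determinism, mass balance."""

import pytest

from wholecellnet import (
    CellNetwork,
    MoleculeNode,
    ReactionNode,
    RoleEdge,
    SynthConfig,
    build_network,
    check_mass_balance,
    closure_pass_adds_nothing,
    generate_synthetic_kb,
)


class TestBuild:
    def test_deterministic_rebuild(self, small_kb, small_net):
        rebuilt, _ = build_network(small_kb)
        assert sorted(rebuilt.molecules) == sorted(small_net.molecules)
        assert sorted(rebuilt.reactions) == sorted(small_net.reactions)
        assert sorted(map(tuple.__repr__, map(
            lambda e: (e.source, e.target, e.role, e.weight), rebuilt.edges))) == sorted(
            map(tuple.__repr__, map(
                lambda e: (e.source, e.target, e.role, e.weight), small_net.edges)))

    def test_single_connected_component(self, small_net):
        assert len(small_net.connected_components()) == 1

    def test_every_non_boundary_molecule_has_a_producer(self, small_net, small_trace):
        assert small_trace.unreachable == []
        for mid, mol in small_net.molecules.items():
            if not mol.is_boundary:
                assert small_net.producers_of(mid), mid

    def test_boundary_nutrients_have_no_producer(self, small_net):
        boundary = [m for m in small_net.molecules.values() if m.is_boundary]
        assert boundary
        for mol in boundary:
            assert not small_net.producers_of(mol.id)

    def test_fixpoint_one_more_pass_adds_nothing(self, small_kb, small_net):
        assert closure_pass_adds_nothing(small_kb, small_net)

    def test_structurally_valid(self, small_net):
        assert small_net.validate().ok

    def test_trace_monotone_growth(self, small_trace):
        # every pass but the last adds something
        for added in small_trace.added_per_pass[:-1]:
            assert sum(added) > 0
        assert sum(small_trace.added_per_pass[-1]) == 0

    def test_division_reachable_from_every_gene_product(self, small_kb, small_net):
        comps = small_net.connected_components()
        comp = next(c for c in comps if small_net.critical_reaction_id in c)
        for gene in small_kb.genes:
            target = small_kb.resolve_component(gene.id)
            assert target in comp

    def test_residual_reactions_appended(self, small_kb, small_net):
        for spec in small_kb.extra_reactions:
            assert spec.id in small_net.reactions

    def test_terminates_on_varied_configs(self):
        for seed, n_genes, n_aa in [(3, 24, 2), (4, 30, 3)]:
            kb = generate_synthetic_kb(
                SynthConfig(seed=seed, n_genes=n_genes, n_amino_acids=n_aa,
                            n_tus=5, n_metabolites=6, n_metabolic_reactions=8,
                            genome_length=18000, n_binding_sites=5)
            )
            net, trace = build_network(kb)
            assert trace.unreachable == []
            assert net.validate().ok


class TestMassBalance:
    def test_balanced_toy_reaction(self):
        net = CellNetwork()
        net.add_molecule(MoleculeNode("H[c]", "hydrogen", "metabolite", "c", mass=1.008))
        net.add_molecule(MoleculeNode("O[c]", "oxygen", "metabolite", "c", mass=15.999))
        net.add_molecule(MoleculeNode("H2O[c]", "water", "metabolite", "c", mass=18.015))
        net.add_reaction_with_edges(
            ReactionNode("RX_W", "water formation", "Metabolism"),
            reactants=[("H[c]", 2), ("O[c]", 1)],
            products=[("H2O[c]", 1)],
        )
        violations, skipped = check_mass_balance(net, tolerance=1e-6)
        assert violations == [] and skipped == []

    def test_corrupted_weight_detected(self):
        net = CellNetwork()
        net.add_molecule(MoleculeNode("H[c]", "hydrogen", "metabolite", "c", mass=1.008))
        net.add_molecule(MoleculeNode("O[c]", "oxygen", "metabolite", "c", mass=15.999))
        net.add_molecule(MoleculeNode("H2O[c]", "water", "metabolite", "c", mass=18.015))
        net.add_reaction_with_edges(
            ReactionNode("RX_W", "water formation", "Metabolism"),
            reactants=[("H[c]", 2), ("O[c]", 1)],
            products=[("H2O[c]", 2)],  # corrupted stoichiometry
        )
        violations, _ = check_mass_balance(net)
        assert [rid for rid, _ in violations] == ["RX_W"]

    def test_whole_synthetic_network_balances(self, small_net):
        violations, skipped = check_mass_balance(small_net)
        assert violations == []
        # reactions touching unknown-mass states (chromosome regions,
        # machinery-bound intermediates) are skipped, not silently passed
        assert skipped
        for rid in skipped:
            parts = small_net.reaction_parts(rid)
            masses = [
                small_net.molecules[m].mass
                for m, _ in parts["reactant"] + parts["product"]
            ]
            assert any(m is None for m in masses)

    def test_modifiers_excluded(self, toy_net):
        # Enz has no mass but is only a modifier: reaction still checked
        toy_net.molecules["Met1[c]"].mass = 1.0
        toy_net.molecules["Met2[c]"].mass = 2.0
        toy_net.molecules["Met3[c]"].mass = 3.0
        violations, skipped = check_mass_balance(toy_net)
        assert violations == [] and skipped == []

    def test_injected_corruption_in_built_network(self, small_net):
        # perturb one product weight of a checked reaction; it must be flagged
        _, skipped = check_mass_balance(small_net)
        checked = [
            rid
            for rid in small_net.reactions
            if rid not in set(skipped) and small_net.reaction_parts(rid)["product"]
            and small_net.reaction_parts(rid)["reactant"]
        ]
        rid = sorted(checked)[0]
        edges = []
        for e in small_net.edges:
            if e.role == "product" and e.source == rid:
                edges.append(RoleEdge(e.source, e.target, e.role, e.weight + 1.0))
            else:
                edges.append(e)
        corrupted = CellNetwork.from_parts(
            list(small_net.molecules.values()),
            list(small_net.reactions.values()),
            edges,
        )
        violations, _ = check_mass_balance(corrupted)
        assert rid in [r for r, _ in violations]
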