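"""Cascading failure: oracle equivalence, confluence, essentiality, confusion rates."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wholecellnet import (
    CellNetwork,
    EssentialityCall,
    ReactionNode,
    cascade_failure,
    cascade_failure_naive,
    confusion_rates,
    essentiality_scan,
    gene_targets,
    planted_essential_genes,
)
from wholecellnet.errors import UnknownIdError

from conftest import make_molecule, random_bipartite_network


def chain_network():
    """geneProduct -(modifier)-> RX1 -> M1 -(reactant)-> RX2 -> M2."""
    net = CellNetwork()
    net.add_molecule(make_molecule("GP[c]", category="protein_monomer"))
    net.add_molecule(make_molecule("M1[c]"))
    net.add_molecule(make_molecule("M2[c]"))
    net.add_reaction_with_edges(
        ReactionNode("RX1", "first", "Metabolism"),
        reactants=[],
        products=[("M1[c]", 1)],
        modifiers=["GP[c]"],
    )
    net.add_reaction_with_edges(
        ReactionNode("RX2", "second", "Metabolism"),
        reactants=[("M1[c]", 1)],
        products=[("M2[c]", 1)],
    )
    return net


class TestCascadeRules:
    def test_linear_chain_collapses(self):
        net = chain_network()
        res = cascade_failure(net, {"GP[c]"})
        assert res.removed_reactions == {"RX1", "RX2"}
        assert res.removed_molecules == {"GP[c]", "M1[c]", "M2[c]"}
        oracle = cascade_failure_naive(net, {"GP[c]"})
        assert oracle.removed_molecules == res.removed_molecules
        assert oracle.removed_reactions == res.removed_reactions

    def test_product_only_molecule_removes_nothing_else(self):
        net = chain_network()
        res = cascade_failure(net, {"M2[c]"})
        assert res.removed_molecules == {"M2[c]"}
        assert res.removed_reactions == set()

    def test_redundant_producer_keeps_molecule(self):
        net = chain_network()
        net.add_molecule(make_molecule("E2[c]", category="protein_monomer"))
        net.add_reaction_with_edges(
            ReactionNode("RX1b", "backup producer", "Metabolism"),
            products=[("M1[c]", 1)],
            modifiers=["E2[c]"],
        )
        res = cascade_failure(net, {"GP[c]"})
        assert "M1[c]" not in res.removed_molecules
        assert res.removed_reactions == {"RX1"}

    def test_boundary_molecule_survives_producer_loss(self):
        net = chain_network()
        net.molecules["M1[c]"].is_boundary = True
        # boundary molecules are exempt even if all producers fail
        res = cascade_failure(net, {"GP[c]"})
        assert "M1[c]" not in res.removed_molecules
        assert res.removed_reactions == {"RX1"}

    def test_unknown_seed_rejected(self):
        with pytest.raises(UnknownIdError):
            cascade_failure(chain_network(), {"nope"})
        with pytest.raises(UnknownIdError):
            cascade_failure(chain_network(), {"RX1"})


class TestOracleEquivalence:
    def test_worklist_matches_naive_on_random_networks(self, rng):
        for _ in range(120):
            net = random_bipartite_network(rng)
            n_seeds = int(rng.integers(1, 4))
            seeds = {
                f"M{int(i)}[c]"
                for i in rng.choice(len(net.molecules), size=min(n_seeds, len(net.molecules)), replace=False)
            }
            a = cascade_failure(net, seeds)
            b = cascade_failure_naive(net, seeds)
            assert a.removed_molecules == b.removed_molecules
            assert a.removed_reactions == b.removed_reactions

    def test_confluence_under_seed_orderings(self, rng):
        py_rng = random.Random(7)
        for _ in range(10):
            net = random_bipartite_network(rng)
            mols = sorted(net.molecules)
            seeds = mols[:3]
            reference = cascade_failure(net, seeds)
            for _ in range(10):
                shuffled = list(seeds)
                py_rng.shuffle(shuffled)
                res = cascade_failure(net, shuffled)
                assert res.removed_molecules == reference.removed_molecules
                assert res.removed_reactions == reference.removed_reactions

    def test_monotonicity_in_seed_set(self, rng):
        for _ in range(30):
            net = random_bipartite_network(rng)
            mols = sorted(net.molecules)
            s1 = set(mols[:2])
            s2 = set(mols[2:4])
            r1 = cascade_failure(net, s1)
            r12 = cascade_failure(net, s1 | s2)
            assert r1.removed_molecules <= r12.removed_molecules
            assert r1.removed_reactions <= r12.removed_reactions


class TestGeneTargets:
    def test_protein_gene_yields_both_monomer_states(self, small_kb, small_net):
        gene = next(g for g in small_kb.genes if g.name == "ftsZ")
        targets = gene_targets(small_kb, small_net, gene.id)
        states = {small_net.molecules[t].state for t in targets}
        assert states == {"immature", "functional"}
        assert all(
            small_net.molecules[t].category == "protein_monomer" for t in targets
        )

    def test_trna_gene_yields_uncharged_rna_node(self, small_kb, small_net):
        trna_gene = next(iter(small_kb.trna_genes.values()))
        targets = gene_targets(small_kb, small_net, trna_gene)
        assert len(targets) == 1
        mol = small_net.molecules[next(iter(targets))]
        assert mol.category == "rna" and mol.state == "functional"

    def test_unknown_function_gene_removes_only_its_own_chain(self, small_kb, small_net):
        unknown = next(g for g in small_kb.genes if g.name == "unknown")
        targets = gene_targets(small_kb, small_net, unknown.id)
        res = cascade_failure(small_net, targets)
        assert not res.division_removed
        # only its own synthesis/decay chain falls
        for rid in res.removed_reactions:
            assert unknown.id in rid


class TestEssentialityScan:
    def test_planted_truth_recovered(self, small_kb, small_net):
        calls = essentiality_scan(small_net, small_kb, mode="single")
        rates = confusion_rates(calls)
        assert (rates.match, rates.false_positive, rates.false_negative) == (1.0, 0.0, 0.0)
        predicted = {c.genes[0] for c in calls if c.predicted == "essential"}
        assert set(planted_essential_genes(small_kb)) <= predicted

    def test_isozyme_pair_is_the_only_combination_essential(self, iso_kb, iso_net):
        singles = essentiality_scan(iso_net, iso_kb, mode="single")
        iso_genes = sorted(g.id for g in iso_kb.genes if g.name.startswith("isozyme"))
        single_by_gene = {c.genes[0]: c.predicted for c in singles}
        for gid in iso_genes:
            assert single_by_gene[gid] == "non_essential"
        pairs = essentiality_scan(iso_net, iso_kb, mode="double")
        essential_pairs = [c.genes for c in pairs if c.predicted == "essential"]
        assert essential_pairs == [tuple(iso_genes)]

    def test_no_self_pairs_in_double_scan(self, iso_kb, iso_net):
        pairs = essentiality_scan(iso_net, iso_kb, mode="double")
        assert all(g1 != g2 for g1, g2 in (c.genes for c in pairs))


class TestConfusionRates:
    @staticmethod
    def _calls(pairs):
        return [
            EssentialityCall(genes=(f"g{i}",), predicted=p, experimental=e)
            for i, (p, e) in enumerate(pairs)
        ]

    def test_perfect_predictor(self):
        calls = self._calls([("essential", "essential")] * 2 + [("non_essential", "non-essential")] * 8)
        r = confusion_rates(calls)
        assert (r.match, r.false_positive, r.false_negative) == (1.0, 0.0, 0.0)
        assert r.restricted_match == 1.0 and r.restricted_false_positive == 0.0

    def test_all_non_essential_predictor_closed_form(self):
        f = 0.3
        n = 10
        k = int(f * n)
        calls = self._calls(
            [("non_essential", "essential")] * k
            + [("non_essential", "non-essential")] * (n - k)
        )
        r = confusion_rates(calls)
        assert (r.match, r.false_positive, r.false_negative) == (1 - f, 0.0, f)
        assert r.restricted_match is None

    def test_ten_gene_toy_missing_one(self):
        calls = self._calls(
            [("essential", "essential"), ("non_essential", "essential")]
            + [("non_essential", "non-essential")] * 8
        )
        r = confusion_rates(calls)
        assert (r.match, r.false_positive, r.false_negative) == (0.9, 0.0, 0.1)

    def test_unknown_labels_count_as_non_essential(self):
        calls = self._calls([("essential", "unknown"), ("non_essential", "unknown")])
        r = confusion_rates(calls)
        assert r.match == 0.5 and r.false_positive == 0.5 and r.false_negative == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=30
        )
    )
    def test_rates_sum_to_one(self, table):
        calls = self._calls(
            [
                (
                    "essential" if p else "non_essential",
                    "essential" if e else "non-essential",
                )
                for p, e in table
            ]
        )
        r = confusion_rates(calls)
        assert abs(r.match + r.false_positive + r.false_negative - 1.0) < 1e-12
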