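"""Shared fixtures: toy networks, synthetic knowledge bases, random bipartite nets."""

from pathlib import Path

import numpy as np
import pytest

from wholecellnet import (
    CellNetwork,
    MoleculeNode,
    ReactionNode,
    SynthConfig,
    build_network,
    generate_synthetic_kb,
)

DATA = Path(__file__).parent / "data"


def make_molecule(mid, **kw):
    defaults = dict(name=mid, category="metabolite", compartment="c")
    defaults.update(kw)
    return MoleculeNode(id=mid, **defaults)


def build_fig_toy():
    """Met1 + Met2 -> Met3 catalysed by Enz: 5 nodes, 4 edges."""
    net = CellNetwork()
    for mid in ("Met1[c]", "Met2[c]", "Met3[c]"):
        net.add_molecule(make_molecule(mid))
    net.add_molecule(make_molecule("Enz[c]", category="protein_monomer"))
    net.add_reaction_with_edges(
        ReactionNode("RX_toy", "toy reaction", "Metabolism"),
        reactants=[("Met1[c]", 1), ("Met2[c]", 1)],
        products=[("Met3[c]", 1)],
        modifiers=["Enz[c]"],
    )
    return net


@pytest.fixture
def toy_net():
    return build_fig_toy()


@pytest.fixture(scope="session")
def minicell_path():
    return DATA / "minicell.json"


@pytest.fixture(scope="session")
def small_kb():
    return generate_synthetic_kb(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_net(small_kb):
    net, trace = build_network(small_kb)
    return net


@pytest.fixture(scope="session")
def small_trace(small_kb):
    _, trace = build_network(small_kb)
    return trace


@pytest.fixture(scope="session")
def iso_kb():
    """Redundant-isozyme knowledge base (duplicated amino-acid importers)."""
    return generate_synthetic_kb(
        SynthConfig(seed=5, isozyme_pair=True, n_aa_importers=2, n_genes=44)
    )


@pytest.fixture(scope="session")
def iso_net(iso_kb):
    net, _ = build_network(iso_kb)
    return net


def random_bipartite_network(rng, max_nodes=30):
    """Random bipartite reaction network with boundary flags, for cascade oracles."""
    n_mol = int(rng.integers(2, max(3, max_nodes * 2 // 3)))
    n_rxn = int(rng.integers(1, max(2, max_nodes - n_mol)))
    net = CellNetwork()
    for i in range(n_mol):
        net.add_molecule(
            make_molecule(f"M{i}[c]", is_boundary=bool(rng.random() < 0.1))
        )
    for j in range(n_rxn):
        k_r = int(rng.integers(0, 3))
        k_p = int(rng.integers(0, 3))
        k_m = int(rng.integers(0, 2))
        reactants = [
            (f"M{int(i)}[c]", float(rng.integers(1, 4)))
            for i in rng.choice(n_mol, size=min(k_r, n_mol), replace=False)
        ]
        products = [
            (f"M{int(i)}[c]", float(rng.integers(1, 4)))
            for i in rng.choice(n_mol, size=min(k_p, n_mol), replace=False)
        ]
        modifiers = [
            f"M{int(i)}[c]" for i in rng.choice(n_mol, size=min(k_m, n_mol), replace=False)
        ]
        if not reactants and not modifiers:
            reactants = [(f"M{int(rng.integers(n_mol))}[c]", 1.0)]
        net.add_reaction_with_edges(
            ReactionNode(f"R{j}", f"rxn {j}", "Metabolism"),
            reactants=reactants,
            products=products,
            modifiers=modifiers,
        )
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
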