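"""Bipartite, directed, weighted reaction-graph data model.

A cell network has two node kinds sharing one id namespace: *molecule*
nodes (any physical entity in a compartment -- a metabolite, a protein
state, an RNA, a chromosome region) and *reaction* nodes (any interaction,
labelled with the cellular process it belongs to).  Edges are role-typed:

* ``reactant`` -- molecule -> reaction, weight = stoichiometry,
* ``product``  -- reaction -> molecule, weight = stoichiometry,
* ``modifier`` -- molecule -> reaction, weight 1; the molecule enables the
  reaction (catalyst, template, regulator) without being consumed.

Distinct states and distinct compartments of the same chemical are
distinct molecule nodes.  Parallel edges are allowed (they arise in the
rewiring null model), so the underlying graph is a multigraph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx

from .errors import DuplicateIdError, NetworkError, UnknownIdError

COMPARTMENTS = ("c", "m", "tc", "tm", "e")
"""Cytosol, cell membrane, terminal-organelle cytosol/membrane, extracellular."""

CATEGORIES = (
    "metabolite",
    "protein_monomer",
    "protein_complex",
    "rna",
    "chromosome_region",
    "other",
)

ROLES = ("reactant", "product", "modifier")

PROCESSES = (
    "Metabolism",
    "Transmembrane Transport",
    "Replication",
    "Transcription",
    "RNA Processing",
    "tRNA Aminoacylation",
    "Translation",
    "Protein Maturation",
    "Macromolecular Complexation",
    "Protein-DNA Interaction",
    "Protein Decay",
    "RNA Decay",
    "Cellular Division",
    "Host Interaction",
    "DNA Repair",
)

#: Molecule states.  ``functional`` is the default, mature form; the other
#: values mark intermediates created by process templates.
STATES = ("functional", "immature", "precursor", "charged", "bound", "transient")


@dataclass
class MoleculeNode:
    """A physical entity in a compartment; one node per state and location."""

    id: str
    name: str
    category: str
    compartment: str
    mass: Optional[float] = None
    gene_ids: frozenset = frozenset()
    state: str = "functional"
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise NetworkError(f"unknown molecule category {self.category!r} for {self.id}")
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(f"unknown compartment {self.compartment!r} for {self.id}")
        if self.state not in STATES:
            raise NetworkError(f"unknown state {self.state!r} for {self.id}")
        if self.mass is not None and self.mass < 0:
            raise NetworkError(f"negative mass for {self.id}")
        self.gene_ids = frozenset(self.gene_ids)


@dataclass
class ReactionNode:
    """An interaction between molecules, labelled with its cellular process."""

    id: str
    name: str
    process: str
    evidence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise NetworkError(f"unknown process {self.process!r} for {self.id}")


@dataclass(frozen=True)
class RoleEdge:
    """Directed, role-typed, weighted link between a molecule and a reaction."""

    source: str
    target: str
    role: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NetworkError(f"unknown edge role {self.role!r}")
        if not self.weight > 0:
            raise NetworkError(
                f"non-positive weight {self.weight} on edge {self.source}->{self.target}"
            )


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self) -> Iterator[str]:
        return iter(self.violations)


class CellNetwork:
    """Mutable container for the bipartite molecule/reaction graph.

    Molecules and reactions share a single id namespace.  Incidence
    indexes are maintained on mutation so degree queries, producer lookups
    and cascade dynamics are O(1) per node.
    """

    def __init__(self) -> None:
        self.molecules: dict[str, MoleculeNode] = {}
        self.reactions: dict[str, ReactionNode] = {}
        self.edges: list[RoleEdge] = []
        self.critical_reaction_id: Optional[str] = None
        # rid -> {"reactant": [(mid, w)], "product": [(mid, w)], "modifier": [(mid, 1.0)]}
        self._rxn_roles: dict[str, dict[str, list]] = {}
        # mid -> {"reactant": [rid], "product": [rid], "modifier": [rid]}
        self._mol_roles: dict[str, dict[str, list]] = {}

    # -- plumbing -----------------------------------------------------------

    def _check_new_id(self, node_id: str) -> None:
        if node_id in self.molecules or node_id in self.reactions:
            raise DuplicateIdError(f"id {node_id!r} already present in the network")

    def has_node(self, node_id: str) -> bool:
        return node_id in self.molecules or node_id in self.reactions

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_nodes(self) -> int:
        return len(self.molecules) + len(self.reactions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    # -- mutation -----------------------------------------------------------

    def add_molecule(self, mol: MoleculeNode) -> "CellNetwork":
        self._check_new_id(mol.id)
        self.molecules[mol.id] = mol
        self._mol_roles[mol.id] = {"reactant": [], "product": [], "modifier": []}
        return self

    def add_reaction_with_edges(
        self,
        rxn: ReactionNode,
        reactants: Sequence[tuple] = (),
        products: Sequence[tuple] = (),
        modifiers: Sequence[str] = (),
    ) -> "CellNetwork":
        """Add a reaction node plus all its role edges atomically."""
        self._check_new_id(rxn.id)
        for mid, w in list(reactants) + list(products):
            if mid not in self.molecules:
                raise UnknownIdError(f"reaction {rxn.id}: unknown molecule {mid!r}")
            if not w > 0:
                raise NetworkError(f"reaction {rxn.id}: non-positive weight {w} for {mid}")
        for mid in modifiers:
            if mid not in self.molecules:
                raise UnknownIdError(f"reaction {rxn.id}: unknown modifier {mid!r}")
        self.reactions[rxn.id] = rxn
        roles = {"reactant": [], "product": [], "modifier": []}
        for mid, w in reactants:
            roles["reactant"].append((mid, float(w)))
            self._mol_roles[mid]["reactant"].append(rxn.id)
            self.edges.append(RoleEdge(mid, rxn.id, "reactant", float(w)))
        for mid, w in products:
            roles["product"].append((mid, float(w)))
            self._mol_roles[mid]["product"].append(rxn.id)
            self.edges.append(RoleEdge(rxn.id, mid, "product", float(w)))
        for mid in modifiers:
            roles["modifier"].append((mid, 1.0))
            self._mol_roles[mid]["modifier"].append(rxn.id)
            self.edges.append(RoleEdge(mid, rxn.id, "modifier", 1.0))
        self._rxn_roles[rxn.id] = roles
        return self

    # -- queries ------------------------------------------------------------

    def reaction_parts(self, rid: str) -> dict:
        if rid not in self.reactions:
            raise UnknownIdError(f"unknown reaction {rid!r}")
        return self._rxn_roles[rid]

    def reactants_of(self, rid: str) -> list:
        return list(self.reaction_parts(rid)["reactant"])

    def products_of(self, rid: str) -> list:
        return list(self.reaction_parts(rid)["product"])

    def modifiers_of(self, rid: str) -> list:
        return [m for m, _ in self.reaction_parts(rid)["modifier"]]

    def producers_of(self, mid: str) -> set:
        """Reactions with a product edge into this molecule."""
        if mid not in self.molecules:
            raise UnknownIdError(f"unknown molecule {mid!r}")
        return set(self._mol_roles[mid]["product"])

    def consumers_of(self, mid: str) -> set:
        if mid not in self.molecules:
            raise UnknownIdError(f"unknown molecule {mid!r}")
        return set(self._mol_roles[mid]["reactant"])

    def modified_by(self, mid: str) -> set:
        if mid not in self.molecules:
            raise UnknownIdError(f"unknown molecule {mid!r}")
        return set(self._mol_roles[mid]["modifier"])

    def incident_reactions(self, mid: str) -> set:
        """All reactions touching this molecule in any role."""
        if mid not in self.molecules:
            raise UnknownIdError(f"unknown molecule {mid!r}")
        r = self._mol_roles[mid]
        return set(r["reactant"]) | set(r["product"]) | set(r["modifier"])

    def degree(self, node_id: str, mode: str = "all", roles: Optional[Iterable[str]] = None) -> int:
        """Count incident edges, filtered by direction and role.

        ``mode`` is ``in``, ``out`` or ``all``.  For a molecule, reactant
        and modifier edges are outgoing and product edges incoming; for a
        reaction the directions are mirrored.
        """
        if mode not in ("in", "out", "all"):
            raise ValueError(f"bad degree mode {mode!r}")
        role_set = set(ROLES) if roles is None else set(roles)
        if not role_set <= set(ROLES):
            raise ValueError(f"bad roles {roles!r}")
        if node_id in self.molecules:
            r = self._mol_roles[node_id]
            out = sum(len(r[k]) for k in ("reactant", "modifier") if k in role_set)
            inc = len(r["product"]) if "product" in role_set else 0
        elif node_id in self.reactions:
            r = self._rxn_roles[node_id]
            inc = sum(len(r[k]) for k in ("reactant", "modifier") if k in role_set)
            out = len(r["product"]) if "product" in role_set else 0
        else:
            raise UnknownIdError(f"unknown node {node_id!r}")
        if mode == "in":
            return inc
        if mode == "out":
            return out
        return inc + out

    def connected_components(self) -> list:
        """Weakly connected components as a list of node-id sets."""
        return [set(c) for c in nx.weakly_connected_components(self.to_networkx())]

    # -- validation ---------------------------------------------------------

    def validate(self) -> ValidationReport:
        """Report structural violations; an empty report means valid."""
        report = ValidationReport()
        dup = set(self.molecules) & set(self.reactions)
        for node_id in sorted(dup):
            report.violations.append(f"duplicate id across node kinds: {node_id}")
        for e in self.edges:
            src_is_mol = e.source in self.molecules
            src_is_rxn = e.source in self.reactions
            tgt_is_mol = e.target in self.molecules
            tgt_is_rxn = e.target in self.reactions
            if not (src_is_mol or src_is_rxn):
                report.violations.append(f"dangling edge source: {e.source}")
                continue
            if not (tgt_is_mol or tgt_is_rxn):
                report.violations.append(f"dangling edge target: {e.target}")
                continue
            if src_is_mol == tgt_is_mol:
                report.violations.append(
                    f"bipartiteness violation: {e.source} -> {e.target} ({e.role})"
                )
                continue
            if e.role in ("reactant", "modifier") and not (src_is_mol and tgt_is_rxn):
                report.violations.append(
                    f"{e.role} edge must run molecule->reaction: {e.source} -> {e.target}"
                )
            if e.role == "product" and not (src_is_rxn and tgt_is_mol):
                report.violations.append(
                    f"product edge must run reaction->molecule: {e.source} -> {e.target}"
                )
            if not e.weight > 0:
                report.violations.append(f"non-positive weight on {e.source} -> {e.target}")
        for rid in self.reactions:
            parts = self._rxn_roles.get(rid, {"reactant": [], "modifier": []})
            if not parts["reactant"] and not parts["modifier"]:
                report.violations.append(f"reaction {rid} has no reactant or modifier edges")
        return report

    # -- conversion / construction ------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for mid, mol in self.molecules.items():
            g.add_node(
                mid,
                kind="molecule",
                name=mol.name,
                category=mol.category,
                compartment=mol.compartment,
                state=mol.state,
                boundary=int(mol.is_boundary),
                genes=";".join(sorted(mol.gene_ids)),
                **({"mass": float(mol.mass)} if mol.mass is not None else {}),
            )
        for rid, rxn in self.reactions.items():
            g.add_node(
                rid,
                kind="reaction",
                name=rxn.name,
                process=rxn.process,
                **({"evidence": rxn.evidence} if rxn.evidence else {}),
            )
        for e in self.edges:
            g.add_edge(e.source, e.target, role=e.role, weight=float(e.weight))
        return g

    @classmethod
    def from_parts(
        cls,
        molecules: Iterable[MoleculeNode],
        reactions: Iterable[ReactionNode],
        edges: Iterable[RoleEdge],
        critical_reaction_id: Optional[str] = None,
    ) -> "CellNetwork":
        """Rebuild a network from raw node/edge collections.

        Used by the rewiring null model and the file readers, where edges
        do not arrive grouped by reaction.  Bipartiteness and endpoint
        existence are enforced; the reactant-or-modifier invariant is not
        (a rewired reaction may legitimately lose all its inputs).
        """
        net = cls()
        for mol in molecules:
            net.add_molecule(mol)
        for rxn in reactions:
            net._check_new_id(rxn.id)
            net.reactions[rxn.id] = rxn
            net._rxn_roles[rxn.id] = {"reactant": [], "product": [], "modifier": []}
        for e in edges:
            if e.role in ("reactant", "modifier"):
                mid, rid = e.source, e.target
            else:
                rid, mid = e.source, e.target
            if mid not in net.molecules or rid not in net.reactions:
                raise NetworkError(
                    f"edge {e.source}->{e.target} ({e.role}) violates bipartite roles"
                )
            net.edges.append(e)
            net._rxn_roles[rid][e.role].append((mid, e.weight))
            net._mol_roles[mid][e.role].append(rid)
        net.critical_reaction_id = critical_reaction_id
        return net

    def copy(self) -> "CellNetwork":
        return CellNetwork.from_parts(
            [replace(m) for m in self.molecules.values()],
            [replace(r) for r in self.reactions.values()],
            list(self.edges),
            self.critical_reaction_id,
        )
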