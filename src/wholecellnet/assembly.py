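"""Recursive network construction from the metabolism outward.

Seeding: every metabolic/transport reaction from the knowledge base, its
metabolites and enzymes, plus the functional product of every gene and
the complexes the cell-division reaction will require.  Closure: any
molecule that lacks a producing reaction (and is not a boundary nutrient)
triggers instantiation of its biosynthesis template -- complexation for
complexes, translation/maturation for monomers, transcription (with RNA
processing) for RNAs, aminoacylation for charged tRNAs, replication for
chromosome regions -- and, where applicable, its decay template.  The
closure runs to a fixpoint, residual knowledge-base reactions are then
appended and closed over again, and finally the single cell-division
reaction is attached and recorded as the network's critical reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import names, templates
from .chromosome import partition_chromosome
from .errors import TemplateError
from .kb import KBBundle, ReactionSpec
from .model import CellNetwork, MoleculeNode, ReactionNode
from .templates import TemplateConfig, TemplateInstance


@dataclass
class AssemblyTrace:
    iterations: int = 0
    added_per_pass: list = field(default_factory=list)  # (n_molecules, n_reactions)
    unreachable: list = field(default_factory=list)


def apply_instance(net: CellNetwork, inst: TemplateInstance) -> tuple:
    """Apply a template instance idempotently; returns (mol_added, rxn_added)."""
    mols, rxns = 0, 0
    for mol in inst.new_molecules:
        if not net.has_node(mol.id):
            net.add_molecule(mol)
            mols += 1
    for step in inst.steps:
        if net.has_node(step.reaction.id):
            continue
        net.add_reaction_with_edges(
            step.reaction, step.reactants, step.products, step.modifiers
        )
        rxns += 1
    return mols, rxns


def _kb_reaction_instance(kb: KBBundle, spec: ReactionSpec) -> TemplateInstance:
    """Wrap a knowledge-base reaction (metabolic, transport, residual) as an instance."""
    inst = TemplateInstance(process=spec.process, substrate_id=spec.id)
    mols: dict = {}
    directions = [("", spec.reactants, spec.products)]
    if spec.reversible:
        directions = [("_fwd", spec.reactants, spec.products), ("_rev", spec.products, spec.reactants)]
    modifier_ids = []
    for ref in spec.modifiers:
        mid = kb.resolve_component(ref)
        modifier_ids.append(mid)
        mols.setdefault(mid, _node_for(kb, mid, ref))
    for mid, _ in list(spec.reactants) + list(spec.products):
        mols.setdefault(mid, templates.metabolite_node(kb, mid))
    for suffix, reactants, products in directions:
        inst.steps.append(
            templates.TemplateStep(
                ReactionNode(spec.id + suffix, spec.name, spec.process, spec.evidence),
                reactants=list(reactants),
                products=list(products),
                modifiers=modifier_ids,
            )
        )
    inst.new_molecules = list(mols.values())
    return inst


def _node_for(kb: KBBundle, mol_id: str, ref: str) -> MoleculeNode:
    if ref in kb.complex_by_id:
        return templates.complex_node(kb, ref)
    if ref in kb.gene_by_id:
        gene = kb.gene_by_id[ref]
        if gene.product_type == "protein":
            return templates.monomer_node(kb, ref)
        return templates.gene_rna_node(kb, ref)
    return templates.metabolite_node(kb, mol_id)


class _Builder:
    def __init__(self, kb: KBBundle, cfg: TemplateConfig):
        self.kb = kb
        self.cfg = cfg
        self.net = CellNetwork()
        self.trace = AssemblyTrace()
        self.regions = partition_chromosome(kb)
        self._instantiated: set = set()
        self._decayed: set = set()
        self._unreachable: set = set()
        # reverse maps for template dispatch
        self._gene_of_monomer: dict = {}
        self._tu_of_rna: dict = {}
        for gene in kb.genes:
            if gene.product_type == "protein":
                ann = kb.annotation(gene.id)
                self._gene_of_monomer[names.monomer(gene.id, ann.compartment)] = gene.id
                self._gene_of_monomer[names.immature_monomer(gene.id)] = gene.id
        for tu in kb.transcription_units:
            self._tu_of_rna[names.tu_rna(tu.id)] = tu.id
            for gid in tu.gene_ids:
                g = kb.gene_by_id[gid]
                if g.product_type != "protein":
                    self._tu_of_rna[names.gene_rna(gid)] = tu.id
                    self._tu_of_rna[names.rna_precursor(gid)] = tu.id

    def _once(self, key: str, make) -> tuple:
        if key in self._instantiated:
            return (0, 0)
        self._instantiated.add(key)
        return apply_instance(self.net, make())

    def _template_for(self, mol: MoleculeNode):
        kb = self.kb
        if mol.category == "chromosome_region":
            return "replication", lambda: templates.instantiate_replication(
                kb, self.regions, self.cfg
            )
        if mol.category == "protein_complex":
            name, _ = names.split(mol.id)
            if name in kb.complex_by_id:
                return f"complexation:{name}", lambda: templates.instantiate_complexation(kb, name)
            return None
        if mol.category == "protein_monomer":
            gene_id = self._gene_of_monomer.get(mol.id)
            if gene_id is not None:
                return f"translation:{gene_id}", lambda: templates.instantiate_translation(
                    kb, kb.gene_by_id[gene_id], self.cfg
                )
            return None
        if mol.category == "rna":
            if mol.state == "charged":
                gid = next(iter(mol.gene_ids))
                return f"charging:{gid}", lambda: templates.instantiate_aminoacylation(
                    kb, gid, self.cfg
                )
            tu_id = self._tu_of_rna.get(mol.id)
            if tu_id is not None:
                return f"transcription:{tu_id}", lambda: templates.instantiate_transcription(
                    kb, kb.tu_by_id[tu_id], self.regions, self.cfg
                )
            return None
        return None

    def _closure_pass(self) -> tuple:
        mols, rxns = 0, 0
        for mid in sorted(self.net.molecules):
            mol = self.net.molecules[mid]
            needs_producer = (
                not mol.is_boundary
                and mid not in self._unreachable
                and not self.net.producers_of(mid)
            )
            if needs_producer:
                dispatch = self._template_for(mol)
                if dispatch is None:
                    self._unreachable.add(mid)
                else:
                    key, make = dispatch
                    try:
                        dm, dr = self._once(key, make)
                    except TemplateError:
                        self._unreachable.add(mid)
                        self._instantiated.discard(key)
                        continue
                    mols += dm
                    rxns += dr
                    if not self.net.producers_of(mid):
                        self._unreachable.add(mid)
            if (
                mid not in self._decayed
                and mol.state == "functional"
                and mol.category in ("rna", "protein_monomer", "protein_complex")
            ):
                self._decayed.add(mid)
                dm, dr = self._once(
                    f"decay:{mid}", lambda m=mol: templates.instantiate_decay(self.kb, m)
                )
                mols += dm
                rxns += dr
        return mols, rxns

    def run_closure(self, record_final_zero: bool = True) -> None:
        while True:
            mols, rxns = self._closure_pass()
            self.trace.iterations += 1
            if (mols, rxns) != (0, 0) or record_final_zero:
                self.trace.added_per_pass.append((mols, rxns))
            if mols == 0 and rxns == 0:
                break

    def seed(self) -> None:
        mols, rxns = 0, 0
        for spec in self.kb.metabolic_reactions:
            dm, dr = self._once(f"kb:{spec.id}", lambda s=spec: _kb_reaction_instance(self.kb, s))
            mols += dm
            rxns += dr
        for gene in self.kb.genes:
            target = self.kb.resolve_component(gene.id)
            if not self.net.has_node(target):
                self.net.add_molecule(_node_for(self.kb, target, gene.id))
                mols += 1
        for cplx_id in self.kb.division_requirements:
            mol_id = names.mol(cplx_id, self.kb.complex_by_id[cplx_id].compartment)
            if not self.net.has_node(mol_id):
                self.net.add_molecule(templates.complex_node(self.kb, cplx_id))
                mols += 1
        # The chromosome is always present: replication is seeded explicitly
        # (transcription's consume-and-reproduce convention would otherwise
        # satisfy the producer check for regions without any replication).
        dm, dr = self._once(
            "replication",
            lambda: templates.instantiate_replication(self.kb, self.regions, self.cfg),
        )
        mols += dm
        rxns += dr
        self.trace.added_per_pass.append((mols, rxns))

    def residual(self) -> None:
        mols, rxns = 0, 0
        for spec in self.kb.extra_reactions:
            dm, dr = self._once(f"kb:{spec.id}", lambda s=spec: _kb_reaction_instance(self.kb, s))
            mols += dm
            rxns += dr
        if (mols, rxns) != (0, 0):
            self.trace.added_per_pass.append((mols, rxns))

    def finish(self) -> None:
        inst = templates.instantiate_cell_division(self.kb, self.net)
        apply_instance(self.net, inst)
        self.net.critical_reaction_id = inst.steps[0].reaction.id
        self.trace.unreachable = sorted(self._unreachable)


def build_network(
    kb: KBBundle, cfg: Optional[TemplateConfig] = None
) -> tuple:
    """Build the whole-cell network for a knowledge base.

    Returns ``(net, trace)``.  Deterministic: rebuilding from the same KB
    yields identical node and edge sets.
    """
    cfg = cfg or TemplateConfig()
    b = _Builder(kb, cfg)
    b.seed()
    b.run_closure(record_final_zero=False)
    b.residual()
    b.run_closure()
    b.finish()
    return b.net, b.trace


def closure_pass_adds_nothing(
    kb: KBBundle, net: CellNetwork, cfg: Optional[TemplateConfig] = None
) -> bool:
    """Fixpoint check: one more closure pass over a built network adds nothing.

    Template application is idempotent, so re-running a pass on a complete
    network must report zero added molecules and reactions.
    """
    b = _Builder(kb, cfg or TemplateConfig())
    b.net = net
    mols, rxns = b._closure_pass()
    return mols == 0 and rxns == 0


# -- mass balance ------------------------------------------------------------


def check_mass_balance(
    net: CellNetwork, masses: Optional[dict] = None, tolerance: float = 1e-6
) -> tuple:
    """Verify conservation of mass reaction by reaction.

    ``imbalance = |sum w*m(reactants) - sum w*m(products)|``; modifiers are
    excluded.  Reactions involving any molecule of unknown mass are
    skipped and reported separately rather than treated as zero-mass.
    Returns ``(violations, skipped)`` where violations is a list of
    ``(reaction_id, imbalance)`` with relative imbalance above tolerance.
    """
    if masses is None:
        masses = {mid: m.mass for mid, m in net.molecules.items()}
    violations, skipped = [], []
    for rid in sorted(net.reactions):
        parts = net.reaction_parts(rid)
        participants = parts["reactant"] + parts["product"]
        if not participants:
            continue
        if any(masses.get(mid) is None for mid, _ in participants):
            skipped.append(rid)
            continue
        lhs = sum(w * masses[mid] for mid, w in parts["reactant"])
        rhs = sum(w * masses[mid] for mid, w in parts["product"])
        imbalance = abs(lhs - rhs)
        if imbalance > tolerance * max(1.0, lhs, rhs):
            violations.append((rid, imbalance))
    return violations, skipped
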