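"""Rule-based reaction templates.

Each template is a parameterised set of reactions replicated per substrate
(a gene, a transcription unit, a complex, a molecule), in the spirit of
rule-based modeling: chromosome replication, transcription with optional
RNA processing, tRNA aminoacylation, translation with protein maturation,
macromolecular complexation, RNA/protein decay, and the single cell-division
reaction.  A template instantiation returns a self-contained
:class:`TemplateInstance` -- reactions plus every molecule the instance
touches -- which the assembly layer applies to a network idempotently
(ids are deterministic functions of the substrate, so re-instantiating
never duplicates a subnetwork).

Stoichiometric conventions kept consistent across templates so the whole
synthetic network is mass-balanced where masses are known:

* polymerisation consumes NTPs (releasing PPi) or charged tRNAs and GTP
  (releasing GDP, Pi and one water per peptide bond formed);
* decay mirrors synthesis: a polymer degrades to exactly the monomer pool
  its synthesis consumed (nucleoside monophosphates for RNA, free amino
  acids for protein, with the condensation water re-consumed);
* chromosome-region states and machinery-bound intermediates carry no
  mass and are therefore skipped by the balance checker.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from . import masses, names
from .chromosome import (
    ChromosomeRegion,
    region_nt_counts,
    regions_overlapping,
    terminus_region_index,
)
from .errors import TemplateError
from .kb import GeneSpec, KBBundle, TUSpec
from .model import MoleculeNode, ReactionNode


@dataclass
class TemplateConfig:
    """Tunable template parameters.

    ``energy_per_residue`` -- GTP consumed per incorporated residue during
    translation elongation (GTP hydrolysis is stated without a coefficient
    in most sources; two per residue reflects EF-Tu + EF-G usage).
    ``aminoacylation_atp`` -- ATP per tRNA charging event.
    ``ori_proximal_site_count`` -- DnaA box regions required near the
    origin for replication initiation.
    ``stall_templates`` -- attach minimal stall-and-release reaction pairs
    to each transcription/translation chain.
    ``signal_peptide_length`` -- residues cleaved off secreted proteins.
    """

    energy_per_residue: int = 2
    aminoacylation_atp: int = 1
    ori_proximal_site_count: int = 5
    stall_templates: bool = False
    signal_peptide_length: int = 3


@dataclass
class TemplateStep:
    reaction: ReactionNode
    reactants: list = field(default_factory=list)  # [(mol_id, weight)]
    products: list = field(default_factory=list)
    modifiers: list = field(default_factory=list)  # [mol_id]


@dataclass
class TemplateInstance:
    """A self-contained subnetwork produced by one template application.

    ``new_molecules`` lists *every* molecule the instance references, so
    the instance can be applied to a network that does not yet contain
    them; molecules already present are left untouched on application.
    """

    process: str
    substrate_id: str
    steps: list = field(default_factory=list)
    new_molecules: list = field(default_factory=list)

    @property
    def reactions(self) -> list:
        return [s.reaction for s in self.steps]

    @property
    def edges(self) -> list:
        from .model import RoleEdge

        out = []
        for s in self.steps:
            rid = s.reaction.id
            out += [RoleEdge(m, rid, "reactant", w) for m, w in s.reactants]
            out += [RoleEdge(rid, m, "product", w) for m, w in s.products]
            out += [RoleEdge(m, rid, "modifier", 1.0) for m in s.modifiers]
        return out


# -- molecule factories ------------------------------------------------------


def metabolite_node(kb: KBBundle, mol_id: str) -> MoleculeNode:
    name, comp = names.split(mol_id)
    spec = kb.metabolite_by_id.get(name)
    if spec is None or comp not in spec.compartments:
        raise TemplateError(f"unknown metabolite species {mol_id!r}")
    return MoleculeNode(
        id=mol_id,
        name=spec.name,
        category="metabolite",
        compartment=comp,
        mass=spec.mass,
        is_boundary=comp in spec.boundary_compartments,
    )


def monomer_node(kb: KBBundle, gene_id: str, state: str = "functional") -> MoleculeNode:
    gene = kb.gene_by_id[gene_id]
    ann = kb.annotation(gene_id)
    seq = kb.protein_sequence(gene)
    if state == "functional" and ann.secreted:
        seq_eff = seq[TemplateConfig().signal_peptide_length:]
    else:
        seq_eff = seq
    comp = ann.compartment if state == "functional" else "c"
    return MoleculeNode(
        id=names.monomer(gene_id, comp) if state == "functional" else names.immature_monomer(gene_id),
        name=f"{gene.name} monomer" + (" (immature)" if state == "immature" else ""),
        category="protein_monomer",
        compartment=comp,
        mass=masses.protein_mass(seq_eff),
        gene_ids=frozenset({gene_id}),
        state=state,
    )


def gene_rna_node(kb: KBBundle, gene_id: str, state: str = "functional") -> MoleculeNode:
    gene = kb.gene_by_id[gene_id]
    transcript = kb.transcript_sequence(gene.start, gene.end, gene.strand)
    mol_id = names.gene_rna(gene_id) if state == "functional" else names.rna_precursor(gene_id)
    return MoleculeNode(
        id=mol_id,
        name=f"{gene.name} {gene.product_type}" + (" precursor" if state == "precursor" else ""),
        category="rna",
        compartment="c",
        mass=masses.rna_mass(transcript),
        gene_ids=frozenset({gene_id}),
        state=state,
    )


def charged_trna_node(kb: KBBundle, aa_letter: str) -> MoleculeNode:
    gene_id = kb.trna_genes[aa_letter]
    base = gene_rna_node(kb, gene_id)
    return MoleculeNode(
        id=names.charged_trna(gene_id),
        name=f"{base.name} (aminoacylated)",
        category="rna",
        compartment="c",
        mass=(base.mass or 0.0) + masses.AA_MASS[aa_letter],
        gene_ids=base.gene_ids,
        state="charged",
    )


def tu_rna_node(kb: KBBundle, tu: TUSpec, cleaved: bool) -> MoleculeNode:
    transcript = kb.transcript_sequence(tu.start, tu.end, tu.strand)
    return MoleculeNode(
        id=names.tu_rna(tu.id),
        name=f"{tu.id} transcript",
        category="rna",
        compartment="c",
        mass=masses.rna_mass(transcript),
        gene_ids=frozenset(tu.gene_ids),
        state="precursor" if cleaved else "functional",
    )


def complex_mass(kb: KBBundle, cplx_id: str, _seen=None) -> Optional[float]:
    _seen = set() if _seen is None else _seen
    if cplx_id in _seen:
        raise TemplateError(f"cyclic complex composition at {cplx_id}")
    _seen.add(cplx_id)
    total = 0.0
    for ref, stoich in kb.complex_by_id[cplx_id].subunits:
        if ref in kb.complex_by_id:
            part = complex_mass(kb, ref, _seen)
        elif ref in kb.gene_by_id:
            gene = kb.gene_by_id[ref]
            if gene.product_type == "protein":
                part = monomer_node(kb, ref).mass
            else:
                part = gene_rna_node(kb, ref).mass
        else:
            name, _ = names.split(ref)
            part = kb.metabolite_by_id[name].mass
        if part is None:
            return None
        total += stoich * part
    return total


def complex_node(kb: KBBundle, cplx_id: str) -> MoleculeNode:
    spec = kb.complex_by_id[cplx_id]
    genes: set = set()

    def collect(cid):
        for ref, _ in kb.complex_by_id[cid].subunits:
            if ref in kb.complex_by_id:
                collect(ref)
            elif ref in kb.gene_by_id:
                genes.add(ref)

    collect(cplx_id)
    return MoleculeNode(
        id=names.mol(cplx_id, spec.compartment),
        name=spec.name,
        category="protein_complex",
        compartment=spec.compartment,
        mass=complex_mass(kb, cplx_id),
        gene_ids=frozenset(genes),
    )


def region_node(region: ChromosomeRegion) -> MoleculeNode:
    return MoleculeNode(
        id=names.region(region.index),
        name=f"chromosome region {region.index} ({region.kind})",
        category="chromosome_region",
        compartment="c",
    )


def bound_region_node(region: ChromosomeRegion, protein_tag: str, label: str) -> MoleculeNode:
    return MoleculeNode(
        id=names.bound_region(region.index, protein_tag),
        name=f"chromosome region {region.index} bound by {label}",
        category="chromosome_region",
        compartment="c",
        state="bound",
    )


def _transient(mol_id: str, label: str, mass: Optional[float] = None) -> MoleculeNode:
    return MoleculeNode(
        id=mol_id, name=label, category="other", compartment="c", mass=mass, state="transient"
    )


def _agg(pairs) -> list:
    acc: Counter = Counter()
    for mid, w in pairs:
        acc[mid] += w
    return sorted(acc.items())


# -- machinery lookups -------------------------------------------------------


def _machine(kb: KBBundle, key: str) -> str:
    try:
        return kb.machinery[key]
    except KeyError:
        raise TemplateError(f"knowledge base defines no {key!r} machinery") from None


def _machine_complex(kb: KBBundle, key: str):
    cplx_id = _machine(kb, key)
    if cplx_id not in kb.complex_by_id:
        raise TemplateError(f"{key} machinery {cplx_id!r} is not a complex")
    return complex_node(kb, cplx_id)


def _machine_monomer(kb: KBBundle, key: str):
    gene_id = _machine(kb, key)
    if gene_id not in kb.gene_by_id:
        raise TemplateError(f"{key} machinery {gene_id!r} is not a gene")
    return monomer_node(kb, gene_id)


# -- replication -------------------------------------------------------------


def instantiate_replication(
    kb: KBBundle, regions: list, cfg: Optional[TemplateConfig] = None
) -> TemplateInstance:
    """Replication initiation, two elongation arms, terminus release.

    DnaA binds the origin-proximal binding-site regions; the replication
    complex forms from those bound regions plus two replisomes seeded on
    the first region of each side of the origin.  Each arm advances one
    region per reaction, producing two copies of the region being
    duplicated and consuming the next one; dNTP weights are the
    both-strand nucleotide counts of the duplicated region.  The terminus
    reaction joins both arms, releases the replisomes and produces the
    duplicated-chromosome representative.
    """
    cfg = cfg or TemplateConfig()
    n = len(regions)
    ter_idx = terminus_region_index(regions, kb)
    site_regions = [r for r in regions if r.kind == "binding_site"]
    genome_len = kb.genome_length
    site_regions.sort(key=lambda r: min(r.start, genome_len - r.end))
    k = cfg.ori_proximal_site_count
    if len(site_regions) < k:
        raise TemplateError(
            f"replication initiation needs {k} origin-proximal binding-site regions, "
            f"found {len(site_regions)}"
        )
    ori_sites = sorted(site_regions[:k], key=lambda r: r.index)

    dnaa = _machine_monomer(kb, "dnaa_gene")
    replisome = _machine_complex(kb, "replisome")
    inst = TemplateInstance(process="Replication", substrate_id="chromosome")
    mols = {dnaa.id: dnaa, replisome.id: replisome}
    for region in regions:
        node = region_node(region)
        mols[node.id] = node

    bound_ids = []
    for region in ori_sites:
        bound = bound_region_node(region, "DNAA", "DnaA")
        mols[bound.id] = bound
        bound_ids.append(bound.id)
        inst.steps.append(
            TemplateStep(
                ReactionNode(
                    names.rx("PROTEIN_DNA", "DNAA_BIND", region.index),
                    f"DnaA binding at region {region.index}",
                    "Protein-DNA Interaction",
                ),
                reactants=[(dnaa.id, 1), (names.region(region.index), 1)],
                products=[(names.bound_region(region.index, "DNAA"), 1)],
            )
        )

    state_cw0 = _transient(names.replisome_state("CW", 0), "replisome (clockwise arm)")
    state_ccw0 = _transient(
        names.replisome_state("CCW", n - 1), "replisome (counter-clockwise arm)"
    )
    mols[state_cw0.id] = state_cw0
    mols[state_ccw0.id] = state_ccw0
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("REPLICATION", "FORMATION"),
                "replication complex formation",
                "Replication",
            ),
            reactants=_agg(
                [(b, 1) for b in bound_ids]
                + [(replisome.id, 2), (names.region(0), 1), (names.region(n - 1), 1)]
            ),
            products=[(state_cw0.id, 1), (state_ccw0.id, 1)],
        )
    )

    def dntp_pairs(region):
        counts = region_nt_counts(region, kb.genome_sequence, both_strands=True)
        pairs = [(names.dntp(b), c) for b, c in sorted(counts.items()) if c]
        for mid, _ in pairs:
            mols.setdefault(mid, metabolite_node(kb, mid))
        return pairs

    def arm(tag: str, indices: list):
        for j, k_idx in enumerate(indices):
            nxt = indices[j + 1] if j + 1 < len(indices) else "DONE"
            state_next = _transient(
                names.replisome_state(tag, nxt), f"replisome ({tag} arm)"
            )
            mols.setdefault(state_next.id, state_next)
            reactants = [(names.replisome_state(tag, k_idx), 1)] + dntp_pairs(regions[k_idx])
            if nxt != "DONE":
                reactants.append((names.region(nxt), 1))
            inst.steps.append(
                TemplateStep(
                    ReactionNode(
                        names.rx("REPLICATION", "ELONG", tag, k_idx),
                        f"replication elongation at region {k_idx}",
                        "Replication",
                    ),
                    reactants=_agg(reactants),
                    products=[(names.region(k_idx), 2), (names.replisome_state(tag, nxt), 1)],
                )
            )

    arm("CW", list(range(0, ter_idx)))
    arm("CCW", list(range(n - 1, ter_idx - 1, -1)))

    dup = _transient(names.DUPLICATED_CHROMOSOME, "duplicated chromosome")
    mols[dup.id] = dup
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("REPLICATION", "TERMINUS_RELEASE"),
                "terminus release of replisomes",
                "Replication",
            ),
            reactants=[
                (names.replisome_state("CW", "DONE"), 1),
                (names.replisome_state("CCW", "DONE"), 1),
            ],
            products=[(replisome.id, 2), (dup.id, 1)],
        )
    )
    inst.new_molecules = list(mols.values())
    return inst


# -- transcription -----------------------------------------------------------


def tu_is_cleaved(kb: KBBundle, tu: TUSpec) -> bool:
    types = {kb.gene_by_id[g].product_type for g in tu.gene_ids}
    return len(tu.gene_ids) >= 2 and "protein" not in types


def instantiate_transcription(
    kb: KBBundle, tu: TUSpec, regions: list, cfg: Optional[TemplateConfig] = None
) -> TemplateInstance:
    """Transcription of one TU: complex formation, one elongation per
    spanned chromosome region, polymerase release, and -- for cleaved
    polycistronic RNA (tRNA/rRNA operons) -- cleavage plus per-gene
    maturation.  Regions are consumed and reproduced (net zero) so region
    copy numbers stay meaningful; a transcription-factor-bound region is a
    formation modifier when annotated."""
    cfg = cfg or TemplateConfig()
    span = regions_overlapping(regions, tu.start, tu.end, kb)
    if not span:
        raise TemplateError(f"TU {tu.id} resolves to zero chromosome regions")
    if tu.strand == "-":
        span = list(reversed(span))
    first = span[0]

    rnap = _machine_complex(kb, "rna_polymerase")
    inst = TemplateInstance(process="Transcription", substrate_id=tu.id)
    mols = {rnap.id: rnap}
    for idx in span:
        node = region_node(regions[idx])
        mols[node.id] = node

    form_modifiers = []
    if tu.tf_gene:
        tf = monomer_node(kb, tu.tf_gene)
        bound = bound_region_node(regions[first], tu.tf_gene, kb.gene_by_id[tu.tf_gene].name)
        mols[tf.id] = tf
        mols[bound.id] = bound
        inst.steps.append(
            TemplateStep(
                ReactionNode(
                    names.rx("PROTEIN_DNA", "TF_BIND", tu.id),
                    f"transcription factor binding for {tu.id}",
                    "Protein-DNA Interaction",
                ),
                reactants=[(tf.id, 1), (names.region(first), 1)],
                products=[(bound.id, 1)],
            )
        )
        form_modifiers.append(bound.id)

    state_first = _transient(names.tx_state(tu.id, first), f"transcription complex ({tu.id})")
    mols[state_first.id] = state_first
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("TRANSCRIPTION", tu.id, "FORM"),
                f"transcription complex formation ({tu.id})",
                "Transcription",
            ),
            reactants=[(rnap.id, 1), (names.region(first), 1)],
            products=[(state_first.id, 1)],
            modifiers=form_modifiers,
        )
    )

    # NTP stoichiometry: transcript portion overlapping each region.
    length = kb.genome_length
    tu_lo = (tu.start - kb.ori_position) % length
    tu_hi = tu_lo + (tu.end - tu.start)

    def ntp_pairs(idx):
        region = regions[idx]
        best = None
        for shift in (0, length):
            a = max(region.start + shift, tu_lo)
            b = min(region.end + shift, tu_hi)
            if b > a:
                best = (a, b)
        if best is None:
            return []
        abs_a = (best[0] + kb.ori_position) % length
        seq = kb.genome_sequence[abs_a:abs_a + (best[1] - best[0])]
        if tu.strand == "-":
            from .kb import revcomp

            seq = revcomp(seq)
        counts = Counter(seq.replace("T", "U"))
        return [(names.ntp(b), c) for b, c in sorted(counts.items()) if c]

    ppi_total = 0
    for j, idx in enumerate(span):
        nxt = span[j + 1] if j + 1 < len(span) else "DONE"
        state_next = _transient(names.tx_state(tu.id, nxt), f"transcription complex ({tu.id})")
        mols.setdefault(state_next.id, state_next)
        ntps = ntp_pairs(idx)
        ppi_here = sum(c for _, c in ntps)
        ppi_total += ppi_here
        reactants = [(names.tx_state(tu.id, idx), 1)] + ntps
        if nxt != "DONE":
            reactants.append((names.region(nxt), 1))
        products = [(names.region(idx), 1), (names.tx_state(tu.id, nxt), 1)]
        if ppi_here:
            products.append((names.PPI, ppi_here))
            mols.setdefault(names.PPI, metabolite_node(kb, names.PPI))
        inst.steps.append(
            TemplateStep(
                ReactionNode(
                    names.rx("TRANSCRIPTION", tu.id, "ELONG", idx),
                    f"transcription elongation ({tu.id}, region {idx})",
                    "Transcription",
                ),
                reactants=_agg(reactants),
                products=_agg(products),
            )
        )
        for mid, _ in ntps:
            mols.setdefault(mid, metabolite_node(kb, mid))

    cleaved = tu_is_cleaved(kb, tu)
    single_rna = (
        len(tu.gene_ids) == 1
        and kb.gene_by_id[tu.gene_ids[0]].product_type != "protein"
    )
    if single_rna:
        product = gene_rna_node(kb, tu.gene_ids[0])
    else:
        product = tu_rna_node(kb, tu, cleaved)
    mols[product.id] = product
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("TRANSCRIPTION", tu.id, "RELEASE"),
                f"polymerase release ({tu.id})",
                "Transcription",
            ),
            reactants=[(names.tx_state(tu.id, "DONE"), 1)],
            products=[(rnap.id, 1), (product.id, 1)],
        )
    )

    if cleaved:
        rnase = complex_node(kb, kb.decay_params["ribonuclease"])
        mols[rnase.id] = rnase
        precursors = []
        for gid in tu.gene_ids:
            pre = gene_rna_node(kb, gid, state="precursor")
            mols[pre.id] = pre
            precursors.append(pre)
        frag_mass = (product.mass or 0.0) - sum(p.mass or 0.0 for p in precursors)
        cleave_products = [(p.id, 1) for p in precursors]
        if frag_mass > 1e-9:
            frag = _transient(names.tu_fragment(tu.id), f"{tu.id} cleavage fragment", frag_mass)
            mols[frag.id] = frag
            cleave_products.append((frag.id, 1))
        inst.steps.append(
            TemplateStep(
                ReactionNode(
                    names.rx("RNA_PROCESSING", tu.id, "CLEAVAGE"),
                    f"cleavage of {tu.id} transcript",
                    "RNA Processing",
                ),
                reactants=[(product.id, 1)],
                products=cleave_products,
                modifiers=[rnase.id],
            )
        )
        for pre in precursors:
            gid = next(iter(pre.gene_ids))
            mature = gene_rna_node(kb, gid)
            mols[mature.id] = mature
            inst.steps.append(
                TemplateStep(
                    ReactionNode(
                        names.rx("RNA_PROCESSING", gid, "MATURATION"),
                        f"RNA maturation of {gid}",
                        "RNA Processing",
                    ),
                    reactants=[(pre.id, 1)],
                    products=[(mature.id, 1)],
                )
            )

    if cfg.stall_templates:
        stalled = _transient(names.mol(f"TX_COMPLEX_{tu.id}_STALLED"), f"stalled transcription ({tu.id})")
        mols[stalled.id] = stalled
        inst.steps.append(
            TemplateStep(
                ReactionNode(
                    names.rx("TRANSCRIPTION", tu.id, "STALL"),
                    f"transcription stall ({tu.id})",
                    "Transcription",
                ),
                reactants=[(state_first.id, 1)],
                products=[(stalled.id, 1)],
            )
        )
        inst.steps.append(
            TemplateStep(
                ReactionNode(
                    names.rx("TRANSCRIPTION", tu.id, "STALL_RELEASE"),
                    f"stalled polymerase release ({tu.id})",
                    "Transcription",
                ),
                reactants=[(stalled.id, 1)],
                products=[(rnap.id, 1), (names.region(first), 1)],
            )
        )
    inst.new_molecules = list(mols.values())
    return inst


# -- aminoacylation ----------------------------------------------------------


def instantiate_aminoacylation(
    kb: KBBundle, trna_gene_id: str, cfg: Optional[TemplateConfig] = None
) -> TemplateInstance:
    cfg = cfg or TemplateConfig()
    letter = next((a for a, g in kb.trna_genes.items() if g == trna_gene_id), None)
    if letter is None:
        raise TemplateError(f"gene {trna_gene_id!r} is not a mapped tRNA gene")
    synth_gene = kb.synthetase_genes.get(letter)
    if synth_gene is None:
        raise TemplateError(f"no aminoacyl-tRNA synthetase mapped for {letter!r}")
    trna = gene_rna_node(kb, trna_gene_id)
    charged = charged_trna_node(kb, letter)
    synth = monomer_node(kb, synth_gene)
    aa = metabolite_node(kb, names.aa(letter))
    atp = metabolite_node(kb, names.ntp("A"))
    amp = metabolite_node(kb, names.nmp("A"))
    ppi = metabolite_node(kb, names.PPI)
    w = cfg.aminoacylation_atp
    inst = TemplateInstance(process="tRNA Aminoacylation", substrate_id=trna_gene_id)
    inst.new_molecules = [trna, charged, synth, aa, atp, amp, ppi]
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("AMINOACYLATION", trna_gene_id),
                f"aminoacylation of {trna_gene_id} ({letter})",
                "tRNA Aminoacylation",
            ),
            reactants=[(trna.id, 1), (aa.id, 1), (atp.id, w)],
            products=[(charged.id, 1), (amp.id, w), (ppi.id, w)],
            modifiers=[synth.id],
        )
    )
    return inst


# -- translation -------------------------------------------------------------


def instantiate_translation(
    kb: KBBundle, gene: GeneSpec, cfg: Optional[TemplateConfig] = None
) -> TemplateInstance:
    """Translation of one protein-coding gene.

    Formation consumes the 70S ribosome and IF-3 with IF-1, IF-2 and the
    mRNA as modifiers (mRNA copy number is unchanged by translation);
    elongation consumes charged tRNAs per residue count and GTP, releasing
    uncharged tRNAs, IF-3, the ribosome, GDP, Pi and condensation water;
    maturation converts the immature chain into the functional monomer,
    with chaperones as modifiers when annotated and, for secreted
    proteins, the membrane transporter and signal peptidase as modifiers
    plus the cleaved signal peptide as product."""
    cfg = cfg or TemplateConfig()
    if gene.product_type != "protein":
        raise TemplateError(f"gene {gene.id} is not protein-coding")
    seq = kb.protein_sequence(gene)
    L = len(seq)
    ann = kb.annotation(gene.id)
    tu = kb.tu_of_gene(gene.id)

    ribosome = _machine_complex(kb, "ribosome")
    if1 = _machine_monomer(kb, "if1")
    if2 = _machine_monomer(kb, "if2")
    if3 = _machine_monomer(kb, "if3")
    ef = _machine_monomer(kb, "elongation_factor")
    mrna = tu_rna_node(kb, tu, cleaved=False)
    immature = monomer_node(kb, gene.id, state="immature")
    functional = monomer_node(kb, gene.id, state="functional")
    tl_state = _transient(
        names.tl_state(gene.id),
        f"translation complex ({gene.id})",
        mass=(ribosome.mass or 0.0) + (if3.mass or 0.0),
    )

    inst = TemplateInstance(process="Translation", substrate_id=gene.id)
    mols = {
        m.id: m for m in (ribosome, if1, if2, if3, ef, mrna, immature, functional, tl_state)
    }

    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("TRANSLATION", gene.id, "FORM"),
                f"translation complex formation ({gene.id})",
                "Translation",
            ),
            reactants=[(ribosome.id, 1), (if3.id, 1)],
            products=[(tl_state.id, 1)],
            modifiers=[if1.id, if2.id, mrna.id],
        )
    )

    residue_counts = Counter(seq)
    charged_pairs, uncharged_pairs = [], []
    for letter, count in sorted(residue_counts.items()):
        if letter not in kb.trna_genes:
            raise TemplateError(f"no tRNA gene mapped for residue {letter!r} (gene {gene.id})")
        charged = charged_trna_node(kb, letter)
        uncharged = gene_rna_node(kb, kb.trna_genes[letter])
        mols.setdefault(charged.id, charged)
        mols.setdefault(uncharged.id, uncharged)
        charged_pairs.append((charged.id, count))
        uncharged_pairs.append((uncharged.id, count))
    gtp_w = cfg.energy_per_residue * L
    for mid in (names.ntp("G"), names.GDP, names.PI, names.WATER):
        mols.setdefault(mid, metabolite_node(kb, mid))
    elong_products = uncharged_pairs + [
        (immature.id, 1),
        (if3.id, 1),
        (ribosome.id, 1),
        (names.GDP, gtp_w),
        (names.PI, gtp_w),
    ]
    if L > 1:
        elong_products.append((names.WATER, L - 1))
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("TRANSLATION", gene.id, "ELONG"),
                f"translation elongation ({gene.id})",
                "Translation",
            ),
            reactants=_agg([(tl_state.id, 1), (names.ntp("G"), gtp_w)] + charged_pairs),
            products=_agg(elong_products),
            modifiers=[ef.id],
        )
    )

    mat_reactants = [(immature.id, 1)]
    mat_products = [(functional.id, 1)]
    mat_modifiers = []
    for chap in ann.chaperones:
        chap_node = monomer_node(kb, chap)
        mols.setdefault(chap_node.id, chap_node)
        mat_modifiers.append(chap_node.id)
    for met_ref in ann.maturation_modifier_metabolites:
        met = metabolite_node(kb, met_ref)
        mols.setdefault(met.id, met)
        mat_modifiers.append(met.id)
    if ann.secreted:
        if not ann.transporter or not ann.peptidase:
            raise TemplateError(
                f"secreted protein {gene.id} lacks a transporter or peptidase annotation"
            )
        for ref in (ann.transporter, ann.peptidase):
            node = monomer_node(kb, ref)
            mols.setdefault(node.id, node)
            mat_modifiers.append(node.id)
        peptide = MoleculeNode(
            id=names.signal_peptide(gene.id),
            name=f"{gene.name} signal peptide",
            category="other",
            compartment="c",
            mass=masses.protein_mass(seq[: cfg.signal_peptide_length]),
            gene_ids=frozenset({gene.id}),
        )
        mols.setdefault(peptide.id, peptide)
        mols.setdefault(names.WATER, metabolite_node(kb, names.WATER))
        mat_reactants.append((names.WATER, 1))
        mat_products.append((peptide.id, 1))
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("PROTEIN_MATURATION", gene.id),
                f"protein maturation ({gene.id})",
                "Protein Maturation",
            ),
            reactants=mat_reactants,
            products=mat_products,
            modifiers=mat_modifiers,
        )
    )

    if cfg.stall_templates:
        stalled = _transient(
            names.mol(f"TL_COMPLEX_{gene.id}_STALLED"), f"stalled translation ({gene.id})"
        )
        mols.setdefault(stalled.id, stalled)
        inst.steps.append(
            TemplateStep(
                ReactionNode(
                    names.rx("TRANSLATION", gene.id, "STALL"),
                    f"translation stall ({gene.id})",
                    "Translation",
                ),
                reactants=[(tl_state.id, 1)],
                products=[(stalled.id, 1)],
            )
        )
        inst.steps.append(
            TemplateStep(
                ReactionNode(
                    names.rx("TRANSLATION", gene.id, "STALL_RELEASE"),
                    f"stalled ribosome release ({gene.id})",
                    "Translation",
                ),
                reactants=[(stalled.id, 1)],
                products=[(ribosome.id, 1), (if3.id, 1)],
            )
        )
    inst.new_molecules = list(mols.values())
    return inst


# -- complexation ------------------------------------------------------------


def instantiate_complexation(kb: KBBundle, cplx_id: str) -> TemplateInstance:
    spec = kb.complex_by_id.get(cplx_id)
    if spec is None:
        raise TemplateError(f"unknown complex {cplx_id!r}")
    if not spec.subunits:
        raise TemplateError(f"complex {cplx_id} has zero subunits")
    product = complex_node(kb, cplx_id)
    inst = TemplateInstance(process="Macromolecular Complexation", substrate_id=cplx_id)
    mols = {product.id: product}
    reactants = []
    for ref, stoich in spec.subunits:
        if ref in kb.complex_by_id:
            node = complex_node(kb, ref)
        elif ref in kb.gene_by_id:
            gene = kb.gene_by_id[ref]
            node = (
                monomer_node(kb, ref)
                if gene.product_type == "protein"
                else gene_rna_node(kb, ref)
            )
        else:
            node = metabolite_node(kb, ref)
        mols.setdefault(node.id, node)
        reactants.append((node.id, stoich))
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("COMPLEXATION", cplx_id),
                f"formation of {spec.name}",
                "Macromolecular Complexation",
            ),
            reactants=_agg(reactants),
            products=[(product.id, 1)],
        )
    )
    inst.new_molecules = list(mols.values())
    return inst


# -- decay -------------------------------------------------------------------


def _monomer_pool(kb: KBBundle, mol: MoleculeNode) -> tuple:
    """(amino-acid Counter, nucleotide Counter, peptide-bond count) of a molecule."""
    aa_counts: Counter = Counter()
    nt_counts: Counter = Counter()
    bonds = 0

    def add_gene_product(gene_id, stoich, secreted_trim):
        nonlocal bonds
        gene = kb.gene_by_id[gene_id]
        if gene.product_type == "protein":
            seq = kb.protein_sequence(gene)
            if secreted_trim:
                seq = seq[TemplateConfig().signal_peptide_length:]
            for letter in seq:
                aa_counts[letter] += stoich
            bonds += (len(seq) - 1) * stoich
        else:
            transcript = kb.transcript_sequence(gene.start, gene.end, gene.strand)
            for b in transcript:
                nt_counts[b] += stoich

    if mol.category == "protein_monomer":
        gid = next(iter(mol.gene_ids))
        trim = mol.state == "functional" and kb.annotation(gid).secreted
        add_gene_product(gid, 1, trim)
    elif mol.category == "rna":
        name, _ = names.split(mol.id)
        stem = name[:-4] if name.endswith("_RNA") else name
        if stem in kb.gene_by_id:
            gene = kb.gene_by_id[stem]
            for b in kb.transcript_sequence(gene.start, gene.end, gene.strand):
                nt_counts[b] += 1
        elif stem in kb.tu_by_id:
            tu = kb.tu_by_id[stem]
            for b in kb.transcript_sequence(tu.start, tu.end, tu.strand):
                nt_counts[b] += 1
        else:
            raise TemplateError(f"cannot derive sequence for RNA {mol.id!r}")
    elif mol.category == "protein_complex":
        name, _ = names.split(mol.id)

        def walk(cid, mult):
            for ref, stoich in kb.complex_by_id[cid].subunits:
                if ref in kb.complex_by_id:
                    walk(ref, mult * stoich)
                elif ref in kb.gene_by_id:
                    add_gene_product(ref, mult * stoich, False)
        walk(name, 1)
    else:
        raise TemplateError(f"molecule {mol.id!r} ({mol.category}) is not degradable")
    return aa_counts, nt_counts, bonds


def instantiate_decay(kb: KBBundle, mol: MoleculeNode) -> TemplateInstance:
    """Degradation of an RNA, protein monomer or complex to its monomer pool.

    RNA degrades to nucleoside monophosphates (catalysed by the generic
    ribonuclease); proteins hydrolyse to free amino acids, consuming one
    water per peptide bond (catalysed by the generic protease).  Complexes
    degrade to the flattened monomer pool of all their chains."""
    if mol.category not in ("rna", "protein_monomer", "protein_complex"):
        raise TemplateError(f"molecule {mol.id!r} ({mol.category}) is not degradable")
    aa_counts, nt_counts, bonds = _monomer_pool(kb, mol)
    is_rna_only = mol.category == "rna"
    process = "RNA Decay" if is_rna_only else "Protein Decay"
    machinery_key = "ribonuclease" if is_rna_only else "protease"
    machine = complex_node(kb, kb.decay_params[machinery_key])

    inst = TemplateInstance(process=process, substrate_id=mol.id)
    mols = {mol.id: mol, machine.id: machine}
    reactants = [(mol.id, 1)]
    products = []
    for letter, count in sorted(aa_counts.items()):
        node = metabolite_node(kb, names.aa(letter))
        mols.setdefault(node.id, node)
        products.append((node.id, count))
    for base, count in sorted(nt_counts.items()):
        node = metabolite_node(kb, names.nmp(base))
        mols.setdefault(node.id, node)
        products.append((node.id, count))
    if bonds > 0:
        water = metabolite_node(kb, names.WATER)
        mols.setdefault(water.id, water)
        reactants.append((water.id, bonds))
    name, _ = names.split(mol.id)
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("DECAY", name),
                f"degradation of {mol.name}",
                process,
            ),
            reactants=reactants,
            products=products,
            modifiers=[machine.id],
        )
    )
    inst.new_molecules = list(mols.values())
    return inst


# -- cell division -----------------------------------------------------------


def instantiate_cell_division(kb: KBBundle, net) -> TemplateInstance:
    """The single critical cell-division reaction.

    Every required complex (FtsZ ring, chromosome segregation machinery,
    any organism-specific requirement) and the duplicated chromosome are
    linked as modifiers; the reaction has no reactants or products.  All
    requirements must already exist in the network."""
    modifiers = []
    for cplx_id in kb.division_requirements:
        if cplx_id not in kb.complex_by_id:
            raise TemplateError(f"division requirement {cplx_id!r} is not a known complex")
        mol_id = names.mol(cplx_id, kb.complex_by_id[cplx_id].compartment)
        if not net.has_node(mol_id):
            raise TemplateError(f"division requirement {mol_id!r} missing from the network")
        modifiers.append(mol_id)
    if not net.has_node(names.DUPLICATED_CHROMOSOME):
        raise TemplateError(
            f"duplicated chromosome {names.DUPLICATED_CHROMOSOME!r} missing from the network"
        )
    modifiers.append(names.DUPLICATED_CHROMOSOME)
    inst = TemplateInstance(process="Cellular Division", substrate_id="cell")
    inst.steps.append(
        TemplateStep(
            ReactionNode(
                names.rx("CELL_DIVISION"),
                "cell division reaction",
                "Cellular Division",
            ),
            modifiers=modifiers,
        )
    )
    return inst
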