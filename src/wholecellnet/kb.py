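"""Organism knowledge-base schema, reader and writer.

The knowledge base is a single JSON document (``schema_version`` required)
holding the slice of an organism database that network construction
consumes: the circular genome, genes grouped into transcription units,
DnaA binding sites, metabolites and metabolic reactions, macromolecular
complexes, per-protein annotations (chaperones, secretion, cofactors),
decay machinery, the requirements of the cell-division reaction, and
optional experimental gene-essentiality labels.

Protein sequences may be stored explicitly per gene; otherwise they are
derived from the gene's nucleotide sequence with a deterministic reduced
genetic code over the knowledge base's amino-acid alphabet (codon ordinal
modulo alphabet size, no stop codons).  The alphabet is a KB field, not a
constant, so reduced-alphabet toy organisms are first-class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from . import names
from .errors import KBError

SCHEMA_VERSION = "1.0"

PRODUCT_TYPES = ("protein", "tRNA", "rRNA", "ncRNA")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneSpec:
    id: str
    name: str
    start: int
    end: int
    strand: str
    product_type: str
    protein_sequence: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TUSpec:
    id: str
    gene_ids: list
    start: int
    end: int
    strand: str
    tf_gene: Optional[str] = None


@dataclass
class BindingSiteSpec:
    id: str
    position: int
    length: int
    protein: str

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass
class MetaboliteSpec:
    id: str
    name: str
    mass: Optional[float]
    compartments: list
    boundary_compartments: list = field(default_factory=list)


@dataclass
class ReactionSpec:
    id: str
    name: str
    process: str
    reactants: list  # [(molecule_id, weight)]
    products: list
    modifiers: list  # refs: gene id, complex id, or molecule id
    reversible: bool = False
    evidence: Optional[str] = None


@dataclass
class ComplexSpec:
    id: str
    name: str
    subunits: list  # [(component_id, stoichiometry)]; component = gene or complex id
    compartment: str = "c"


@dataclass
class ProteinAnnotation:
    chaperones: list = field(default_factory=list)
    secreted: bool = False
    compartment: str = "c"
    transporter: Optional[str] = None
    peptidase: Optional[str] = None
    maturation_modifier_metabolites: list = field(default_factory=list)


@dataclass
class KBBundle:
    """Fully cross-referenced organism knowledge base."""

    genome_sequence: str
    ori_position: int
    ter_position: int
    genes: list
    transcription_units: list
    binding_sites: list
    metabolites: list
    metabolic_reactions: list
    complexes: list
    extra_reactions: list = field(default_factory=list)
    protein_annotations: dict = field(default_factory=dict)
    decay_params: dict = field(default_factory=dict)
    machinery: dict = field(default_factory=dict)
    trna_genes: dict = field(default_factory=dict)
    synthetase_genes: dict = field(default_factory=dict)
    division_requirements: list = field(default_factory=list)
    experimental_essentiality: dict = field(default_factory=dict)
    amino_acid_alphabet: str = "ACDEFGHIKLMNPQRSTVWY"
    energy: dict = field(default_factory=lambda: {"energy_per_residue": 2, "aminoacylation_atp": 1})
    organism: str = "synthetic"

    # -- derived lookups ----------------------------------------------------

    @property
    def genome_length(self) -> int:
        return len(self.genome_sequence)

    @property
    def gene_by_id(self) -> dict:
        return {g.id: g for g in self.genes}

    @property
    def tu_by_id(self) -> dict:
        return {t.id: t for t in self.transcription_units}

    @property
    def complex_by_id(self) -> dict:
        return {c.id: c for c in self.complexes}

    @property
    def metabolite_by_id(self) -> dict:
        return {m.id: m for m in self.metabolites}

    def tu_of_gene(self, gene_id: str) -> TUSpec:
        for tu in self.transcription_units:
            if gene_id in tu.gene_ids:
                return tu
        raise KBError(f"gene {gene_id!r} belongs to no transcription unit")

    def annotation(self, gene_id: str) -> ProteinAnnotation:
        return self.protein_annotations.get(gene_id, ProteinAnnotation())

    # -- sequence derivation ------------------------------------------------

    def gene_sequence(self, gene: GeneSpec) -> str:
        seq = self.genome_sequence[gene.start:gene.end]
        return revcomp(seq) if gene.strand == "-" else seq

    def transcript_sequence(self, start: int, end: int, strand: str) -> str:
        seq = self.genome_sequence[start:end]
        if strand == "-":
            seq = revcomp(seq)
        return seq.replace("T", "U")

    def protein_sequence(self, gene: GeneSpec) -> str:
        """Residue string for a protein-coding gene.

        Uses the explicit ``protein_sequence`` when present; otherwise maps
        each codon of the coding sequence to ``alphabet[ordinal % n]``.
        """
        if gene.product_type != "protein":
            raise KBError(f"gene {gene.id} is not protein-coding")
        if gene.protein_sequence:
            return gene.protein_sequence
        seq = self.gene_sequence(gene)
        n = len(self.amino_acid_alphabet)
        if n == 0:
            raise KBError("empty amino-acid alphabet")
        residues = []
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            ordinal = (
                16 * _BASE_INDEX[codon[0]] + 4 * _BASE_INDEX[codon[1]] + _BASE_INDEX[codon[2]]
            )
            residues.append(self.amino_acid_alphabet[ordinal % n])
        if not residues:
            raise KBError(f"gene {gene.id}: no protein sequence derivable (length {gene.length})")
        return "".join(residues)

    # -- reference resolution ------------------------------------------------

    def resolve_component(self, ref: str) -> str:
        """Map a KB component reference to a molecule node id.

        A gene id resolves to its functional product (monomer for coding
        genes, RNA node otherwise); a complex id to the complex molecule in
        its compartment; a ``NAME[comp]`` string is passed through.
        """
        if ref in self.complex_by_id:
            return names.mol(ref, self.complex_by_id[ref].compartment)
        if ref in self.gene_by_id:
            gene = self.gene_by_id[ref]
            if gene.product_type == "protein":
                return names.monomer(ref, self.annotation(ref).compartment)
            return names.gene_rna(ref)
        if ref.endswith("]"):
            return ref
        raise KBError(f"unresolvable component reference {ref!r}")

    # -- integrity ----------------------------------------------------------

    def validate(self) -> None:
        length = self.genome_length
        if length <= 0:
            raise KBError("empty genome sequence")
        for pos_name in ("ori_position", "ter_position"):
            pos = getattr(self, pos_name)
            if not 0 <= pos < length:
                raise KBError(f"{pos_name}={pos} outside genome of length {length}")
        seen = set()
        for g in self.genes:
            if g.id in seen:
                raise KBError(f"duplicate gene id {g.id}")
            seen.add(g.id)
            if not (0 <= g.start < g.end <= length):
                raise KBError(
                    f"gene {g.id}: coordinates [{g.start},{g.end}) outside genome "
                    f"of length {length}"
                )
            if g.strand not in ("+", "-"):
                raise KBError(f"gene {g.id}: bad strand {g.strand!r}")
            if g.product_type not in PRODUCT_TYPES:
                raise KBError(f"gene {g.id}: bad product_type {g.product_type!r}")
        membership: dict = {}
        tus = sorted(self.transcription_units, key=lambda t: t.start)
        for tu in tus:
            if not (0 <= tu.start < tu.end <= length):
                raise KBError(f"TU {tu.id}: coordinates outside genome")
            for gid in tu.gene_ids:
                if gid not in seen:
                    raise KBError(f"TU {tu.id}: dangling gene reference {gid!r}")
                if gid in membership:
                    raise KBError(f"gene {gid} assigned to TUs {membership[gid]} and {tu.id}")
                membership[gid] = tu.id
            if tu.tf_gene is not None and tu.tf_gene not in seen:
                raise KBError(f"TU {tu.id}: dangling TF gene {tu.tf_gene!r}")
        for a, b in zip(tus, tus[1:]):
            if b.start < a.end:
                raise KBError(f"TUs {a.id} and {b.id} overlap")
        for g in self.genes:
            if g.id not in membership:
                raise KBError(f"gene {g.id} belongs to no transcription unit")
            tu = self.tu_by_id[membership[g.id]]
            if not (tu.start <= g.start and g.end <= tu.end):
                raise KBError(f"gene {g.id} not contained in its TU {tu.id}")
        sites = sorted(self.binding_sites, key=lambda s: s.position)
        for s in sites:
            if not (0 <= s.position and s.end <= length):
                raise KBError(f"binding site {s.id} outside genome")
        for a, b in zip(sites, sites[1:]):
            if b.position < a.end:
                raise KBError(f"binding sites {a.id} and {b.id} overlap")
        met_ids = set()
        for m in self.metabolites:
            if m.id in met_ids:
                raise KBError(f"duplicate metabolite id {m.id}")
            met_ids.add(m.id)
            for comp in m.compartments:
                if comp not in ("c", "m", "tc", "tm", "e"):
                    raise KBError(f"metabolite {m.id}: bad compartment {comp!r}")
            if not set(m.boundary_compartments) <= set(m.compartments):
                raise KBError(f"metabolite {m.id}: boundary compartment not declared")
        cplx_ids = set()
        for c in self.complexes:
            if c.id in cplx_ids:
                raise KBError(f"duplicate complex id {c.id}")
            cplx_ids.add(c.id)
        for c in self.complexes:
            if not c.subunits:
                raise KBError(f"complex {c.id} has no subunits")
            for ref, stoich in c.subunits:
                if ref not in seen and ref not in cplx_ids:
                    raise KBError(f"complex {c.id}: dangling subunit reference {ref!r}")
                if not stoich > 0:
                    raise KBError(f"complex {c.id}: non-positive stoichiometry for {ref}")
        valid_species = {
            names.mol(m.id, comp) for m in self.metabolites for comp in m.compartments
        }
        for rxn in list(self.metabolic_reactions) + list(self.extra_reactions):
            for mid, w in list(rxn.reactants) + list(rxn.products):
                if mid not in valid_species:
                    raise KBError(f"reaction {rxn.id}: unknown species {mid!r}")
                if not w > 0:
                    raise KBError(f"reaction {rxn.id}: non-positive stoichiometry for {mid}")
            for ref in rxn.modifiers:
                if ref not in seen and ref not in cplx_ids and ref not in valid_species:
                    raise KBError(f"reaction {rxn.id}: dangling enzyme reference {ref!r}")
        for ref in self.division_requirements:
            if ref not in cplx_ids:
                raise KBError(f"division requirement {ref!r} is not a known complex")
        for role, ref in {**self.decay_params, **self.machinery}.items():
            if ref not in seen and ref not in cplx_ids:
                raise KBError(f"{role!r} reference {ref!r} resolves to no gene or complex")
        for aa, gid in {**self.trna_genes, **self.synthetase_genes}.items():
            if aa not in self.amino_acid_alphabet:
                raise KBError(f"tRNA/synthetase entry for {aa!r} outside alphabet")
            if gid not in seen:
                raise KBError(f"tRNA/synthetase gene {gid!r} unknown")
        for gid, label in self.experimental_essentiality.items():
            if gid not in seen:
                raise KBError(f"essentiality label for unknown gene {gid!r}")
            if label not in ("essential", "non-essential"):
                raise KBError(f"gene {gid}: bad essentiality label {label!r}")


# -- serialization -----------------------------------------------------------


def _to_jsonable(bundle: KBBundle, genome_fasta: Optional[str]) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "organism": bundle.organism,
        "genome": {
            "ori_position": bundle.ori_position,
            "ter_position": bundle.ter_position,
        },
        "amino_acid_alphabet": bundle.amino_acid_alphabet,
        "genes": [asdict(g) for g in bundle.genes],
        "transcription_units": [asdict(t) for t in bundle.transcription_units],
        "binding_sites": [asdict(s) for s in bundle.binding_sites],
        "metabolites": [asdict(m) for m in bundle.metabolites],
        "metabolic_reactions": [asdict(r) for r in bundle.metabolic_reactions],
        "extra_reactions": [asdict(r) for r in bundle.extra_reactions],
        "complexes": [asdict(c) for c in bundle.complexes],
        "protein_annotations": {
            gid: asdict(ann) for gid, ann in sorted(bundle.protein_annotations.items())
        },
        "decay_params": bundle.decay_params,
        "machinery": bundle.machinery,
        "trna_genes": bundle.trna_genes,
        "synthetase_genes": bundle.synthetase_genes,
        "division_requirements": bundle.division_requirements,
        "experimental_essentiality": bundle.experimental_essentiality,
        "energy": bundle.energy,
    }
    if genome_fasta:
        doc["genome"]["fasta"] = genome_fasta
    else:
        doc["genome"]["sequence"] = bundle.genome_sequence
    return doc


def write_kb(bundle: KBBundle, path, genome_fasta: Optional[str] = None) -> None:
    """Write a knowledge base as JSON; optionally reference the genome as FASTA."""
    path = Path(path)
    if genome_fasta:
        fasta_path = path.parent / genome_fasta
        with open(fasta_path, "w") as fh:
            fh.write(f">{bundle.organism}\n")
            seq = bundle.genome_sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(path, "w") as fh:
        json.dump(_to_jsonable(bundle, genome_fasta), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _req(doc: dict, key: str):
    if key not in doc:
        raise KBError(f"missing required field {key!r}")
    return doc[key]


def read_kb(path) -> KBBundle:
    """Read and cross-validate a knowledge-base JSON document."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    version = _req(doc, "schema_version")
    if version != SCHEMA_VERSION:
        raise KBError(f"unsupported schema_version {version!r}")
    genome = _req(doc, "genome")
    if "sequence" in genome:
        sequence = genome["sequence"]
    elif "fasta" in genome:
        fasta_path = path.parent / genome["fasta"]
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if not records:
            raise KBError(f"no sequence in FASTA {fasta_path}")
        sequence = str(records[0].seq).upper()
    else:
        raise KBError("genome must provide 'sequence' or 'fasta'")
    bundle = KBBundle(
        genome_sequence=sequence,
        ori_position=_req(genome, "ori_position"),
        ter_position=_req(genome, "ter_position"),
        genes=[GeneSpec(**g) for g in _req(doc, "genes")],
        transcription_units=[TUSpec(**t) for t in _req(doc, "transcription_units")],
        binding_sites=[BindingSiteSpec(**s) for s in doc.get("binding_sites", [])],
        metabolites=[MetaboliteSpec(**m) for m in _req(doc, "metabolites")],
        metabolic_reactions=[
            ReactionSpec(**_tuplify(r)) for r in _req(doc, "metabolic_reactions")
        ],
        extra_reactions=[ReactionSpec(**_tuplify(r)) for r in doc.get("extra_reactions", [])],
        complexes=[ComplexSpec(**_tuplify_complex(c)) for c in doc.get("complexes", [])],
        protein_annotations={
            gid: ProteinAnnotation(**ann)
            for gid, ann in doc.get("protein_annotations", {}).items()
        },
        decay_params=doc.get("decay_params", {}),
        machinery=doc.get("machinery", {}),
        trna_genes=doc.get("trna_genes", {}),
        synthetase_genes=doc.get("synthetase_genes", {}),
        division_requirements=doc.get("division_requirements", []),
        experimental_essentiality=doc.get("experimental_essentiality", {}),
        amino_acid_alphabet=doc.get("amino_acid_alphabet", "ACDEFGHIKLMNPQRSTVWY"),
        energy=doc.get("energy", {"energy_per_residue": 2, "aminoacylation_atp": 1}),
        organism=doc.get("organism", "unknown"),
    )
    bundle.validate()
    return bundle


def _tuplify(rxn: dict) -> dict:
    rxn = dict(rxn)
    rxn["reactants"] = [tuple(x) for x in rxn.get("reactants", [])]
    rxn["products"] = [tuple(x) for x in rxn.get("products", [])]
    return rxn


def _tuplify_complex(cplx: dict) -> dict:
    cplx = dict(cplx)
    cplx["subunits"] = [tuple(x) for x in cplx.get("subunits", [])]
    return cplx
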