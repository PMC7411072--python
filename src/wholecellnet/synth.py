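"""Synthetic organism knowledge bases with provable gene-essentiality ground truth.

The generator emulates the structure of a minimal-bacterium knowledge
base: a circular random genome with genes tiled into non-overlapping
transcription units, DnaA binding sites (five of them origin-proximal),
a core expression machinery (DnaA, replisome, RNA polymerase, ribosome
with one rRNA, initiation/elongation factors, tRNAs and synthetases for a
reduced amino-acid alphabet, decay machinery, membrane importers), a
payload metabolism (a layered reaction network over imported nutrients),
and the cell-division requirements (FtsZ ring and chromosome-segregation
complexes).

Ground-truth essentiality is *constructed*, not simulated: a gene is
labelled essential exactly when its product lies on a unique biosynthesis
path to something the cell-division reaction requires (the machinery
genes, by design of the templates) or when it is an explicitly planted
essential (its product is the sole subunit of an extra division-required
complex).  Everything else -- payload enzymes, chaperones, transcription
factors, secretion machinery, the amino-acid importer (amino acids are
also recycled by protein decay) and the protease (decay products have
independent suppliers) -- is redundant or dead-ended by construction and
labelled non-essential.  The FtsZ coding sequence is forced to contain
every amino acid of the alphabet so that each tRNA and synthetase is
provably on the division path.

With ``isozyme_pair=True`` the generator adds a maturation cofactor for
FtsZ produced by two redundant reactions with distinct enzymes: each
enzyme gene alone is non-essential, while the pair is essential in
combination -- and, with the amino-acid importer duplicated in that mode,
it is the only such pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import masses, names
from .errors import ConfigError
from .kb import (
    BindingSiteSpec,
    ComplexSpec,
    GeneSpec,
    KBBundle,
    MetaboliteSpec,
    ProteinAnnotation,
    ReactionSpec,
    TUSpec,
)


@dataclass
class SynthConfig:
    n_genes: int = 40
    n_tus: int = 12
    n_binding_sites: int = 8
    n_metabolites: int = 12
    n_metabolic_reactions: int = 16
    genome_length: int = 30000
    fraction_secreted: float = 0.1
    fraction_unknown: float = 0.22
    seed: int = 0
    planted_essentials: Optional[list] = None
    n_planted: int = 2
    n_amino_acids: int = 4
    n_aa_importers: int = 1
    isozyme_pair: bool = False
    ori_site_count: int = 5

    def validate(self) -> None:
        positive = {
            "n_genes": self.n_genes,
            "n_tus": self.n_tus,
            "n_metabolites": self.n_metabolites,
            "n_metabolic_reactions": self.n_metabolic_reactions,
            "genome_length": self.genome_length,
        }
        for key, value in positive.items():
            if value <= 0:
                raise ConfigError(f"infeasible config: {key}={value} must be positive")
        if self.n_binding_sites < 0:
            raise ConfigError("n_binding_sites must be >= 0")
        if not 2 <= self.n_amino_acids <= len(masses.AA_ORDER):
            raise ConfigError(
                f"n_amino_acids={self.n_amino_acids} outside [2, {len(masses.AA_ORDER)}]"
            )
        if self.n_metabolic_reactions < self.n_metabolites:
            raise ConfigError("need at least one reaction per payload metabolite")
        if self.n_aa_importers < 1:
            raise ConfigError("need at least one amino-acid importer")
        base = 16 + self.n_aa_importers + 2 * self.n_amino_acids
        extra = self.n_planted + (2 if self.isozyme_pair else 0) + 1
        if self.n_genes < base + extra:
            raise ConfigError(
                f"infeasible config: n_genes={self.n_genes} below minimum "
                f"{base + extra} for this machinery and payload"
            )
        n_coding = self.n_genes - self.n_amino_acids - 1
        if not 4 <= self.n_tus <= n_coding + 2:
            raise ConfigError(
                f"infeasible config: n_tus={self.n_tus} outside [4, {n_coding + 2}]"
            )
        if not 0 <= self.fraction_secreted <= 1 or not 0 <= self.fraction_unknown <= 1:
            raise ConfigError("fractions must lie in [0, 1]")


#: Machinery roles in roster order; (role, product_type, essential).
#: "Essential" means: removing the gene's product nodes provably disconnects
#: the cell-division reaction under the cascade rules.  Subunit genes of
#: *recycled* machines (ribosome, RNA polymerase, replisome -- all released
#: again by elongation/terminus reactions, and likewise the ribonuclease
#: whose loss is buffered by tRNA recycling) are structurally non-essential:
#: the recycle edge keeps the assembled machine supplied with a producer, so
#: a cascade started at the subunit stops at the lost formation reaction.
_MACHINERY = [
    ("dnaA", "protein", True),
    ("replisome_subunit", "protein", False),
    ("rnap_subunit", "protein", False),
    ("ribosomal_protein_L1", "protein", False),
    ("ribosomal_protein_L2", "protein", False),
    ("if1", "protein", True),
    ("if2", "protein", True),
    ("if3", "protein", True),
    ("elongation_factor", "protein", True),
    ("ftsZ", "protein", True),
    ("segregation", "protein", True),
    ("protease", "protein", False),
    ("ribonuclease", "protein", False),
    ("ntp_importer", "protein", True),
    ("dntp_importer", "protein", True),
]


def generate_synthetic_kb(cfg: SynthConfig) -> KBBundle:
    """Deterministically generate a knowledge base for a given configuration."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    alphabet = masses.AA_ORDER[: cfg.n_amino_acids]

    # -- gene roster (genome order): coding run, tRNA block, rRNA ----------
    roster = [dict(role=r, ptype=t, essential=e) for r, t, e in _MACHINERY]
    for i in range(cfg.n_aa_importers):
        roster.append(dict(role=f"aa_importer_{i + 1}", ptype="protein", essential=False))
    for letter in alphabet:
        roster.append(dict(role=f"synthetase_{letter}", ptype="protein", essential=True))

    n_payload = cfg.n_genes - len(roster) - cfg.n_amino_acids - 1
    payload_roles = _assign_payload_roles(cfg, n_payload)
    for role in payload_roles:
        roster.append(dict(role=role, ptype="protein", essential=role == "planted"))
    for letter in alphabet:
        roster.append(dict(role=f"trna_{letter}", ptype="tRNA", essential=True))
    # the rRNA is a ribosome subunit; ribosome recycling makes it non-essential
    roster.append(dict(role="rrna", ptype="rRNA", essential=False))
    assert len(roster) == cfg.n_genes

    for i, entry in enumerate(roster):
        entry["id"] = f"G{i + 1:03d}"

    if cfg.planted_essentials is not None:
        wanted = set(cfg.planted_essentials)
        actual = {e["id"] for e in roster if e["role"] == "planted"}
        all_ids = {e["id"] for e in roster}
        if not wanted <= all_ids:
            raise ConfigError(f"planted_essentials not among gene ids: {sorted(wanted - all_ids)}")
        if wanted != actual:
            raise ConfigError(
                f"planted_essentials must be the payload slots {sorted(actual)}, "
                f"got {sorted(wanted)}"
            )

    by_role: dict = {}
    for entry in roster:
        by_role.setdefault(entry["role"], []).append(entry["id"])

    def one(role: str) -> str:
        return by_role[role][0]

    # -- genome layout ------------------------------------------------------
    ori_margin = 60 + 40 * cfg.ori_site_count
    genes, tus = _layout_genome(cfg, rng, roster, ori_margin)
    span_end = max(tu.end for tu in tus)
    if span_end + 300 > cfg.genome_length:
        raise ConfigError(
            f"infeasible config: genome_length={cfg.genome_length} too small for "
            f"{cfg.n_genes} genes (need > {span_end + 300})"
        )
    mid = span_end // 2
    ter_position = None
    for tu in sorted(tus, key=lambda t: t.end):
        if tu.end >= mid:
            ter_position = tu.end + 12
            break
    assert ter_position is not None

    seq = "".join(rng.choice(list("ACGT"), size=cfg.genome_length))
    seq = _force_coverage_codons(seq, genes, one("ftsZ"), alphabet)

    binding_sites = _place_binding_sites(cfg, rng, ter_position, ori_margin)

    # -- metabolites and reactions -----------------------------------------
    metabolites, reactions = _metabolism(cfg, rng, alphabet, by_role)

    # -- complexes ----------------------------------------------------------
    complexes = [
        ComplexSpec("REPLISOME", "replisome", [(one("replisome_subunit"), 2)]),
        ComplexSpec("RNA_POLYMERASE", "RNA polymerase holoenzyme", [(one("rnap_subunit"), 2)]),
        ComplexSpec(
            "RIBOSOME_70S",
            "ribosome 70S",
            [
                (one("ribosomal_protein_L1"), 2),
                (one("ribosomal_protein_L2"), 1),
                (one("rrna"), 1),
            ],
        ),
        ComplexSpec("FTSZ_RING", "FtsZ ring", [(one("ftsZ"), 6)]),
        ComplexSpec("SEGREGATION_COMPLEX", "chromosome segregation complex", [(one("segregation"), 2)]),
        ComplexSpec("PROTEASE_COMPLEX", "generic protease", [(one("protease"), 4)]),
        ComplexSpec("RIBONUCLEASE_COMPLEX", "generic ribonuclease", [(one("ribonuclease"), 2)]),
        ComplexSpec("NTP_IMPORTER", "NTP importer", [(one("ntp_importer"), 1)], compartment="m"),
        ComplexSpec("DNTP_IMPORTER", "dNTP importer", [(one("dntp_importer"), 1)], compartment="m"),
    ]
    for i in range(cfg.n_aa_importers):
        gid = one(f"aa_importer_{i + 1}")
        complexes.append(
            ComplexSpec(f"AA_IMPORTER_{i + 1}", f"amino-acid importer {i + 1}", [(gid, 1)], compartment="m")
        )
    division_requirements = ["FTSZ_RING", "SEGREGATION_COMPLEX"]
    for gid in by_role.get("planted", []):
        cid = f"CPLX_ESS_{gid}"
        complexes.append(ComplexSpec(cid, f"division factor of {gid}", [(gid, 2)]))
        division_requirements.append(cid)
    enzyme_refs = []
    for j, gid in enumerate(by_role.get("enzyme", [])):
        if j % 2 == 1:
            cid = f"ENZC_{gid}"
            complexes.append(ComplexSpec(cid, f"enzyme dimer of {gid}", [(gid, 2)]))
            enzyme_refs.append(cid)
        else:
            enzyme_refs.append(gid)
    _assign_enzymes(reactions, enzyme_refs, by_role, cfg)

    # -- annotations ---------------------------------------------------------
    annotations: dict = {}
    for role_key, comp in (
        ("ntp_importer", "m"),
        ("dntp_importer", "m"),
        ("sec_transporter", "m"),
        ("sec_peptidase", "m"),
    ):
        for gid in by_role.get(role_key, []):
            annotations[gid] = ProteinAnnotation(compartment=comp)
    for i in range(cfg.n_aa_importers):
        for gid in by_role.get(f"aa_importer_{i + 1}", []):
            annotations[gid] = ProteinAnnotation(compartment="m")
    for gid in by_role.get("secreted", []):
        annotations[gid] = ProteinAnnotation(
            secreted=True,
            compartment="e",
            transporter=one("sec_transporter"),
            peptidase=one("sec_peptidase"),
        )
    chap = by_role.get("chaperone", [])
    if chap:
        for gid in by_role.get("enzyme", [])[:2]:
            annotations[gid] = ProteinAnnotation(chaperones=[chap[0]])
    unknown = by_role.get("unknown", [])
    for gid, comp in zip(unknown[:2], ("tc", "tm")):
        annotations[gid] = ProteinAnnotation(compartment=comp)
    if cfg.isozyme_pair:
        annotations[one("ftsZ")] = ProteinAnnotation(
            maturation_modifier_metabolites=[names.mol("COFR")]
        )

    # TF requirement on a purely plain-payload TU (never one holding the TF,
    # a planted gene or an isozyme gene, which must stay singleton-clean).
    tf_genes = by_role.get("tf", [])
    if tf_genes:
        plain = {
            gid
            for role in ("enzyme", "unknown", "secreted", "chaperone")
            for gid in by_role.get(role, [])
        }
        for tu in tus:
            if tu.gene_ids and set(tu.gene_ids) <= plain and tf_genes[0] not in tu.gene_ids:
                tu.tf_gene = tf_genes[0]
                break

    # -- residual reactions --------------------------------------------------
    extra = [
        ReactionSpec(
            "RX_DNA_REPAIR_1",
            "ATP-dependent DNA ligation",
            "DNA Repair",
            reactants=[(names.ntp("A"), 1)],
            products=[(names.nmp("A"), 1), (names.PPI, 1)],
            modifiers=[by_role["enzyme"][0]] if by_role.get("enzyme") else [],
        )
    ]
    if by_role.get("secreted"):
        metabolites.append(
            MetaboliteSpec("HOST_RECEPTOR", "host receptor", 500.0, ["e"], ["e"])
        )
        metabolites.append(MetaboliteSpec("ADHESION", "adhesion complex", 500.0, ["e"]))
        extra.append(
            ReactionSpec(
                "RX_HOST_ADHESION",
                "adhesion to host receptor",
                "Host Interaction",
                reactants=[(names.mol("HOST_RECEPTOR", "e"), 1)],
                products=[(names.mol("ADHESION", "e"), 1)],
                modifiers=[by_role["secreted"][0]],
            )
        )

    essentiality = {
        e["id"]: "essential" if e["essential"] else "non-essential" for e in roster
    }

    bundle = KBBundle(
        genome_sequence=seq,
        ori_position=0,
        ter_position=ter_position,
        genes=genes,
        transcription_units=tus,
        binding_sites=binding_sites,
        metabolites=metabolites,
        metabolic_reactions=reactions,
        extra_reactions=extra,
        complexes=complexes,
        protein_annotations=annotations,
        decay_params={"protease": "PROTEASE_COMPLEX", "ribonuclease": "RIBONUCLEASE_COMPLEX"},
        machinery={
            "dnaa_gene": one("dnaA"),
            "replisome": "REPLISOME",
            "rna_polymerase": "RNA_POLYMERASE",
            "ribosome": "RIBOSOME_70S",
            "if1": one("if1"),
            "if2": one("if2"),
            "if3": one("if3"),
            "elongation_factor": one("elongation_factor"),
        },
        trna_genes={letter: one(f"trna_{letter}") for letter in alphabet},
        synthetase_genes={letter: one(f"synthetase_{letter}") for letter in alphabet},
        division_requirements=division_requirements,
        experimental_essentiality=essentiality,
        amino_acid_alphabet=alphabet,
        organism=f"synthetic-minicell-{cfg.seed}",
    )
    bundle.validate()
    return bundle


def planted_essential_genes(bundle: KBBundle) -> list:
    """Gene ids whose products are sole subunits of planted division factors."""
    out = []
    for cid in bundle.division_requirements:
        if cid.startswith("CPLX_ESS_"):
            out.append(cid[len("CPLX_ESS_"):])
    return sorted(out)


# -- helpers -----------------------------------------------------------------


def _assign_payload_roles(cfg: SynthConfig, n_payload: int) -> list:
    roles = ["planted"] * cfg.n_planted
    if cfg.isozyme_pair:
        roles += ["isozyme_a", "isozyme_b"]
    rest = n_payload - len(roles)
    if rest < 1:
        raise ConfigError("infeasible config: no payload slot left for an enzyme")
    secreted_block = cfg.fraction_secreted > 0 and rest >= 6
    roles_tail = ["enzyme"]
    rest -= 1
    if rest >= 1:
        roles_tail.append("tf")
        rest -= 1
    if rest >= 1:
        roles_tail.append("chaperone")
        rest -= 1
    if secreted_block and rest >= 3:
        roles_tail += ["sec_transporter", "sec_peptidase"]
        rest -= 2
        n_secreted = max(1, round(cfg.fraction_secreted * rest))
        n_secreted = min(n_secreted, rest)
        roles_tail += ["secreted"] * n_secreted
        rest -= n_secreted
    n_unknown = min(rest, round(cfg.fraction_unknown * rest))
    roles_tail += ["unknown"] * n_unknown
    rest -= n_unknown
    roles_tail += ["enzyme"] * rest
    return roles + roles_tail


def _layout_genome(cfg: SynthConfig, rng, roster: list, ori_margin: int):
    coding = [e for e in roster if e["ptype"] == "protein"]
    trnas = [e for e in roster if e["ptype"] == "tRNA"]
    rrnas = [e for e in roster if e["ptype"] == "rRNA"]
    n_coding_tus = cfg.n_tus - 2
    base, rem = divmod(len(coding), n_coding_tus)
    blocks, k = [], 0
    for i in range(n_coding_tus):
        size = base + (1 if i < rem else 0)
        blocks.append(coding[k:k + size])
        k += size
    blocks.append(trnas)
    blocks.append(rrnas)

    ftsz_id = next(e["id"] for e in roster if e["role"] == "ftsZ")
    genes, tus = [], []
    p = ori_margin
    for b_idx, block in enumerate(blocks):
        tu_start = p
        strand = "+" if rng.random() < 0.5 else "-"
        if any(e["id"] == ftsz_id for e in block):
            strand = "+"  # keeps the alphabet-coverage codons writable in place
        block_genes = []
        for entry in block:
            if entry["ptype"] == "protein":
                length = int(rng.integers(30, 81)) * 3
            elif entry["ptype"] == "tRNA":
                length = 76
            else:
                length = 120
            block_genes.append(
                GeneSpec(
                    id=entry["id"],
                    name=entry["role"],
                    start=p,
                    end=p + length,
                    strand=strand,
                    product_type=entry["ptype"],
                )
            )
            p += length + int(rng.integers(6, 19))
        tu_end = block_genes[-1].end + 4
        tus.append(
            TUSpec(
                id=f"TU{b_idx + 1:03d}",
                gene_ids=[g.id for g in block_genes],
                start=tu_start,
                end=tu_end,
                strand=strand,
            )
        )
        genes.extend(block_genes)
        p = tu_end + int(rng.integers(25, 61))
    return genes, tus


def _force_coverage_codons(seq: str, genes: list, ftsz_id: str, alphabet: str) -> str:
    """Rewrite the start of the FtsZ coding sequence so every amino acid of
    the alphabet appears at least once in its protein (plus-strand gene)."""
    bases = "ACGT"
    gene = next(g for g in genes if g.id == ftsz_id)
    codons = []
    for i in range(len(alphabet)):
        codons.append(bases[i // 16] + bases[(i // 4) % 4] + bases[i % 4])
    patch = "".join(codons)
    return seq[: gene.start] + patch + seq[gene.start + len(patch):]


def _place_binding_sites(cfg: SynthConfig, rng, ter_position: int, ori_margin: int) -> list:
    sites = []
    for i in range(cfg.ori_site_count):
        sites.append(BindingSiteSpec(f"DNAA_BOX_ORI_{i + 1}", 30 + 40 * i, 8, "DnaA"))
    margin = 150
    length = cfg.genome_length
    occupied = [(s.position, s.end) for s in sites]
    placed = 0
    attempts = 0
    while placed < cfg.n_binding_sites and attempts < 5000:
        attempts += 1
        pos = int(rng.integers(ori_margin + margin, length - 10))
        if abs(pos - ter_position) < margin or pos + 8 > length:
            continue
        if any(a - 10 < pos < b + 10 for a, b in occupied):
            continue
        occupied.append((pos, pos + 8))
        placed += 1
        sites.append(BindingSiteSpec(f"DNAA_BOX_{placed}", pos, 8, "DnaA"))
    return sites


def _metabolism(cfg: SynthConfig, rng, alphabet: str, by_role: dict):
    metabolites = [
        MetaboliteSpec(f"AA_{x}", f"amino acid {x}", masses.AA_MASS[x], ["c", "e"], ["e"])
        for x in alphabet
    ]
    for base in "ACGU":
        metabolites.append(
            MetaboliteSpec(f"{base}TP", f"{base}TP", masses.NTP_MASS[base], ["c", "e"], ["e"])
        )
        metabolites.append(MetaboliteSpec(f"{base}MP", f"{base}MP", masses.NMP_MASS[base], ["c"]))
    for base in "ACGT":
        metabolites.append(
            MetaboliteSpec(f"d{base}TP", f"d{base}TP", masses.DNTP_MASS[base], ["c", "e"], ["e"])
        )
    metabolites += [
        MetaboliteSpec("GDP", "GDP", masses.GDP, ["c"]),
        MetaboliteSpec("PI", "phosphate", masses.PI, ["c"]),
        MetaboliteSpec("PPI", "pyrophosphate", masses.PPI, ["c"]),
        MetaboliteSpec("WATER", "water", masses.WATER, ["c", "e"], ["e"]),
    ]
    n_nutrients = max(1, cfg.n_metabolites // 4)
    for i in range(n_nutrients):
        mass = round(float(rng.uniform(100, 300)), 2)
        metabolites.append(
            MetaboliteSpec(f"NUT_{i + 1}", f"nutrient {i + 1}", mass, ["c", "e"], ["e"])
        )

    reactions = []
    aa_importers = [f"AA_IMPORTER_{i + 1}" for i in range(cfg.n_aa_importers)]

    def uptake(met_id, importer, tag):
        reactions.append(
            ReactionSpec(
                f"RX_TRANSPORT_{tag}",
                f"uptake of {met_id}",
                "Transmembrane Transport",
                reactants=[(names.mol(met_id, "e"), 1)],
                products=[(names.mol(met_id, "c"), 1)],
                modifiers=[importer],
            )
        )

    for j, x in enumerate(alphabet):
        for imp in aa_importers:  # duplicated importers give redundant supply
            uptake(f"AA_{x}", imp, f"AA_{x}_{imp[-1]}")
    uptake("WATER", aa_importers[0], "WATER")
    for i in range(n_nutrients):
        uptake(f"NUT_{i + 1}", aa_importers[i % len(aa_importers)], f"NUT_{i + 1}")
    for base in "ACGU":
        uptake(f"{base}TP", "NTP_IMPORTER", f"{base}TP")
    for base in "ACGT":
        uptake(f"d{base}TP", "DNTP_IMPORTER", f"d{base}TP")

    # layered payload metabolism: each product's mass is the weighted sum of
    # its reactants, so every reaction is exactly balanced
    mass_of = {m.id: m.mass for m in metabolites}
    pool = [f"AA_{x}" for x in alphabet] + [f"NUT_{i + 1}" for i in range(n_nutrients)]
    payload_specs = []
    for i in range(cfg.n_metabolites):
        k = int(rng.integers(1, 3))
        picks = list(rng.choice(len(pool), size=min(k, len(pool)), replace=False))
        reactants = []
        total = 0.0
        for idx in picks:
            w = int(rng.integers(1, 3))
            reactants.append((names.mol(pool[idx], "c"), w))
            total += w * mass_of[pool[idx]]
        pid = f"M_{i + 1:03d}"
        mass_of[pid] = round(total, 6)
        metabolites.append(MetaboliteSpec(pid, f"payload metabolite {i + 1}", mass_of[pid], ["c"]))
        spec = ReactionSpec(
            f"RX_METAB_{i + 1:03d}",
            f"synthesis of {pid}",
            "Metabolism",
            reactants=reactants,
            products=[(names.mol(pid, "c"), 1)],
            modifiers=[],
        )
        reactions.append(spec)
        payload_specs.append(spec)
        pool.append(pid)
    for k in range(cfg.n_metabolic_reactions - cfg.n_metabolites):
        src = payload_specs[int(rng.integers(len(payload_specs)))]
        reactions.append(
            ReactionSpec(
                f"RX_METAB_ISO_{k + 1:03d}",
                f"isozyme route for {src.products[0][0]}",
                "Metabolism",
                reactants=list(src.reactants),
                products=list(src.products),
                modifiers=[],
            )
        )
    if cfg.isozyme_pair:
        x = alphabet[0]
        metabolites.append(
            MetaboliteSpec("COFR", "division cofactor", masses.AA_MASS[x], ["c"])
        )
        for tag, role in (("A", "isozyme_a"), ("B", "isozyme_b")):
            reactions.append(
                ReactionSpec(
                    f"RX_METAB_COFR_{tag}",
                    f"cofactor synthesis (isozyme {tag})",
                    "Metabolism",
                    reactants=[(names.mol(f"AA_{x}", "c"), 1)],
                    products=[(names.mol("COFR", "c"), 1)],
                    modifiers=[by_role[role][0]],
                )
            )
    return metabolites, reactions


def _assign_enzymes(reactions: list, enzyme_refs: list, by_role: dict, cfg: SynthConfig) -> None:
    """Give every payload Metabolism reaction at least one enzyme (round robin)."""
    if not enzyme_refs:
        raise ConfigError("no payload enzymes available for metabolic reactions")
    j = 0
    for rxn in reactions:
        if rxn.process == "Metabolism" and not rxn.modifiers:
            rxn.modifiers = [enzyme_refs[j % len(enzyme_refs)]]
            j += 1
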