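"""Process templates: stoichiometries, structure, idempotence, conservation."""

from collections import Counter
from dataclasses import replace

import pytest

from wholecellnet import CellNetwork, TemplateConfig
from wholecellnet.assembly import apply_instance
from wholecellnet.chromosome import partition_chromosome, region_nt_counts, terminus_region_index
from wholecellnet.errors import TemplateError
from wholecellnet.kb import ComplexSpec
from wholecellnet import names, templates


def residue_counts(kb, gene):
    """Independent residue tally straight from the coding sequence."""
    seq = kb.gene_sequence(gene)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    n = len(kb.amino_acid_alphabet)
    counts = Counter()
    for i in range(0, len(seq) - len(seq) % 3, 3):
        c = seq[i:i + 3]
        counts[kb.amino_acid_alphabet[(16 * idx[c[0]] + 4 * idx[c[1]] + idx[c[2]]) % n]] += 1
    return counts


def step_by_suffix(inst, suffix):
    hits = [s for s in inst.steps if s.reaction.id.endswith(suffix)]
    assert len(hits) == 1, f"{suffix}: {[s.reaction.id for s in inst.steps]}"
    return hits[0]


@pytest.fixture(scope="module")
def regions(small_kb):
    return partition_chromosome(small_kb)


class TestTranslation:
    def test_trna_weights_match_sequence(self, small_kb):
        gene = next(g for g in small_kb.genes if g.name == "ftsZ")
        inst = templates.instantiate_translation(small_kb, gene)
        elong = step_by_suffix(inst, "_ELONG")
        expected = residue_counts(small_kb, gene)
        charged = {
            mid: w for mid, w in elong.reactants
            if mid.endswith("_RNA_AMINOACYLATED[c]")
        }
        for letter, count in expected.items():
            cid = names.charged_trna(small_kb.trna_genes[letter])
            assert charged[cid] == count
        # uncharged tRNAs come back out with identical weights
        uncharged = {mid: w for mid, w in elong.products if mid.endswith("_RNA[c]")}
        for letter, count in expected.items():
            assert uncharged[names.gene_rna(small_kb.trna_genes[letter])] == count
        # energy: GTP weight equals energy_per_residue * length
        gtp = dict(elong.reactants)[names.ntp("G")]
        assert gtp == TemplateConfig().energy_per_residue * sum(expected.values())

    def test_plain_protein_has_bare_maturation(self, small_kb):
        plain = next(
            g.id
            for g in small_kb.genes
            if g.product_type == "protein"
            and g.id not in small_kb.protein_annotations
            and g.name in ("unknown", "enzyme")
        )
        inst = templates.instantiate_translation(small_kb, small_kb.gene_by_id[plain])
        mat = step_by_suffix(inst, f"PROTEIN_MATURATION_{plain}")
        assert mat.modifiers == []
        assert not any("SIGNAL_PEPTIDE" in m for m, _ in mat.products)

    def test_secreted_protein_maturation(self, small_kb):
        secreted = next(
            gid for gid, ann in small_kb.protein_annotations.items() if ann.secreted
        )
        inst = templates.instantiate_translation(small_kb, small_kb.gene_by_id[secreted])
        mat = step_by_suffix(inst, f"PROTEIN_MATURATION_{secreted}")
        products = dict(mat.products)
        assert names.signal_peptide(secreted) in products
        ann = small_kb.protein_annotations[secreted]
        assert names.monomer(ann.transporter, "m") in mat.modifiers
        assert names.monomer(ann.peptidase, "m") in mat.modifiers
        # secreted functional monomer ends up extracellular
        assert names.monomer(secreted, "e") in products

    def test_chaperone_modifier_when_annotated(self, small_kb):
        chaperoned = next(
            gid for gid, ann in small_kb.protein_annotations.items() if ann.chaperones
        )
        inst = templates.instantiate_translation(small_kb, small_kb.gene_by_id[chaperoned])
        mat = step_by_suffix(inst, f"PROTEIN_MATURATION_{chaperoned}")
        chap = small_kb.protein_annotations[chaperoned].chaperones[0]
        assert names.monomer(chap) in mat.modifiers

    def test_mrna_is_formation_modifier(self, small_kb):
        gene = next(g for g in small_kb.genes if g.product_type == "protein")
        inst = templates.instantiate_translation(small_kb, gene)
        form = step_by_suffix(inst, "_FORM")
        tu = small_kb.tu_of_gene(gene.id)
        assert names.tu_rna(tu.id) in form.modifiers
        assert names.tu_rna(tu.id) not in [m for m, _ in form.reactants]


class TestAminoacylation:
    def test_charged_and_uncharged_distinct(self, small_kb):
        letter = small_kb.amino_acid_alphabet[0]
        inst = templates.instantiate_aminoacylation(small_kb, small_kb.trna_genes[letter])
        step = inst.steps[0]
        reactant_ids = {m for m, _ in step.reactants}
        product_ids = {m for m, _ in step.products}
        gene = small_kb.trna_genes[letter]
        assert names.gene_rna(gene) in reactant_ids
        assert names.charged_trna(gene) in product_ids
        assert names.gene_rna(gene) != names.charged_trna(gene)
        assert names.monomer(small_kb.synthetase_genes[letter]) in step.modifiers

    def test_missing_synthetase_errors(self, small_kb):
        crippled = replace(small_kb, synthetase_genes={})
        letter = small_kb.amino_acid_alphabet[0]
        with pytest.raises(TemplateError, match="synthetase"):
            templates.instantiate_aminoacylation(crippled, small_kb.trna_genes[letter])


class TestComplexation:
    def test_ribosome_stoichiometry(self, small_kb):
        inst = templates.instantiate_complexation(small_kb, "RIBOSOME_70S")
        weights = sorted(w for _, w in inst.steps[0].reactants)
        assert weights == [1, 1, 2]
        assert dict(inst.steps[0].products) == {names.mol("RIBOSOME_70S"): 1}

    def test_homodimer_single_reactant_weight_two(self, small_kb):
        inst = templates.instantiate_complexation(small_kb, "REPLISOME")
        assert len(inst.steps[0].reactants) == 1
        assert inst.steps[0].reactants[0][1] == 2

    def test_nested_complex_uses_complex_node(self, small_kb):
        ftsz = next(g.id for g in small_kb.genes if g.name == "ftsZ")
        nested = replace(
            small_kb,
            complexes=small_kb.complexes
            + [ComplexSpec("NEST", "nested machine", [("RIBOSOME_70S", 1), (ftsz, 2)])],
        )
        inst = templates.instantiate_complexation(nested, "NEST")
        assert (names.mol("RIBOSOME_70S"), 1) in inst.steps[0].reactants

    def test_zero_subunits_rejected(self, small_kb):
        bad = replace(
            small_kb, complexes=small_kb.complexes + [ComplexSpec("EMPTY", "none", [])]
        )
        with pytest.raises(TemplateError, match="zero subunits"):
            templates.instantiate_complexation(bad, "EMPTY")


class TestReplication:
    def test_chain_lengths_cover_all_regions(self, small_kb, regions):
        inst = templates.instantiate_replication(small_kb, regions)
        ter = terminus_region_index(regions, small_kb)
        cw = [s for s in inst.steps if "_ELONG_CW_" in s.reaction.id]
        ccw = [s for s in inst.steps if "_ELONG_CCW_" in s.reaction.id]
        assert len(cw) == ter
        assert len(ccw) == len(regions) - ter
        assert len(cw) + len(ccw) == len(regions)

    def test_current_region_product_weight_two(self, small_kb, regions):
        inst = templates.instantiate_replication(small_kb, regions)
        for step in inst.steps:
            if "_ELONG_" not in step.reaction.id:
                continue
            idx = int(step.reaction.id.rsplit("_", 1)[1])
            assert dict(step.products)[names.region(idx)] == 2

    def test_dntp_weights_equal_both_strand_counts(self, small_kb, regions):
        inst = templates.instantiate_replication(small_kb, regions)
        step = next(s for s in inst.steps if s.reaction.id.endswith("_ELONG_CW_0"))
        counts = region_nt_counts(regions[0], small_kb.genome_sequence, both_strands=True)
        got = {m: w for m, w in step.reactants if m.startswith("d")}
        assert got == {names.dntp(b): c for b, c in counts.items() if c}

    def test_too_few_ori_sites_errors(self, small_kb, regions):
        cfg = TemplateConfig(ori_proximal_site_count=99)
        with pytest.raises(TemplateError, match="99"):
            templates.instantiate_replication(small_kb, regions, cfg)

    def test_terminus_releases_replisomes_and_duplicated_chromosome(self, small_kb, regions):
        inst = templates.instantiate_replication(small_kb, regions)
        release = step_by_suffix(inst, "TERMINUS_RELEASE")
        products = dict(release.products)
        assert products[names.mol("REPLISOME")] == 2
        assert products[names.DUPLICATED_CHROMOSOME] == 1


class TestTranscription:
    def test_elongation_per_spanned_region(self, small_kb, regions):
        for tu in small_kb.transcription_units:
            inst = templates.instantiate_transcription(small_kb, tu, regions)
            elongs = [s for s in inst.steps if "_ELONG_" in s.reaction.id]
            from wholecellnet.chromosome import regions_overlapping

            span = regions_overlapping(regions, tu.start, tu.end, small_kb)
            assert len(elongs) == len(span) >= 1

    def test_minus_strand_walks_backwards(self, small_kb, regions):
        from wholecellnet.chromosome import regions_overlapping

        multi = None
        for tu in small_kb.transcription_units:
            span = regions_overlapping(regions, tu.start, tu.end, small_kb)
            if tu.strand == "-" and len(span) >= 2:
                multi = (tu, span)
                break
        if multi is None:
            pytest.skip("no multi-region minus-strand TU in this bundle")
        tu, span = multi
        inst = templates.instantiate_transcription(small_kb, tu, regions)
        order = [
            int(s.reaction.id.rsplit("_", 1)[1])
            for s in inst.steps
            if "_ELONG_" in s.reaction.id
        ]
        assert order == sorted(order, reverse=True)

    def test_polycistronic_trna_cleavage(self, small_kb, regions):
        trna_tu = small_kb.tu_of_gene(next(iter(small_kb.trna_genes.values())))
        inst = templates.instantiate_transcription(small_kb, trna_tu, regions)
        cleave = step_by_suffix(inst, "_CLEAVAGE")
        precursor_products = [m for m, _ in cleave.products if "_RNA_PRECURSOR" in m]
        assert len(precursor_products) == len(trna_tu.gene_ids)
        maturations = [s for s in inst.steps if "_MATURATION" in s.reaction.id]
        assert len(maturations) == len(trna_tu.gene_ids)

    def test_mrna_tu_one_rna_node_no_cleavage(self, small_kb, regions):
        mrna_tu = next(
            tu
            for tu in small_kb.transcription_units
            if len(tu.gene_ids) >= 2
            and all(small_kb.gene_by_id[g].product_type == "protein" for g in tu.gene_ids)
        )
        inst = templates.instantiate_transcription(small_kb, mrna_tu, regions)
        assert not any("_CLEAVAGE" in s.reaction.id for s in inst.steps)
        release = step_by_suffix(inst, "_RELEASE")
        rna_products = [m for m, _ in release.products if m == names.tu_rna(mrna_tu.id)]
        assert len(rna_products) == 1

    def test_regions_consumed_and_reproduced_net_zero(self, small_kb, regions):
        tu = small_kb.transcription_units[0]
        inst = templates.instantiate_transcription(small_kb, tu, regions)
        consumed = Counter()
        produced = Counter()
        for step in inst.steps:
            for m, w in step.reactants:
                if m.startswith("CHR_REGION_") and "__" not in m:
                    consumed[m] += w
            for m, w in step.products:
                if m.startswith("CHR_REGION_") and "__" not in m:
                    produced[m] += w
        assert consumed == produced


class TestDecay:
    def test_rna_decay_counts(self, small_kb, small_net):
        trna_gene = next(iter(small_kb.trna_genes.values()))
        mol = small_net.molecules[names.gene_rna(trna_gene)]
        inst = templates.instantiate_decay(small_kb, mol)
        step = inst.steps[0]
        gene = small_kb.gene_by_id[trna_gene]
        transcript = small_kb.transcript_sequence(gene.start, gene.end, gene.strand)
        expected = Counter(transcript)
        got = {m: w for m, w in step.products}
        for base, count in expected.items():
            assert got[names.nmp(base)] == count

    def test_protein_decay_conserves_monomers(self, small_kb, small_net):
        gene = next(g for g in small_kb.genes if g.name == "ftsZ")
        mol = small_net.molecules[names.monomer(gene.id)]
        inst = templates.instantiate_decay(small_kb, mol)
        step = inst.steps[0]
        expected = residue_counts(small_kb, gene)
        got = {m: w for m, w in step.products}
        assert sum(got.values()) == sum(expected.values())
        for letter, count in expected.items():
            assert got[names.aa(letter)] == count

    def test_metabolite_not_degradable(self, small_kb, small_net):
        atp = small_net.molecules[names.ntp("A")]
        with pytest.raises(TemplateError, match="not degradable"):
            templates.instantiate_decay(small_kb, atp)


class TestDivision:
    def test_exactly_one_division_reaction(self, small_net):
        division = [
            r for r in small_net.reactions.values() if r.process == "Cellular Division"
        ]
        assert len(division) == 1
        assert small_net.critical_reaction_id == division[0].id

    def test_modifier_count_matches_requirements(self, small_kb, small_net):
        mods = small_net.modifiers_of(small_net.critical_reaction_id)
        assert len(mods) == len(small_kb.division_requirements) + 1  # + duplicated chromosome
        assert names.DUPLICATED_CHROMOSOME in mods

    def test_missing_requirement_named(self, small_kb):
        empty = CellNetwork()
        with pytest.raises(TemplateError, match="FTSZ_RING"):
            templates.instantiate_cell_division(small_kb, empty)


class TestInstanceContracts:
    def test_instances_valid_in_isolation_and_idempotent(self, small_kb, regions):
        gene = next(g for g in small_kb.genes if g.product_type == "protein")
        instances = [
            templates.instantiate_translation(small_kb, gene),
            templates.instantiate_transcription(
                small_kb, small_kb.transcription_units[0], regions
            ),
            templates.instantiate_replication(small_kb, regions),
            templates.instantiate_complexation(small_kb, "RIBOSOME_70S"),
            templates.instantiate_aminoacylation(
                small_kb, next(iter(small_kb.trna_genes.values()))
            ),
        ]
        for inst in instances:
            net = CellNetwork()
            apply_instance(net, inst)
            assert net.validate().ok, inst.process
            before = (net.n_nodes, net.n_edges)
            added = apply_instance(net, inst)
            assert added == (0, 0)
            assert (net.n_nodes, net.n_edges) == before

    def test_stall_templates_attach_when_enabled(self, small_kb, regions):
        cfg = TemplateConfig(stall_templates=True)
        tu = small_kb.transcription_units[0]
        inst = templates.instantiate_transcription(small_kb, tu, regions, cfg)
        assert any("_STALL" in s.reaction.id for s in inst.steps)
        gene = next(g for g in small_kb.genes if g.product_type == "protein")
        inst2 = templates.instantiate_translation(small_kb, gene, cfg)
        assert any("_STALL" in s.reaction.id for s in inst2.steps)
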