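# Methods

## The network model

A whole-cell biochemical network is a bipartite, directed, weighted
multigraph. Molecule nodes represent physical entities — metabolites,
protein monomers and complexes, RNAs, chromosome regions, and "other"
intermediates such as machinery-bound states. One node per chemical
state and per compartment: inhibited vs. active protein, charged vs.
uncharged tRNA, and cytosolic vs. extracellular glucose are all distinct
nodes. Reaction nodes carry a cellular-process label drawn from a fixed
vocabulary of fifteen processes (Metabolism, Transmembrane Transport,
Replication, Transcription, RNA Processing, tRNA Aminoacylation,
Translation, Protein Maturation, Macromolecular Complexation,
Protein-DNA Interaction, Protein Decay, RNA Decay, Cellular Division,
Host Interaction, DNA Repair).

Edges are role-typed. Reactant edges run molecule→reaction and product
edges reaction→molecule, both weighted by stoichiometry. Modifier edges
(molecule→reaction, weight 1) attach catalysts, templates and
regulators that are neither consumed nor produced — enzymes, the mRNA in
translation, transcription-factor-bound chromosome regions. Reactions
are encoded irreversibly; a reversible knowledge-base reaction becomes
two reaction nodes (`_fwd`/`_rev`), which keeps the cascade semantics
unambiguous. Molecules and reactions share one id namespace; molecule
ids are `NAME[compartment]`, generated reaction ids are
`RX_<PROCESS>_<substrate>_<step>` so that rebuilding a template for the
same substrate always reproduces the same ids (idempotence).

## Knowledge-base schema

The input is a single JSON document (`schema_version: "1.0"`): circular
genome (inline or as a referenced FASTA), origin and terminus positions,
genes grouped into non-overlapping transcription units (TUs), DnaA
binding sites, metabolites with masses and compartments (extracellular
nutrients flagged as boundary species), metabolic/transport reactions
with enzyme references, complexes with subunit stoichiometry, per-gene
protein annotations (chaperones, secretion with transporter/peptidase,
maturation cofactors), decay machinery, core expression machinery roles,
tRNA/synthetase maps per amino-acid letter, the complexes required by
cell division, and optional experimental essentiality labels. The
amino-acid alphabet is a KB field (default the 20 standard residues), so
reduced-alphabet toy organisms are representable without special cases.
Protein sequences may be given explicitly; otherwise they are derived by
a deterministic reduced genetic code (codon ordinal modulo alphabet
size — no stop codons, so random genes always translate).

## Chromosome representation

The circular chromosome is partitioned into regions with cut points at
every DnaA binding-site boundary plus the replication origin and
terminus; each binding site is its own region and each maximal gap
between cut points is a region. Coordinates are 0-based and half-open;
indices run clockwise from 0 at the origin. Regions tile the circle
exactly, the partition is invariant (up to relabeling) under rotating
all coordinates, and per-region nucleotide counts (optionally including
the complement strand) supply polymerisation stoichiometry.

## Process templates

Templates are reaction sets replicated per substrate.

**Replication.** DnaA monomers bind the five origin-proximal
binding-site regions (`ori_proximal_site_count`, default 5). The
replication-complex formation consumes these DnaA-bound regions, two
replisomes, and the first region on each side of the origin, producing
two replisome-bound states. Each arm advances one region per reaction:
an elongation duplicates its region (product weight 2), consumes the
next region of the arm and dNTPs weighted by the both-strand nucleotide
counts of the duplicated region — summed over the template, dNTP demand
equals the both-strand composition of the whole genome exactly once.
The terminus reaction joins both arms, releases the replisomes and
produces the duplicated-chromosome node that cell division requires.

**Transcription.** Polymerase binds the TU's first region (consuming
it); when a transcription factor is annotated, the TF-bound region —
produced by an explicit Protein-DNA Interaction reaction — is a
formation modifier. One elongation per spanned region consumes NTPs for
the transcript portion overlapping that region (releasing PPi) and
walks to index i+1 or i−1 according to strand; each elongation
reproduces the region it transcribed, so region copy numbers are net
unchanged. Release returns the polymerase and emits one RNA node per TU
(polycistronic mRNAs stay one node). TUs composed of ≥2 tRNA/rRNA genes
are cleaved (ribonuclease as modifier) into per-gene precursors plus a
mass-closing fragment, followed by per-gene maturation. Minimal
stall-and-release reaction pairs can be attached per chain
(`stall_templates`, default off).

**Aminoacylation.** tRNA + amino acid + ATP → charged tRNA + AMP + PPi,
with the synthetase as modifier (`aminoacylation_atp`, default 1).

**Translation.** Formation consumes the 70S ribosome and IF-3, with
IF-1, IF-2 and the mRNA as modifiers (mRNA copy number is unchanged by
translation, hence modifier). Elongation consumes charged tRNAs with
weights equal to the protein's per-residue counts and GTP with weight
`energy_per_residue × length` (default 2 per residue, reflecting
EF-Tu + EF-G hydrolysis), with the elongation factor as modifier; it
releases the immature protein, uncharged tRNAs, IF-3, the ribosome,
GDP, Pi and one water per peptide bond. Maturation converts immature to
functional monomer; chaperones are modifiers when annotated; secreted
proteins additionally take the membrane transporter and signal
peptidase as modifiers, consume one water and produce the cleaved
signal peptide, with the functional monomer placed in its annotated
compartment.

**Complexation** is a single formation reaction with subunit
stoichiometry (nested complexes are reactant complex nodes).
**Decay** degrades an RNA to nucleoside monophosphates (ribonuclease as
modifier) and a protein or complex to free amino acids (protease as
modifier), consuming one water per peptide bond — exactly the monomer
pool its synthesis consumed. **Cell division** is a single reaction
whose modifiers are every division-required complex plus the duplicated
chromosome; its id becomes the network's critical reaction.

## Assembly

Seeding takes every KB metabolic/transport reaction with its molecules
and enzymes, the functional product node of every gene (so
unknown-function genes appear with just their synthesis and decay
chains), the division-required complexes, and the replication template
(the chromosome is always present; the consume-and-reproduce convention
for regions would otherwise mask its absence from the producer check).
The closure then repeatedly finds molecules without a producing
reaction (boundary nutrients exempt) and instantiates their biosynthesis
template — complexation for complexes, translation for monomers,
transcription for RNAs, aminoacylation for charged tRNAs — plus decay
for every functional RNA, monomer and complex, until a pass adds
nothing. Termination is guaranteed: the universe of instantiable
templates is finite and application is idempotent. Residual KB
reactions (e.g. Host Interaction, DNA Repair) are appended afterwards
and closed over again; finally the division reaction is attached. A
trace records per-pass additions and any molecule for which no
biosynthesis route exists.

**Mass balance.** For every reaction,
|Σ w·m(reactants) − Σ w·m(products)| must vanish; modifiers are
excluded. The default tolerance is 1e-6 relative to the heavier side.
Molecules of unknown mass (chromosome regions, machinery-bound states)
cause their reactions to be skipped and reported separately — never
treated as zero mass. Violations are reported, not repaired. The
package's polymer conventions make balance exact where masses are
known: condensation water is explicit (weight L−1 on translation, the
same weight as a decay reactant), NTP = NMP + PPi, ATP = AMP + PPi,
GTP = GDP + Pi, charged tRNA = tRNA + amino acid, complexes are subunit
sums, and secreted-protein cleavage adds one hydrolysis water.

## Cascading-failure essentiality

Deleting a gene removes its functional-product molecule nodes: all
monomer-state nodes (immature and functional) for coding genes, the
mature RNA node for tRNA/rRNA genes. Complexes containing the product
are not seeded; the cascade removes them via their formation reactions
when appropriate. Propagation rules, iterated to a fixpoint:

* R1 — a reaction is removed when any of its reactant **or modifier**
  molecules is removed;
* R2 — a non-boundary molecule is removed when **all** reactions
  producing it are removed, provided it had at least one producer in
  the intact network.

Both rules are monotone, so the result is order-independent; the
worklist implementation is tested for exact agreement with a naive
repeat-until-stable rescan oracle. An alternative molecule rule
(death on isolation, i.e. loss of consumers too) was considered and
rejected: consumer loss does not deprive a molecule of supply.
A gene (or pair) is essential iff the critical division reaction is
removed. The double scan enumerates unordered pairs, by default only
among genes that are singly non-essential — monotonicity guarantees no
combination-essential pair is missed — and excludes self-pairs.
Confusion rates against experimental labels: match, false positive
(predicted essential, experimentally not) and false negative sum to 1;
genes with unknown labels count as non-essential; a restricted variant
conditions on predicted-essential genes only.

**A structural consequence worth knowing.** Machines that the templates
*recycle* — the ribosome, polymerase and replisome are released again
by elongation/terminus reactions — retain a producer when their
formation reaction is lost, so deleting one of their subunit genes does
not cascade past the formation step. Under these rules such genes are
structurally non-essential even though they are biologically
indispensable; this is a genuine limitation of static producer-loss
cascades (a dynamical model would starve the cycle) and a major source
of false negatives against real knockout data.

## Rewiring null model

Each edge is selected independently with probability p (u ≤ p for
u ~ U(0,1)); a selected edge has **both** endpoints redrawn uniformly
among nodes of the same kind, preserving the node set, bipartiteness,
role directions and the (role, weight) edge multiset. Collisions are
kept as parallel edges so the edge count is exactly preserved. Defaults
for the essentiality-vs-rewiring scan: p from 0 to 1 in steps of 0.02,
50 replicates per p, per-cell seeds spawned deterministically from one
master seed. The desk-scale tests and the acceptance script use a
two-point grid (0 and 0.5) with 20 replicates, which suffices for the
monotone false-positive trend.

## Topology

Degree is the unweighted count of incident edges, any role and either
direction (modifier edges count; reaction degree is likewise a plain
connection count). A molecule's process count is the number of distinct
process labels over its incident reactions; the multi-process fraction
is the share of molecules with ≥2. Spearman rank correlation between
degree and process count is computed for all molecules and restricted
to proteins and metabolites; degenerate inputs (constant ranks, fewer
than two points) report the correlation as undefined (`None`), never 0.
Degree histograms are exported for external plotting; no power-law fit
is performed.

## The synthetic organism generator

`generate_synthetic_kb` builds organisms whose essentiality ground
truth is **provable from construction**, not assumed or simulated. The
default conditions (one organism per seed, byte-identical for a fixed
seed): 40 genes on a 30 kb circular genome in 12 TUs; a 4-letter
amino-acid alphabet (keeping tRNA/synthetase pairs affordable at this
gene count); 5 origin-proximal DnaA boxes plus 8 random ones; 12
payload metabolites made by 16 Metabolism reactions layered over
imported nutrients (product mass = weighted reactant sum, so every
reaction balances exactly); 22% unknown-function genes and 10% secreted
proteins among the payload, echoing minimal-bacterium annotation
levels. Fixed machinery: DnaA, one replisome and one polymerase subunit
gene, two ribosomal proteins plus one rRNA, IF-1/2/3, an elongation
factor, FtsZ and a segregation gene (their complexes are the division
requirements), protease and ribonuclease, and membrane importers for
NTPs, dNTPs and amino acids. The FtsZ coding sequence is forced to
contain every alphabet letter, which puts every tRNA and synthetase on
the unique path to division.

Essential by construction: the planted genes (sole subunits of extra
division-required complexes), DnaA, the initiation/elongation factors,
FtsZ, segregation, tRNAs, synthetases, and the NTP/dNTP importers (sole
supply of polymerisation substrates). Non-essential by construction:
payload enzymes (their metabolism dead-ends), chaperones and
transcription factors (annotated only on payload), secretion machinery,
the amino-acid importer (decay reactions also regenerate amino acids),
the protease (its products have independent suppliers), and — per the
recycling consequence above — subunits of the ribosome, polymerase and
replisome and the ribonuclease (buffered by tRNA recycling). With
`isozyme_pair=True` (and the amino-acid importer duplicated so no other
buffered pair exists), an FtsZ maturation cofactor is produced by two
reactions with distinct enzymes: each enzyme is singly non-essential
and exactly that pair is combination-essential.

What the generator does **not** emulate: realistic sequence composition
or codon usage, operon structure beyond contiguous blocks, kinetic or
expression-level variation, condition-dependent essentiality, and the
scale of a real organism (hundreds of genes rather than hundreds of
thousands of nodes — though 1000-gene organisms build in seconds and
are used for the 10⁴-node serialization tests). Passing tests therefore
demonstrate correctness of the construction, cascade and analysis
machinery on networks with the right *shape*, not predictive accuracy
on real knockout data.

## Numerical and design choices

* Masses: average masses for amino acids and water; energy-carrier
  masses chosen to satisfy the hydrolysis identities exactly (see
  `masses.py`). Unknown masses are permitted and excluded from balance
  checking.
* Problem sizes in the test suite: 20 organisms of 24–100 genes for
  essentiality recovery (24 is the machinery floor: 17 fixed roles plus
  tRNA/synthetase pairs at a 2-letter alphabet plus one enzyme); 500
  random ≤30-node networks for the cascade oracle; a 10⁴-edge network
  for the binomial rewiring check; a 10⁴-node organism for round-trips.
* SBML Level 3 Version 2 core; molecule category/state/genes/mass and
  reaction process are carried in a package annotation namespace, and
  non-SId characters are sanitised deterministically with the original
  id preserved, so round-trips are lossless. GML uses the networkx
  dialect with the same attributes.
* Determinism everywhere: one `numpy` Generator per entry point, seeds
  below 2³¹, sorted iteration orders in the builder and scans.

## Known limitations

Static structure only — no fluxes, kinetics or simulation; the cascade
cannot see flux bottlenecks or dosage effects. Recycled-machine
subunits are systematically called non-essential (above). Reversibility
is an encoding convention, not curated thermodynamics. The SBML
validator checks structure and the declared level/version, not the full
specification. Mass-balance failures are reported, not repaired.
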