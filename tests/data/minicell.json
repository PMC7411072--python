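{
 "amino_acid_alphabet": "AC",
 "binding_sites": [
  {
   "id": "box1",
   "length": 8,
   "position": 100,
   "protein": "DnaA"
  }
 ],
 "complexes": [
  {
   "compartment": "c",
   "id": "CPX1",
   "name": "alpha homodimer",
   "subunits": [
    [
     "g1",
     2
    ]
   ]
  }
 ],
 "decay_params": {
  "protease": "CPX1",
  "ribonuclease": "CPX1"
 },
 "division_requirements": [
  "CPX1"
 ],
 "energy": {
  "aminoacylation_atp": 1,
  "energy_per_residue": 2
 },
 "experimental_essentiality": {},
 "extra_reactions": [],
 "genes": [
  {
   "end": 240,
   "id": "g1",
   "name": "enzyme alpha",
   "product_type": "protein",
   "protein_sequence": null,
   "start": 150,
   "strand": "+"
  },
  {
   "end": 352,
   "id": "g2",
   "name": "enzyme beta",
   "product_type": "protein",
   "protein_sequence": null,
   "start": 250,
   "strand": "+"
  },
  {
   "end": 450,
   "id": "g3",
   "name": "initiator",
   "product_type": "protein",
   "protein_sequence": null,
   "start": 360,
   "strand": "+"
  },
  {
   "end": 705,
   "id": "g4",
   "name": "kinase",
   "product_type": "protein",
   "protein_sequence": null,
   "start": 600,
   "strand": "-"
  },
  {
   "end": 808,
   "id": "g5",
   "name": "porin",
   "product_type": "protein",
   "protein_sequence": null,
   "start": 715,
   "strand": "-"
  }
 ],
 "genome": {
  "ori_position": 0,
  "sequence": "AGGATACACACTCTCCTTTTAGCAATTACGAGCTGATTAGTAAAACAGCACAACAGCTAGGTGTCAATAGGCCTCTTCGGGACGTAGTTAGCCAGACCGCTACCCACCGGCCGTAGACCTCCGTCGTCTCCAGCCGGTCCTCCGGCGGTATCCGAGACACCATTTAACTCCTATACCTTCCTCTTGGAGAACCAGTAATAGGCCATAATCCGGTTCTGAATGCCGACAGCGCGGCGAGGCCTAGGGCGAAGAACGGTCCACGGGCACAATCGCAATCACCGTTAATAATATTATGCCATCCACCAGACCGATGCGACTGTGATTACTATAATAAGTTATCTAGGCCACGTGCGGTTAGGTTGAATGGATATTGCTCTTTCTCTTCTTTACCAAAGAAAGCCTCAACTCCCAAACTTTTCCACGCGCCGGGGCAACGTCATTCGACGGTGCGTAATAGCTCATATAGTGAGATAAGGGTATCTATCAGAGAAGGCCACCTCGGTTGCTTGGACGTGAATCGATCACAACGACAGCGTATTACTTATACGTATTCCAAATCCCTGCCAAACATAGCAACTGGGCGTGGAGAGTCGCTTACCCACCGTGACCCCGCCTTAACGAATTGCGCATTAGTTTTGGGAGAATAGGATCGTAATCTTCAGTACAGGAGGGTGTTATGTACCTTTAAGATATCCATAGCGCACCTCCCACTGCCAATTGACACAACCTGCAGCCGCGTGTCCCAAAGGCGCATCAATGGCGCCAGGTGACACCTAGTCTCAGCACCTTCGCTGATGTGGCCCAGCTGCTCTTTTTTTAGGTTGGACGCTGAAGTCCCATGCTGACGTGCCAACTCATTCCCACCGACAGCGGAAATGATGTAGGTCTAGGGTTATCCATGGAACATTACATAGGTCTCATTTGAAGGAAGCTGCCAGTTAGCAACACCCTTCCTGACGTGATGGGTCTGTCTTGGTGTTACTTTATTAGCGTCCAATAAGTTAATGTAATTGCTAGCTTCATGCACGCACTCTCTTTACTCGCGCTAATGCACTTACACAGCGACTACGTACGTGGGACGCACATGGGGGTCTACTTGGGGTAGCGAATAGCACAGATTCTTCTATGCGAGAGGTAGTTTGCGAGAGCCTCGAGAGCTTGGACGCCTATAGGTCTAGATGATTAAAAACGAGGACTAAA",
  "ter_position": 560
 },
 "machinery": {
  "dnaa_gene": "g3",
  "elongation_factor": "g2",
  "if1": "g4",
  "if2": "g4",
  "if3": "g4",
  "replisome": "CPX1",
  "ribosome": "CPX1",
  "rna_polymerase": "CPX1"
 },
 "metabolic_reactions": [
  {
   "evidence": null,
   "id": "rx_uptake_glc",
   "modifiers": [
    "g5"
   ],
   "name": "glucose uptake",
   "process": "Transmembrane Transport",
   "products": [
    [
     "GLC[c]",
     1
    ]
   ],
   "reactants": [
    [
     "GLC[e]",
     1
    ]
   ],
   "reversible": false
  },
  {
   "evidence": null,
   "id": "rx_pgi",
   "modifiers": [
    "g2"
   ],
   "name": "isomerisation",
   "process": "Metabolism",
   "products": [
    [
     "G6P[c]",
     1
    ]
   ],
   "reactants": [
    [
     "GLC[c]",
     1
    ]
   ],
   "reversible": false
  },
  {
   "evidence": null,
   "id": "rx_aldol",
   "modifiers": [
    "CPX1"
   ],
   "name": "condensation",
   "process": "Metabolism",
   "products": [
    [
     "FBP[c]",
     1
    ]
   ],
   "reactants": [
    [
     "GLC[c]",
     1
    ],
    [
     "G6P[c]",
     1
    ]
   ],
   "reversible": false
  }
 ],
 "metabolites": [
  {
   "boundary_compartments": [
    "e"
   ],
   "compartments": [
    "c",
    "e"
   ],
   "id": "GLC",
   "mass": 180.16,
   "name": "glucose"
  },
  {
   "boundary_compartments": [],
   "compartments": [
    "c"
   ],
   "id": "G6P",
   "mass": 180.16,
   "name": "glucose 6-phosphate"
  },
  {
   "boundary_compartments": [],
   "compartments": [
    "c"
   ],
   "id": "FBP",
   "mass": 360.32,
   "name": "fructose bisphosphate"
  }
 ],
 "organism": "minicell",
 "protein_annotations": {},
 "schema_version": "1.0",
 "synthetase_genes": {},
 "transcription_units": [
  {
   "end": 455,
   "gene_ids": [
    "g1",
    "g2",
    "g3"
   ],
   "id": "tu1",
   "start": 145,
   "strand": "+",
   "tf_gene": null
  },
  {
   "end": 812,
   "gene_ids": [
    "g4",
    "g5"
   ],
   "id": "tu2",
   "start": 595,
   "strand": "-",
   "tf_gene": null
  }
 ],
 "trna_genes": {}
}
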