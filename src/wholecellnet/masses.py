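"""Reference masses (average, Da) used to keep synthetic networks mass-balanced.

Energy-carrier masses are chosen self-consistently so that the canonical
hydrolysis identities hold exactly: ATP = AMP + PPi and GTP = GDP + Pi.
Monophosphates are defined as NTP - PPi, which makes transcription
(NTP in, PPi out, RNA = sum of NMPs) and RNA decay (RNA -> NMPs) balance
without an explicit water term; peptide-bond condensation releases one
water per bond, accounted explicitly in translation and protein decay.
"""

from __future__ import annotations

WATER = 18.02
PI = 79.98
PPI = 159.96

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Free amino-acid average masses, Da.
AA_MASS = {
    "A": 89.09, "C": 121.16, "D": 133.10, "E": 147.13, "F": 165.19,
    "G": 75.07, "H": 155.15, "I": 131.17, "K": 146.19, "L": 131.17,
    "M": 149.21, "N": 132.12, "P": 115.13, "Q": 146.15, "R": 174.20,
    "S": 105.09, "T": 119.12, "V": 117.15, "W": 204.23, "Y": 181.19,
}

NTP_MASS = {"A": 507.18, "C": 483.16, "G": 523.18, "U": 484.14}
NMP_MASS = {b: m - PPI for b, m in NTP_MASS.items()}
DNTP_MASS = {"A": 491.18, "C": 467.16, "G": 507.18, "T": 482.17}
GDP = NTP_MASS["G"] - PI
ATP = NTP_MASS["A"]
AMP = NMP_MASS["A"]
GTP = NTP_MASS["G"]


def protein_mass(residues: str) -> float:
    """Mass of a polypeptide: sum of free residues minus condensation water."""
    if not residues:
        return 0.0
    return sum(AA_MASS[a] for a in residues) - (len(residues) - 1) * WATER


def rna_mass(transcript: str) -> float:
    """Mass of an RNA as the sum of its monophosphate residues."""
    return sum(NMP_MASS[b] for b in transcript)
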