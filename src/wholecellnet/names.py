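"""Deterministic id schemes for molecules and reactions.

Molecule ids are ``<name>[<compartment>]``; generated reaction ids are
``RX_<PROCESS-TAG>_<substrate>_<step>`` so that re-instantiating a
template for the same substrate reproduces identical ids.
"""

from __future__ import annotations


def mol(name: str, compartment: str = "c") -> str:
    return f"{name}[{compartment}]"


def split(mol_id: str) -> tuple:
    """Split ``NAME[c]`` into (NAME, c)."""
    name, _, comp = mol_id.rpartition("[")
    return name, comp.rstrip("]")


def monomer(gene_id: str, compartment: str = "c") -> str:
    return mol(f"{gene_id}_MONOMER", compartment)


def immature_monomer(gene_id: str) -> str:
    return mol(f"{gene_id}_MONOMER_IMMATURE")


def signal_peptide(gene_id: str) -> str:
    return mol(f"{gene_id}_SIGNAL_PEPTIDE")


def gene_rna(gene_id: str) -> str:
    return mol(f"{gene_id}_RNA")


def rna_precursor(gene_id: str) -> str:
    return mol(f"{gene_id}_RNA_PRECURSOR")


def charged_trna(gene_id: str) -> str:
    return mol(f"{gene_id}_RNA_AMINOACYLATED")


def tu_rna(tu_id: str) -> str:
    return mol(f"{tu_id}_RNA")


def tu_fragment(tu_id: str) -> str:
    return mol(f"{tu_id}_CLEAVAGE_FRAGMENT")


def region(index: int) -> str:
    return mol(f"CHR_REGION_{index}")


def bound_region(index: int, protein: str) -> str:
    return mol(f"CHR_REGION_{index}__{protein}")


def replisome_state(arm: str, index) -> str:
    return mol(f"REPLISOME_{arm}_AT_{index}")


def tx_state(tu_id: str, index) -> str:
    return mol(f"TX_COMPLEX_{tu_id}_AT_{index}")


def tl_state(gene_id: str) -> str:
    return mol(f"TL_COMPLEX_{gene_id}")


DUPLICATED_CHROMOSOME = mol("CHROMOSOME_DUPLICATED")

AA_METABOLITE = "AA_{}"  # e.g. AA_A[c]
NTP_METABOLITE = "{}TP"  # ATP, CTP, GTP, UTP
NMP_METABOLITE = "{}MP"
DNTP_METABOLITE = "d{}TP"  # dATP, dCTP, dGTP, dTTP


def aa(letter: str, compartment: str = "c") -> str:
    return mol(AA_METABOLITE.format(letter), compartment)


def ntp(base: str, compartment: str = "c") -> str:
    return mol(NTP_METABOLITE.format(base), compartment)


def nmp(base: str, compartment: str = "c") -> str:
    return mol(NMP_METABOLITE.format(base), compartment)


def dntp(base: str, compartment: str = "c") -> str:
    return mol(DNTP_METABOLITE.format(base), compartment)


WATER = mol("WATER")
PI = mol("PI")
PPI = mol("PPI")
GDP = mol("GDP")


def rx(process_tag: str, *parts) -> str:
    tag = "_".join(str(p) for p in parts)
    return f"RX_{process_tag}_{tag}" if tag else f"RX_{process_tag}"
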