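"""Topological summaries of a whole-cell network.

Node degree is the number of incident connections, any role and either
direction (modifier edges count).  A molecule's process participation is
the number of distinct process labels among the reactions it touches;
molecules in two or more processes are the interfaces between them.
Spearman rank correlation between degree and process count is reported
both over all molecules and restricted to proteins and metabolites,
where degree distributions in the literature are closest to power laws.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from .model import CellNetwork


@dataclass
class TopologySummary:
    n_molecules: int
    n_reactions: int
    n_edges: int
    molecules_per_category: dict
    reactions_per_process: dict
    molecules_per_compartment: dict
    degree_histogram: dict  # degree -> count (all molecule nodes)
    degree_histogram_per_category: dict
    reaction_degree_histogram: dict
    processes_per_molecule_histogram: dict
    fraction_multi_process: float
    spearman_all: Optional[float] = None
    spearman_protein_metabolite: Optional[float] = None
    extras: dict = field(default_factory=dict)


def processes_per_molecule(net: CellNetwork) -> dict:
    """Distinct cellular processes each molecule participates in (any role)."""
    out = {}
    for mid in net.molecules:
        procs = {net.reactions[rid].process for rid in net.incident_reactions(mid)}
        out[mid] = len(procs)
    return out


def _spearman(x, y) -> Optional[float]:
    # undefined (not zero) for constant ranks or fewer than two points
    if len(x) < 2 or len(set(x)) < 2 or len(set(y)) < 2:
        return None
    rho = stats.spearmanr(x, y).statistic
    return None if rho != rho else float(rho)


def summarize_topology(net: CellNetwork) -> TopologySummary:
    proc_counts = processes_per_molecule(net)
    mol_degrees = {mid: net.degree(mid) for mid in net.molecules}
    per_category_hist: dict = {}
    cat_counter: Counter = Counter()
    comp_counter: Counter = Counter()
    for mid, mol in net.molecules.items():
        cat_counter[mol.category] += 1
        comp_counter[mol.compartment] += 1
        per_category_hist.setdefault(mol.category, Counter())[mol_degrees[mid]] += 1
    rxn_counter = Counter(r.process for r in net.reactions.values())
    multi = sum(1 for c in proc_counts.values() if c >= 2)
    n_mol = net.n_molecules

    pm_ids = [
        mid
        for mid, mol in net.molecules.items()
        if mol.category in ("protein_monomer", "protein_complex", "metabolite")
    ]
    all_ids = sorted(net.molecules)
    return TopologySummary(
        n_molecules=n_mol,
        n_reactions=net.n_reactions,
        n_edges=net.n_edges,
        molecules_per_category=dict(cat_counter),
        reactions_per_process=dict(rxn_counter),
        molecules_per_compartment=dict(comp_counter),
        degree_histogram=dict(Counter(mol_degrees.values())),
        degree_histogram_per_category={k: dict(v) for k, v in per_category_hist.items()},
        reaction_degree_histogram=dict(Counter(net.degree(rid) for rid in net.reactions)),
        processes_per_molecule_histogram=dict(Counter(proc_counts.values())),
        fraction_multi_process=multi / n_mol if n_mol else float("nan"),
        spearman_all=_spearman(
            [mol_degrees[m] for m in all_ids], [proc_counts[m] for m in all_ids]
        ),
        spearman_protein_metabolite=_spearman(
            [mol_degrees[m] for m in pm_ids], [proc_counts[m] for m in pm_ids]
        ),
    )


def summary_to_jsonable(summary: TopologySummary) -> dict:
    def key_str(d):
        return {str(k): v for k, v in d.items()}

    return {
        "n_molecules": summary.n_molecules,
        "n_reactions": summary.n_reactions,
        "n_edges": summary.n_edges,
        "molecules_per_category": summary.molecules_per_category,
        "reactions_per_process": summary.reactions_per_process,
        "molecules_per_compartment": summary.molecules_per_compartment,
        "degree_histogram": key_str(summary.degree_histogram),
        "degree_histogram_per_category": {
            k: key_str(v) for k, v in summary.degree_histogram_per_category.items()
        },
        "reaction_degree_histogram": key_str(summary.reaction_degree_histogram),
        "processes_per_molecule_histogram": key_str(summary.processes_per_molecule_histogram),
        "fraction_multi_process": summary.fraction_multi_process,
        "spearman_all": summary.spearman_all,
        "spearman_protein_metabolite": summary.spearman_protein_metabolite,
    }
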