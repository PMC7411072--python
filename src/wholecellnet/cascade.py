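"""Cascading-failure dynamics and gene-essentiality prediction.

Deleting a gene removes the molecule nodes representing its functional
product (protein monomer states for coding genes, the RNA itself for
tRNA/rRNA genes).  Failures then propagate to a fixpoint under two rules:

* a reaction fails when any of its reactant or modifier molecules has
  been removed (loss of a substrate or of the catalyst/template);
* a non-boundary molecule fails when *all* reactions producing it have
  failed, provided it had at least one producer in the intact network.

The result is order-independent (the rules are monotone), which the test
suite checks against a naive repeat-until-stable oracle.  A gene (or gene
pair) is called essential when the cascade removes the critical
cell-division reaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd

from .errors import UnknownIdError
from .kb import KBBundle
from .model import CellNetwork


@dataclass
class CascadeResult:
    seeds: set
    removed_molecules: set
    removed_reactions: set
    division_removed: bool = False


@dataclass
class EssentialityCall:
    genes: tuple
    predicted: str  # "essential" | "non_essential"
    experimental: str = "unknown"
    removed_molecules: int = 0
    removed_reactions: int = 0


def cascade_failure(net: CellNetwork, seeds: Iterable[str]) -> CascadeResult:
    """Worklist fixpoint of the failure propagation rules."""
    seeds = set(seeds)
    for s in seeds:
        if s not in net.molecules:
            raise UnknownIdError(f"cascade seed {s!r} is not a molecule node")
    removed_mols = set(seeds)
    removed_rxns: set = set()
    live_producers = {mid: len(net.producers_of(mid)) for mid in net.molecules}
    stack = list(seeds)
    while stack:
        mid = stack.pop()
        # R1: reactions lose a reactant or modifier
        for rid in net.consumers_of(mid) | net.modified_by(mid):
            if rid in removed_rxns:
                continue
            removed_rxns.add(rid)
            # R2: products may lose their last producer
            for qid, _ in net.reaction_parts(rid)["product"]:
                if qid in removed_mols:
                    continue
                live_producers[qid] -= 1
                if (
                    live_producers[qid] <= 0
                    and not net.molecules[qid].is_boundary
                    and net.producers_of(qid)
                ):
                    removed_mols.add(qid)
                    stack.append(qid)
    result = CascadeResult(
        seeds=seeds, removed_molecules=removed_mols, removed_reactions=removed_rxns
    )
    if net.critical_reaction_id is not None:
        result.division_removed = net.critical_reaction_id in removed_rxns
    return result


def cascade_failure_naive(net: CellNetwork, seeds: Iterable[str]) -> CascadeResult:
    """Reference implementation: full rescans until nothing changes.

    Independent of the worklist bookkeeping; used as the oracle in tests.
    """
    removed_mols = set(seeds)
    removed_rxns: set = set()
    while True:
        changed = False
        for rid in net.reactions:
            if rid in removed_rxns:
                continue
            parts = net.reaction_parts(rid)
            inputs = [m for m, _ in parts["reactant"] + parts["modifier"]]
            if any(m in removed_mols for m in inputs):
                removed_rxns.add(rid)
                changed = True
        for mid in net.molecules:
            if mid in removed_mols:
                continue
            producers = net.producers_of(mid)
            if (
                producers
                and producers <= removed_rxns
                and not net.molecules[mid].is_boundary
            ):
                removed_mols.add(mid)
                changed = True
        if not changed:
            break
    result = CascadeResult(
        seeds=set(seeds), removed_molecules=removed_mols, removed_reactions=removed_rxns
    )
    if net.critical_reaction_id is not None:
        result.division_removed = net.critical_reaction_id in removed_rxns
    return result


def gene_targets(kb: KBBundle, net: CellNetwork, gene_id: str) -> set:
    """Molecule nodes that represent a gene's functional product.

    Protein-coding genes map to all monomer-state nodes (immature and
    functional); tRNA/rRNA/ncRNA genes map to the mature RNA node itself.
    Complexes containing the monomer are not seeded -- the cascade removes
    them through their formation reactions.
    """
    gene = kb.gene_by_id.get(gene_id)
    if gene is None:
        raise UnknownIdError(f"unknown gene {gene_id!r}")
    targets = set()
    if gene.product_type == "protein":
        wanted_categories = ("protein_monomer",)
        wanted_states = ("functional", "immature")
    else:
        wanted_categories = ("rna",)
        wanted_states = ("functional",)
    for mid, mol in net.molecules.items():
        if (
            mol.category in wanted_categories
            and mol.state in wanted_states
            and mol.gene_ids == frozenset({gene_id})
        ):
            targets.add(mid)
    return targets


def essentiality_scan(
    net: CellNetwork,
    kb: KBBundle,
    mode: str = "single",
    restrict_pairs_to_single_nonessential: bool = True,
) -> list:
    """Single- or double-deletion essentiality calls against the critical reaction.

    In double mode each unordered pair is deleted jointly and reported as
    essential-in-combination only when neither singleton was essential.
    By monotonicity of the cascade, restricting pairs to genes that are
    singly non-essential loses no combination-essential pair.
    """
    if net.critical_reaction_id is None:
        raise UnknownIdError("network has no critical reaction set")
    labels = kb.experimental_essentiality
    gene_ids = sorted(g.id for g in kb.genes)
    target_cache = {g: gene_targets(kb, net, g) for g in gene_ids}

    def pair_experimental(genes):
        vals = [labels.get(g, "unknown") for g in genes]
        if "unknown" in vals:
            return "unknown"
        return "essential" if all(v == "essential" for v in vals) else "non-essential"

    singles = {}
    calls = []
    for g in gene_ids:
        res = cascade_failure(net, target_cache[g])
        predicted = "essential" if res.division_removed else "non_essential"
        singles[g] = predicted
        calls.append(
            EssentialityCall(
                genes=(g,),
                predicted=predicted,
                experimental=labels.get(g, "unknown"),
                removed_molecules=len(res.removed_molecules),
                removed_reactions=len(res.removed_reactions),
            )
        )
    if mode == "single":
        return calls
    if mode != "double":
        raise ValueError(f"bad scan mode {mode!r}")

    pool = gene_ids
    if restrict_pairs_to_single_nonessential:
        pool = [g for g in gene_ids if singles[g] == "non_essential"]
    pair_calls = []
    for g1, g2 in combinations(pool, 2):
        res = cascade_failure(net, target_cache[g1] | target_cache[g2])
        pair_essential = (
            res.division_removed
            and singles[g1] == "non_essential"
            and singles[g2] == "non_essential"
        )
        pair_calls.append(
            EssentialityCall(
                genes=(g1, g2),
                predicted="essential" if pair_essential else "non_essential",
                experimental=pair_experimental((g1, g2)),
                removed_molecules=len(res.removed_molecules),
                removed_reactions=len(res.removed_reactions),
            )
        )
    return pair_calls


@dataclass
class ConfusionRates:
    match: float
    false_positive: float
    false_negative: float
    restricted_match: Optional[float] = None
    restricted_false_positive: Optional[float] = None
    n: int = 0
    n_predicted_essential: int = 0


def confusion_rates(calls: Iterable[EssentialityCall], labels: Optional[dict] = None) -> ConfusionRates:
    """Match / false-positive / false-negative fractions against experiment.

    Genes with unknown experimental labels are counted as non-essential.
    The three rates sum to one.  The restricted variant conditions on
    predicted-essential genes only (its false-negative rate is zero by
    construction).
    """
    calls = list(calls)
    n = len(calls)
    if n == 0:
        return ConfusionRates(match=float("nan"), false_positive=float("nan"), false_negative=float("nan"))
    match = fp = fn = 0
    pred_ess = pred_ess_correct = 0
    for call in calls:
        if labels is not None:
            exp = labels.get(call.genes[0] if len(call.genes) == 1 else call.genes, call.experimental)
        else:
            exp = call.experimental
        exp_essential = exp == "essential"
        pred_essential = call.predicted == "essential"
        if pred_essential:
            pred_ess += 1
            if exp_essential:
                pred_ess_correct += 1
        if pred_essential == exp_essential:
            match += 1
        elif pred_essential:
            fp += 1
        else:
            fn += 1
    rates = ConfusionRates(
        match=match / n,
        false_positive=fp / n,
        false_negative=fn / n,
        n=n,
        n_predicted_essential=pred_ess,
    )
    if pred_ess:
        rates.restricted_match = pred_ess_correct / pred_ess
        rates.restricted_false_positive = 1.0 - pred_ess_correct / pred_ess
    return rates


def calls_to_frame(calls: Iterable[EssentialityCall]) -> pd.DataFrame:
    rows = [
        {
            "genes": "+".join(c.genes),
            "predicted": c.predicted,
            "experimental": c.experimental,
            "removed_molecules": c.removed_molecules,
            "removed_reactions": c.removed_reactions,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
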