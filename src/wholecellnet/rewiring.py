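"""Bipartite-preserving probabilistic rewiring null model.

Each edge is selected independently with probability ``p``; a selected
edge has both endpoints redrawn uniformly at random among nodes of the
same kind (molecule endpoints stay molecules, reaction endpoints stay
reactions), which preserves the node set, the edge multiset of
(role, weight), bipartiteness and the direction conventions.  Duplicate
edges arising from collisions are kept as parallel edges so the edge
count is exactly preserved.  The essentiality scan over a probability
grid quantifies how strongly the gene-essentiality prediction depends on
the true wiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import confusion_rates, essentiality_scan
from .kb import KBBundle
from .model import CellNetwork, RoleEdge


@dataclass
class RewireConfig:
    p_grid: list = field(default_factory=lambda: [round(0.02 * i, 2) for i in range(51)])
    replicates: int = 50
    seed: int = 0

    def __post_init__(self):
        if any(not 0 <= p <= 1 for p in self.p_grid):
            raise ValueError("rewiring probabilities must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def rewire(net: CellNetwork, p: float, seed: int) -> CellNetwork:
    """Randomly reassign both endpoints of each edge with probability ``p``.

    Deterministic for a fixed seed; ``p=0`` returns an identical network.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"rewiring probability {p} outside [0, 1]")
    if p == 0:
        return net.copy()
    rng = np.random.default_rng(seed)
    mol_ids = sorted(net.molecules)
    rxn_ids = sorted(net.reactions)
    new_edges = []
    for edge in net.edges:
        u = rng.random()
        if u <= p and mol_ids and rxn_ids:
            if edge.role in ("reactant", "modifier"):
                source = mol_ids[rng.integers(len(mol_ids))]
                target = rxn_ids[rng.integers(len(rxn_ids))]
            else:
                source = rxn_ids[rng.integers(len(rxn_ids))]
                target = mol_ids[rng.integers(len(mol_ids))]
            new_edges.append(RoleEdge(source, target, edge.role, edge.weight))
        else:
            new_edges.append(edge)
    return CellNetwork.from_parts(
        list(net.molecules.values()),
        list(net.reactions.values()),
        new_edges,
        net.critical_reaction_id,
    )


def rewire_essentiality_scan(
    net: CellNetwork, kb: KBBundle, cfg: RewireConfig
) -> pd.DataFrame:
    """Single-gene essentiality confusion rates across the rewiring grid.

    One row per (p, replicate); per-replicate seeds are spawned
    deterministically from the master seed so each cell of the grid is
    independently reproducible.
    """
    rows = []
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(len(cfg.p_grid) * cfg.replicates)
    k = 0
    for p in cfg.p_grid:
        for rep in range(cfg.replicates):
            child_seed = int(streams[k].generate_state(1)[0] % (2**31))
            k += 1
            rewired = net if p == 0 else rewire(net, p, child_seed)
            calls = essentiality_scan(rewired, kb, mode="single")
            rates = confusion_rates(calls)
            rows.append(
                {
                    "p": p,
                    "replicate": rep,
                    "match": rates.match,
                    "false_positive": rates.false_positive,
                    "false_negative": rates.false_negative,
                    "n_predicted_essential": rates.n_predicted_essential,
                }
            )
    return pd.DataFrame(rows)
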