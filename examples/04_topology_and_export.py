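"""Topological summary and standard-format export.

Computes per-category/process counts, the fraction of molecules acting
as interfaces between two or more cellular processes, and the Spearman
correlation between a molecule's degree and its process count; then
exports the network as GML and SBML L3V2 and reads both back.
"""

from pathlib import Path

from wholecellnet import (
    SynthConfig,
    build_network,
    generate_synthetic_kb,
    read_gml,
    read_sbml,
    summarize_topology,
    write_gml,
    write_sbml,
)

kb = generate_synthetic_kb(SynthConfig(seed=1))
net, _ = build_network(kb)
s = summarize_topology(net)

print(f"molecules by category: {s.molecules_per_category}")
print(f"reactions by process: {dict(sorted(s.reactions_per_process.items()))}")
print(f"molecules in >=2 processes: {100 * s.fraction_multi_process:.1f}%")
print(f"Spearman degree vs processes (all molecules): {s.spearman_all:+.3f}")
print(f"Spearman degree vs processes (proteins+metabolites): "
      f"{s.spearman_protein_metabolite:+.3f}")
# Proteins and metabolites show the positive degree/process correlation;
# over all molecules the correlation is weaker because chromosome regions
# and template intermediates are high-degree but single-process.

out = Path("scratch")
out.mkdir(exist_ok=True)
write_gml(net, out / "network.gml")
write_sbml(net, out / "network.sbml")
g = read_gml(out / "network.gml")
s2 = read_sbml(out / "network.sbml")
print(f"GML round-trip: {g.n_nodes} nodes; SBML round-trip: {s2.n_nodes} nodes "
      f"(original {net.n_nodes})")
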