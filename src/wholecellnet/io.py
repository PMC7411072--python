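"""Serialization of cell networks to GML and SBML.

GML round-trips through :mod:`networkx`; node kind, category,
compartment, state, boundary flag, gene list, mass, process, edge role
and weight are stored as plain attributes (the documented dialect), and
reading validates bipartiteness.

SBML is written as Level 3 Version 2 core: one species per molecule
(with ``boundaryCondition`` for boundary nutrients), one reaction per
reaction node with stoichiometric species references and
modifier-species references for modifier edges.  Ids that are not legal
SBML SIds are sanitised deterministically and the original ids preserved
in a package annotation, so the reader restores them losslessly.
"""

from __future__ import annotations

import re

import networkx as nx
from lxml import etree

from .errors import NetworkError
from .model import CellNetwork, MoleculeNode, ReactionNode, RoleEdge

# -- GML ---------------------------------------------------------------------


def write_gml(net: CellNetwork, path) -> None:
    nx.write_gml(net.to_networkx(), str(path))


def read_gml(path) -> CellNetwork:
    try:
        g = nx.read_gml(str(path))
    except Exception as exc:  # networkx raises several parse error types
        raise NetworkError(f"malformed GML file {path}: {exc}") from exc
    molecules, reactions = [], []
    for node_id, attrs in g.nodes(data=True):
        kind = attrs.get("kind")
        if kind == "molecule":
            molecules.append(
                MoleculeNode(
                    id=node_id,
                    name=attrs.get("name", node_id),
                    category=attrs.get("category", "other"),
                    compartment=attrs.get("compartment", "c"),
                    mass=attrs.get("mass"),
                    gene_ids=frozenset(x for x in attrs.get("genes", "").split(";") if x),
                    state=attrs.get("state", "functional"),
                    is_boundary=bool(attrs.get("boundary", 0)),
                )
            )
        elif kind == "reaction":
            reactions.append(
                ReactionNode(
                    id=node_id,
                    name=attrs.get("name", node_id),
                    process=attrs.get("process", "Metabolism"),
                    evidence=attrs.get("evidence"),
                )
            )
        else:
            raise NetworkError(f"GML node {node_id!r} lacks a valid 'kind' attribute")
    edges = []
    for u, v, attrs in g.edges(data=True):
        role = attrs.get("role")
        if role is None:
            raise NetworkError(f"GML edge {u}->{v} lacks a 'role' attribute")
        edges.append(RoleEdge(u, v, role, float(attrs.get("weight", 1.0))))
    net = CellNetwork.from_parts(molecules, reactions, edges)
    report = net.validate()
    bad = [v for v in report if "bipartiteness" in v or "dangling" in v]
    if bad:
        raise NetworkError(f"GML file {path} is not a valid bipartite network: {bad[:3]}")
    return net


# -- SBML --------------------------------------------------------------------

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
ANNOT_NS = "https://wholecellnet.readthedocs.io/ns/network"

_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _sanitize_ids(ids) -> dict:
    """Deterministic mapping of arbitrary ids to unique SBML SIds."""
    mapping: dict = {}
    used: set = set()
    for raw in ids:
        sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
        if not sid or not re.match(r"[A-Za-z_]", sid[0]):
            sid = "_" + sid
        candidate, k = sid, 2
        while candidate in used:
            candidate = f"{sid}_{k}"
            k += 1
        used.add(candidate)
        mapping[raw] = candidate
    return mapping


def write_sbml(net: CellNetwork, path) -> dict:
    """Write an SBML L3V2 document; returns the id-sanitisation mapping."""
    nsmap = {None: SBML_NS, "wcn": ANNOT_NS}
    q = lambda tag: f"{{{SBML_NS}}}{tag}"
    qa = lambda tag: f"{{{ANNOT_NS}}}{tag}"
    root = etree.Element(q("sbml"), nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(root, q("model"), id="whole_cell_network")

    comps = sorted({m.compartment for m in net.molecules.values()}) or ["c"]
    loc = etree.SubElement(model, q("listOfCompartments"))
    for comp in comps:
        etree.SubElement(loc, q("compartment"), id=f"compartment_{comp}", constant="true")

    mapping = _sanitize_ids(sorted(net.molecules) + sorted(net.reactions))
    los = etree.SubElement(model, q("listOfSpecies"))
    for mid in sorted(net.molecules):
        mol = net.molecules[mid]
        sp = etree.SubElement(
            los,
            q("species"),
            id=mapping[mid],
            name=mol.name,
            compartment=f"compartment_{mol.compartment}",
            hasOnlySubstanceUnits="true",
            boundaryCondition="true" if mol.is_boundary else "false",
            constant="false",
        )
        ann = etree.SubElement(etree.SubElement(sp, q("annotation")), qa("molecule"))
        ann.set("origId", mid)
        ann.set("category", mol.category)
        ann.set("state", mol.state)
        ann.set("genes", ";".join(sorted(mol.gene_ids)))
        if mol.mass is not None:
            ann.set("mass", repr(float(mol.mass)))

    lor = etree.SubElement(model, q("listOfReactions"))
    for rid in sorted(net.reactions):
        rxn = net.reactions[rid]
        parts = net.reaction_parts(rid)
        el = etree.SubElement(lor, q("reaction"), id=mapping[rid], name=rxn.name, reversible="false")
        ann = etree.SubElement(etree.SubElement(el, q("annotation")), qa("reaction"))
        ann.set("origId", rid)
        ann.set("process", rxn.process)
        if rxn.evidence:
            ann.set("evidence", rxn.evidence)
        if parts["reactant"]:
            lst = etree.SubElement(el, q("listOfReactants"))
            for mid, w in parts["reactant"]:
                etree.SubElement(
                    lst,
                    q("speciesReference"),
                    species=mapping[mid],
                    stoichiometry=repr(float(w)),
                    constant="true",
                )
        if parts["product"]:
            lst = etree.SubElement(el, q("listOfProducts"))
            for mid, w in parts["product"]:
                etree.SubElement(
                    lst,
                    q("speciesReference"),
                    species=mapping[mid],
                    stoichiometry=repr(float(w)),
                    constant="true",
                )
        if parts["modifier"]:
            lst = etree.SubElement(el, q("listOfModifiers"))
            for mid, _ in parts["modifier"]:
                etree.SubElement(lst, q("modifierSpeciesReference"), species=mapping[mid])

    if net.critical_reaction_id is not None:
        ann = etree.SubElement(etree.SubElement(model, q("annotation")), qa("network"))
        ann.set("criticalReaction", net.critical_reaction_id)

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return mapping


def read_sbml(path) -> CellNetwork:
    """Read back an SBML document written by :func:`write_sbml`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise NetworkError(f"malformed SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != f"{{{SBML_NS}}}sbml":
        raise NetworkError(f"{path} is not an SBML L3V2 document")
    q = lambda tag: f"{{{SBML_NS}}}{tag}"
    qa = lambda tag: f"{{{ANNOT_NS}}}{tag}"
    model = root.find(q("model"))
    molecules, reactions, edges = [], [], []
    sid_to_orig: dict = {}
    for sp in model.findall(f"{q('listOfSpecies')}/{q('species')}"):
        ann = sp.find(f"{q('annotation')}/{qa('molecule')}")
        orig = ann.get("origId") if ann is not None else sp.get("id")
        sid_to_orig[sp.get("id")] = orig
        mass = ann.get("mass") if ann is not None else None
        molecules.append(
            MoleculeNode(
                id=orig,
                name=sp.get("name", orig),
                category=ann.get("category", "other") if ann is not None else "other",
                compartment=sp.get("compartment", "compartment_c").split("_", 1)[1],
                mass=float(mass) if mass is not None else None,
                gene_ids=frozenset(
                    x for x in (ann.get("genes", "") if ann is not None else "").split(";") if x
                ),
                state=ann.get("state", "functional") if ann is not None else "functional",
                is_boundary=sp.get("boundaryCondition") == "true",
            )
        )
    critical = None
    net_ann = model.find(f"{q('annotation')}/{qa('network')}")
    if net_ann is not None:
        critical = net_ann.get("criticalReaction")
    for el in model.findall(f"{q('listOfReactions')}/{q('reaction')}"):
        ann = el.find(f"{q('annotation')}/{qa('reaction')}")
        orig = ann.get("origId") if ann is not None else el.get("id")
        reactions.append(
            ReactionNode(
                id=orig,
                name=el.get("name", orig),
                process=ann.get("process", "Metabolism") if ann is not None else "Metabolism",
                evidence=ann.get("evidence") if ann is not None else None,
            )
        )
        for ref in el.findall(f"{q('listOfReactants')}/{q('speciesReference')}"):
            edges.append(
                RoleEdge(
                    sid_to_orig[ref.get("species")], orig, "reactant",
                    float(ref.get("stoichiometry", 1.0)),
                )
            )
        for ref in el.findall(f"{q('listOfProducts')}/{q('speciesReference')}"):
            edges.append(
                RoleEdge(
                    orig, sid_to_orig[ref.get("species")], "product",
                    float(ref.get("stoichiometry", 1.0)),
                )
            )
        for ref in el.findall(f"{q('listOfModifiers')}/{q('modifierSpeciesReference')}"):
            edges.append(RoleEdge(sid_to_orig[ref.get("species")], orig, "modifier", 1.0))
    return CellNetwork.from_parts(molecules, reactions, edges, critical)


def validate_sbml_structure(path) -> list:
    """Structural checks of an SBML L3V2 document; returns a list of problems."""
    problems = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    root = tree.getroot()
    if root.tag != f"{{{SBML_NS}}}sbml":
        problems.append("root element is not sbml (level 3 version 2 core namespace)")
        return problems
    if (root.get("level"), root.get("version")) != ("3", "2"):
        problems.append("declared level/version is not 3/2")
    q = lambda tag: f"{{{SBML_NS}}}{tag}"
    model = root.find(q("model"))
    if model is None:
        problems.append("missing model element")
        return problems
    species_ids = set()
    for sp in model.findall(f"{q('listOfSpecies')}/{q('species')}"):
        sid = sp.get("id")
        if sid is None or not _SID_RE.match(sid):
            problems.append(f"illegal species id {sid!r}")
        if sid in species_ids:
            problems.append(f"duplicate species id {sid!r}")
        species_ids.add(sid)
        if sp.get("compartment") is None:
            problems.append(f"species {sid} lacks a compartment")
        if sp.get("constant") is None:
            problems.append(f"species {sid} lacks required 'constant' attribute")
    comp_ids = {
        c.get("id") for c in model.findall(f"{q('listOfCompartments')}/{q('compartment')}")
    }
    for sp in model.findall(f"{q('listOfSpecies')}/{q('species')}"):
        if sp.get("compartment") not in comp_ids:
            problems.append(f"species {sp.get('id')} references unknown compartment")
    for el in model.findall(f"{q('listOfReactions')}/{q('reaction')}"):
        rid = el.get("id")
        if rid is None or not _SID_RE.match(rid):
            problems.append(f"illegal reaction id {rid!r}")
        if el.get("reversible") is None:
            problems.append(f"reaction {rid} lacks required 'reversible' attribute")
        for ref in el.iter(q("speciesReference"), q("modifierSpeciesReference")):
            if ref.get("species") not in species_ids:
                problems.append(f"reaction {rid} references unknown species")
    return problems
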