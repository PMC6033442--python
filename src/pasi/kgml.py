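"""KEGG KGML parsing into signed directed pathway graphs, plus topology utilities.

A pathway is modelled as nodes (gene products, gene-product groups, and
compounds) joined by directed, signed relations.  ``map``-type KGML entries
(links to other pathways) carry no expression-measurable content and are
dropped on parse.  Relation subtypes are collapsed to a sign: inhibiting
subtypes win over activating ones, everything else is neutral.

The module also provides controlled structural degradation
(:func:`remove_random`) used to probe robustness of downstream scoring to
incomplete pathway knowledge, and a minimal KGML writer so synthetic
pathways can exercise the real parser.
"""

from __future__ import annotations

import logging
import math
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

GENE = "gene"
GROUP = "group"
COMPOUND = "compound"

INHIBITING_SUBTYPES = frozenset({"inhibition", "repression"})
ACTIVATING_SUBTYPES = frozenset({"activation", "expression"})


def relation_sign(subtypes) -> int:
    """Collapse KGML relation subtypes to a sign in {-1, +1, 0}.

    Inhibition takes precedence over activation when both are listed
    (missing an inhibiting edge is the costlier mistake); subtypes implying
    neither direction (binding/association, phosphorylation, ...) are
    neutral.
    """
    names = {str(s).strip().lower() for s in subtypes}
    if names & INHIBITING_SUBTYPES:
        return -1
    if names & ACTIVATING_SUBTYPES:
        return +1
    return 0


@dataclass(frozen=True)
class PathwayNode:
    """A functional unit of a pathway: a gene product, group, or compound."""

    node_id: str
    kind: str  # gene | group | compound
    members: frozenset = frozenset()  # Entrez IDs; empty for compounds
    component_ids: tuple = ()  # for groups: the entry IDs of the components

    def __post_init__(self) -> None:
        if self.kind in (GENE, GROUP) and not self.members:
            raise InputError(f"{self.kind} node {self.node_id} has no member genes")


@dataclass(frozen=True)
class Relation:
    """A directional interaction between two pathway nodes."""

    source: str
    target: str
    sign: int
    subtypes: tuple = ()

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


@dataclass
class Pathway:
    pathway_id: str
    name: str
    nodes: list
    relations: list

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise InputError("pathway_id must be nonempty")
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise InputError(f"duplicate node ids in pathway {self.pathway_id}")
        known = set(ids)
        for rel in self.relations:
            if rel.source not in known or rel.target not in known:
                raise InputError(
                    f"relation {rel.source}->{rel.target} references a missing node"
                )

    @property
    def node_ids(self) -> list:
        return [n.node_id for n in self.nodes]

    def node(self, node_id: str) -> PathwayNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise InputError(f"no node {node_id!r} in pathway {self.pathway_id}")

    def member_genes(self) -> set:
        """Union of Entrez IDs over all gene/group nodes."""
        out: set = set()
        for n in self.nodes:
            out |= set(n.members)
        return out

    def graph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((r.source, r.target) for r in self.relations)
        return g


def _entrez_members(name_attr: str) -> frozenset:
    members = set()
    for token in str(name_attr).split():
        if ":" in token:
            token = token.split(":", 1)[1]
        try:
            members.add(int(token))
        except ValueError:
            continue
    return frozenset(members)


def parse_kgml(file) -> Pathway:
    """Parse one KGML file into a :class:`Pathway`.

    Gene entries become gene nodes carrying all listed Entrez IDs; group
    entries become group nodes whose members are the union of their
    components' members; compound entries are kept as member-less compound
    nodes; map entries (and any other entry type) are dropped.  Relations
    referencing dropped entries are discarded with a log message, and
    duplicate (source, target, sign) relations are de-duplicated.
    """
    try:
        tree = ET.parse(os.fspath(file))
    except ET.ParseError as exc:
        raise FormatError(f"malformed KGML in {file}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise FormatError(f"{file}: root element is <{root.tag}>, expected <pathway>")
    pathway_id = str(root.get("name", "")).removeprefix("path:") or str(
        root.get("number", "")
    )
    name = str(root.get("title", pathway_id))

    raw: dict[str, ET.Element] = {}
    for entry in root.findall("entry"):
        raw[str(entry.get("id"))] = entry

    nodes: list[PathwayNode] = []
    kept: set[str] = set()
    n_dropped = 0
    for entry_id, entry in raw.items():
        etype = str(entry.get("type", ""))
        if etype == GENE:
            members = _entrez_members(entry.get("name", ""))
            if not members:
                logger.info("%s: gene entry %s has no parseable Entrez IDs, dropped", pathway_id, entry_id)
                n_dropped += 1
                continue
            nodes.append(PathwayNode(entry_id, GENE, members))
            kept.add(entry_id)
        elif etype == COMPOUND:
            nodes.append(PathwayNode(entry_id, COMPOUND))
            kept.add(entry_id)
        elif etype == GROUP:
            comp_ids = tuple(str(c.get("id")) for c in entry.findall("component"))
            members: set = set()
            for cid in comp_ids:
                comp = raw.get(cid)
                if comp is None:
                    logger.info("%s: group %s references missing component %s", pathway_id, entry_id, cid)
                    continue
                members |= set(_entrez_members(comp.get("name", "")))
            if not members:
                logger.info("%s: group entry %s has no measurable members, dropped", pathway_id, entry_id)
                n_dropped += 1
                continue
            nodes.append(PathwayNode(entry_id, GROUP, frozenset(members), comp_ids))
            kept.add(entry_id)
        else:
            # map entries (links to other pathways) and exotic types carry no
            # measurable content
            n_dropped += 1
    if n_dropped:
        logger.info("%s: dropped %d non-measurable entries", pathway_id, n_dropped)

    relations: list[Relation] = []
    seen: set = set()
    n_bad = 0
    for rel in root.findall("relation"):
        source, target = str(rel.get("entry1")), str(rel.get("entry2"))
        if source not in kept or target not in kept:
            n_bad += 1
            continue
        subtypes = tuple(str(s.get("name", "")) for s in rel.findall("subtype"))
        key = (source, target, relation_sign(subtypes))
        if key in seen:
            continue
        seen.add(key)
        relations.append(Relation(source, target, key[2], subtypes))
    if n_bad:
        logger.info("%s: dropped %d relations with missing endpoints", pathway_id, n_bad)

    return Pathway(pathway_id, name, nodes, relations)


def read_kgml_dir(directory) -> list:
    """Parse every ``*.xml`` / ``*.kgml`` file in a directory, sorted by name."""
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"KGML directory not found: {directory}")
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".xml", ".kgml")
    )
    if not files:
        raise InputError(f"no KGML files in {directory}")
    return [parse_kgml(p) for p in files]


def downstream_reach(p: Pathway, node_id: str) -> int:
    """Number of distinct other nodes reachable by following relations forward.

    Sign-agnostic; the start node is excluded even when it sits on a cycle
    or a self-loop.
    """
    if node_id not in set(p.node_ids):
        raise InputError(f"no node {node_id!r} in pathway {p.pathway_id}")
    g = p.graph()
    return len(nx.descendants(g, node_id) - {node_id})


def inhibition_fraction(p: Pathway) -> float:
    """Share of relations whose sign is inhibiting; NaN if there are none."""
    if not p.relations:
        return math.nan
    n_inh = sum(1 for r in p.relations if r.sign == -1)
    return n_inh / len(p.relations)


def remove_random(p: Pathway, fraction: float, what: str, seed) -> Pathway:
    """Remove ``floor(fraction * N)`` nodes or relations uniformly at random.

    Node removal also deletes all relations incident to a removed node, so
    the output is always a structurally valid pathway.  Deterministic for a
    fixed seed.
    """
    if not 0.0 <= fraction <= 0.5:
        raise InputError(f"removal fraction must be in [0, 0.5], got {fraction}")
    if what not in ("nodes", "relations"):
        raise InputError(f"what must be 'nodes' or 'relations', got {what!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if what == "relations":
        n = len(p.relations)
        k = math.floor(fraction * n)
        if k == 0:
            return replace(p, nodes=list(p.nodes), relations=list(p.relations))
        drop = set(rng.choice(n, size=k, replace=False).tolist())
        relations = [r for i, r in enumerate(p.relations) if i not in drop]
        return replace(p, nodes=list(p.nodes), relations=relations)

    n = len(p.nodes)
    k = math.floor(fraction * n)
    if k == 0:
        return replace(p, nodes=list(p.nodes), relations=list(p.relations))
    drop_idx = set(rng.choice(n, size=k, replace=False).tolist())
    removed = {p.nodes[i].node_id for i in drop_idx}
    nodes = [nd for i, nd in enumerate(p.nodes) if i not in drop_idx]
    # drop components of surviving groups that referenced removed entries
    nodes = [
        replace(nd, component_ids=tuple(c for c in nd.component_ids if c not in removed))
        if nd.kind == GROUP
        else nd
        for nd in nodes
    ]
    relations = [
        r for r in p.relations if r.source not in removed and r.target not in removed
    ]
    return replace(p, nodes=nodes, relations=relations)


def write_kgml(p: Pathway, file) -> None:
    """Write a minimal well-formed KGML file that round-trips through
    :func:`parse_kgml` to an equal :class:`Pathway`.

    Group nodes must carry ``component_ids`` referencing gene entries of the
    same pathway (as parsed groups do); a group without components cannot be
    expressed in KGML and raises :class:`InputError`.
    """
    org = "".join(c for c in p.pathway_id if c.isalpha()) or "ko"
    number = "".join(c for c in p.pathway_id if c.isdigit())
    root = ET.Element(
        "pathway",
        {"name": f"path:{p.pathway_id}", "org": org, "number": number, "title": p.name},
    )
    for node in p.nodes:
        if node.kind == GENE:
            ET.SubElement(
                root,
                "entry",
                {
                    "id": node.node_id,
                    "name": " ".join(f"{org}:{m}" for m in sorted(node.members)),
                    "type": GENE,
                },
            )
        elif node.kind == COMPOUND:
            ET.SubElement(
                root, "entry", {"id": node.node_id, "name": "undefined", "type": COMPOUND}
            )
        elif node.kind == GROUP:
            if not node.component_ids:
                raise InputError(
                    f"group node {node.node_id} has no component ids; cannot emit KGML"
                )
            entry = ET.SubElement(
                root, "entry", {"id": node.node_id, "name": "undefined", "type": GROUP}
            )
            for cid in node.component_ids:
                ET.SubElement(entry, "component", {"id": cid})
        else:
            raise InputError(f"unknown node kind {node.kind!r}")
    for rel in p.relations:
        elem = ET.SubElement(
            root,
            "relation",
            {"entry1": rel.source, "entry2": rel.target, "type": "PPrel"},
        )
        subtypes = rel.subtypes
        if not subtypes and rel.sign != 0:
            subtypes = ("inhibition",) if rel.sign == -1 else ("activation",)
        for name in subtypes:
            ET.SubElement(elem, "subtype", {"name": name, "value": ""})
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(os.fspath(file), encoding="unicode", xml_declaration=True)
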