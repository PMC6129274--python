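"""Hierarchical orthologous groups (HOGs) from OrthoXML.

A HOG is a tree whose leaves are genes and whose internal nodes are either
ortholog groups (speciation events) or paralog groups (duplication events).
Score propagation decays across every edge, and edges below a duplication
node carry a heavier penalty because they separate paralogous lineages.

The OrthoXML subset read here is the 0.3-style layout OMA distributes:
``<species><database><genes><gene id protId>`` declarations followed by
``<groups>`` containing nested ``<orthologGroup>`` / ``<paralogGroup>`` /
``<geneRef>`` elements.
"""
from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import IO, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "GENE_LEAF",
    "ORTHOLOG_GROUP",
    "PARALOG_GROUP",
    "HOGNode",
    "GeneCatalogue",
    "OrthoXMLError",
    "parse_orthoxml",
    "write_orthoxml",
    "edge_factor",
    "leaf_genes",
    "iter_nodes",
]

GENE_LEAF = "gene_leaf"
ORTHOLOG_GROUP = "ortholog_group"
PARALOG_GROUP = "paralog_group"

_NS = "http://orthoXML.org/2011/"


class OrthoXMLError(ValueError):
    """Raised for an invalid OrthoXML document (e.g. unresolved geneRef)."""


@dataclass(eq=False)
class HOGNode:
    """One node of a HOG tree.

    ``kind`` is one of :data:`GENE_LEAF`, :data:`ORTHOLOG_GROUP`,
    :data:`PARALOG_GROUP`.  Leaves carry a ``gene_id`` and no children;
    internal nodes carry >= 1 child.  ``hog_id`` is the identifier of the
    root group the node belongs to.  Nodes hash by identity so they can key
    per-node score tables.
    """

    kind: str
    children: list["HOGNode"] = field(default_factory=list)
    gene_id: str | None = None
    taxon: str | None = None
    hog_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind == GENE_LEAF:
            if self.gene_id is None:
                raise ValueError("gene_leaf requires a gene_id")
            if self.children:
                raise ValueError("gene_leaf cannot have children")
        elif self.kind not in (ORTHOLOG_GROUP, PARALOG_GROUP):
            raise ValueError(f"unknown node kind {self.kind!r}")

    @property
    def is_leaf(self) -> bool:
        return self.kind == GENE_LEAF


@dataclass
class GeneCatalogue:
    """Mapping from OrthoXML-internal gene ids to external ids and species."""

    ext_id: dict[str, str] = field(default_factory=dict)
    species: dict[str, str] = field(default_factory=dict)

    def add(self, internal_id: str, ext_id: str, species: str) -> None:
        if internal_id in self.ext_id:
            raise OrthoXMLError(f"duplicate gene id {internal_id!r}")
        self.ext_id[internal_id] = ext_id
        self.species[internal_id] = species


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_group(elem: ET.Element, catalogue: GeneCatalogue, hog_id: str) -> HOGNode | None:
    kind = ORTHOLOG_GROUP if _local(elem.tag) == "orthologGroup" else PARALOG_GROUP
    children: list[HOGNode] = []
    for child in elem:
        tag = _local(child.tag)
        if tag == "geneRef":
            ref = child.get("id", "")
            if ref not in catalogue.ext_id:
                raise OrthoXMLError(f"geneRef to undeclared gene id {ref!r}")
            children.append(
                HOGNode(GENE_LEAF, gene_id=catalogue.ext_id[ref], hog_id=hog_id)
            )
        elif tag in ("orthologGroup", "paralogGroup"):
            sub = _parse_group(child, catalogue, hog_id)
            if sub is not None:
                children.append(sub)
        # <property>/<score> etc. are ignored
    if not children:
        logger.warning("empty %s element dropped", _local(elem.tag))
        return None
    return HOGNode(kind, children=children, hog_id=hog_id,
                   taxon=elem.get("taxonId") or None)


def parse_orthoxml(stream: IO) -> tuple[list[HOGNode], GeneCatalogue]:
    """Parse an OrthoXML document into a forest of HOG trees.

    Returns one tree per top-level ``<orthologGroup>`` (or
    ``<paralogGroup>``), with nesting preserved and geneRefs resolved to
    external ids through the :class:`GeneCatalogue`.

    Raises
    ------
    OrthoXMLError
        On a geneRef to an undeclared gene id, or duplicate gene ids.
    """
    tree = ET.parse(stream)
    root = tree.getroot()
    catalogue = GeneCatalogue()
    for species in root.iter():
        if _local(species.tag) != "species":
            continue
        sp_name = species.get("name", "")
        for gene in species.iter():
            if _local(gene.tag) == "gene":
                catalogue.add(
                    gene.get("id", ""),
                    gene.get("protId") or gene.get("geneId") or gene.get("id", ""),
                    sp_name,
                )
    forest: list[HOGNode] = []
    for groups in root:
        if _local(groups.tag) != "groups":
            continue
        for i, elem in enumerate(groups):
            if _local(elem.tag) not in ("orthologGroup", "paralogGroup"):
                continue
            hog_id = elem.get("id") or f"HOG{i + 1}"
            node = _parse_group(elem, catalogue, hog_id)
            if node is not None:
                forest.append(node)
    return forest, catalogue


def write_orthoxml(forest: list[HOGNode], catalogue: GeneCatalogue, stream: IO[str]) -> None:
    """Serialise a HOG forest back to OrthoXML (round-trips through
    :func:`parse_orthoxml` up to isomorphism)."""
    ET.register_namespace("", _NS)
    root = ET.Element(f"{{{_NS}}}orthoXML", {"version": "0.3", "origin": "qtlprio",
                                             "originVersion": "1"})
    by_species: dict[str, list[str]] = {}
    for internal, sp in catalogue.species.items():
        by_species.setdefault(sp, []).append(internal)
    for sp, internals in sorted(by_species.items()):
        sp_el = ET.SubElement(root, f"{{{_NS}}}species", {"name": sp, "NCBITaxId": "0"})
        db = ET.SubElement(sp_el, f"{{{_NS}}}database", {"name": "synthetic", "version": "1"})
        genes = ET.SubElement(db, f"{{{_NS}}}genes")
        for internal in internals:
            ET.SubElement(genes, f"{{{_NS}}}gene",
                          {"id": internal, "protId": catalogue.ext_id[internal]})
    ext_to_internal = {v: k for k, v in catalogue.ext_id.items()}
    groups = ET.SubElement(root, f"{{{_NS}}}groups")

    def emit(node: HOGNode, parent: ET.Element) -> None:
        if node.is_leaf:
            ET.SubElement(parent, f"{{{_NS}}}geneRef",
                          {"id": ext_to_internal[node.gene_id]})
            return
        tag = "orthologGroup" if node.kind == ORTHOLOG_GROUP else "paralogGroup"
        attrs = {}
        if node.hog_id and parent is groups:
            attrs["id"] = node.hog_id
        el = ET.SubElement(parent, f"{{{_NS}}}{tag}", attrs)
        for child in node.children:
            emit(child, el)

    for hog in forest:
        emit(hog, groups)
    ET.ElementTree(root).write(stream, encoding="unicode", xml_declaration=True)


def edge_factor(parent: HOGNode, decay: float, paralog_mode: str = "squared_decay") -> float:
    """Multiplier applied to a score crossing one edge below ``parent``.

    Ortholog edges decay once, ``(1-d)``; edges below a duplication node
    pay the paralogy penalty.  Under the default ``squared_decay`` the
    penalty is the decay applied twice, ``(1-d)**2``; ``doubled_rate``
    reads it as a doubled rate, ``1-2d`` (floored at 0).
    """
    if not 0.0 <= decay < 1.0:
        raise ValueError(f"decay must be in [0, 1), got {decay}")
    base = 1.0 - decay
    if parent.kind != PARALOG_GROUP:
        return base
    if paralog_mode == "squared_decay":
        return base * base
    if paralog_mode == "doubled_rate":
        return max(0.0, 1.0 - 2.0 * decay)
    raise ValueError(f"unknown paralog_mode {paralog_mode!r}")


def iter_nodes(node: HOGNode) -> Iterator[HOGNode]:
    """Pre-order iteration over a HOG subtree (iterative; deep trees safe)."""
    stack = [node]
    while stack:
        current = stack.pop()
        yield current
        stack.extend(reversed(current.children))


def leaf_genes(node: HOGNode) -> set[str]:
    """Gene ids of all gene_leaf descendants (including ``node`` itself)."""
    return {n.gene_id for n in iter_nodes(node) if n.is_leaf}
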