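"""OBO ontologies as is_a DAGs, with trait-term matching.

Annotation terms count toward a trait when the trait is mapped to the term
itself or to any of its is_a ancestors: an annotation to "galactose
biosynthetic process" is evidence for the more general "hexose biosynthetic
process" as well.  Only ``is_a`` edges are traversed by default; other
relationship types (``part_of``, ``regulates``, ...) are ignored, and ChEBI
is normally matched by exact accession only (see
:func:`term_counts_toward_trait`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "OntologyDAG",
    "OboParseError",
    "parse_obo",
    "ancestor_closure",
    "term_counts_toward_trait",
]


class OboParseError(ValueError):
    """Raised for a structurally invalid OBO file (cycles, dangling is_a)."""


@dataclass(frozen=True)
class Term:
    """A single ontology term (one ``[Term]`` stanza)."""

    id: str
    name: str = ""
    namespace: str = ""
    parents: frozenset[str] = field(default_factory=frozenset)
    alt_ids: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


class OntologyDAG:
    """An is_a DAG over :class:`Term` objects.

    Parameters
    ----------
    terms:
        Terms keyed by primary accession.

    Attributes
    ----------
    terms:
        Mapping accession -> :class:`Term`.
    alt_map:
        Mapping alternate accession -> canonical accession.
    graph:
        ``networkx.DiGraph`` with child -> parent edges (is_a only,
        non-obsolete terms).
    """

    def __init__(self, terms: dict[str, Term]):
        self.terms = terms
        self.alt_map: dict[str, str] = {}
        for term in terms.values():
            for alt in term.alt_ids:
                self.alt_map[alt] = term.id
        graph = nx.DiGraph()
        graph.add_nodes_from(terms)
        for term in terms.values():
            for parent in term.parents:
                if parent not in terms:
                    raise OboParseError(
                        f"is_a parent {parent!r} of {term.id!r} is never defined"
                    )
                graph.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OboParseError(f"cyclic is_a graph, e.g. {cycle}")
        self.graph = graph

    def resolve(self, accession: str) -> str | None:
        """Canonical accession for ``accession`` (following alt_ids), or None."""
        if accession in self.terms:
            return accession
        return self.alt_map.get(accession)

    def __contains__(self, accession: str) -> bool:
        return self.resolve(accession) is not None

    def __len__(self) -> int:
        return len(self.terms)


def _iter_stanzas(lines: Iterable[str]):
    """Yield (stanza_name, [tag-value lines]) from an OBO stream."""
    name = None
    body: list[str] = []
    for raw in lines:
        line = raw.split("!", 1)[0].rstrip() if not raw.startswith("!") else ""
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            if name is not None:
                yield name, body
            name, body = line[1:-1], []
        elif name is not None:
            body.append(line)
    if name is not None:
        yield name, body


def parse_obo(stream: IO[str] | Iterable[str]) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Only the tags needed for trait matching are read: ``id``, ``name``,
    ``namespace``, ``is_a``, ``alt_id`` and ``is_obsolete``.  Obsolete terms
    are kept (so annotations to them can be recognised and warned about) but
    carry no parents and never participate in closures.

    Raises
    ------
    OboParseError
        If a ``[Term]`` lacks an id, an ``is_a`` target is never defined, or
        the is_a graph is cyclic.
    """
    terms: dict[str, Term] = {}
    for stanza, body in _iter_stanzas(stream):
        if stanza != "Term":
            continue
        tid = ""
        name = ""
        namespace = ""
        parents: set[str] = set()
        alt_ids: set[str] = set()
        obsolete = False
        for line in body:
            tag, _, value = line.partition(":")
            value = value.strip()
            if tag == "id":
                tid = value
            elif tag == "name":
                name = value
            elif tag == "namespace":
                namespace = value
            elif tag == "is_a":
                parents.add(value.split()[0])
            elif tag == "alt_id":
                alt_ids.add(value)
            elif tag == "is_obsolete":
                obsolete = value.lower() == "true"
        if not tid:
            raise OboParseError("[Term] stanza without an id")
        if obsolete:
            parents = set()
        terms[tid] = Term(
            id=tid,
            name=name,
            namespace=namespace,
            parents=frozenset(parents),
            alt_ids=frozenset(alt_ids),
            obsolete=obsolete,
        )
    return OntologyDAG(terms)


def ancestor_closure(dag: OntologyDAG, term: str) -> frozenset[str]:
    """Reflexive transitive is_a closure of ``term`` (the term plus all
    ancestors), resolving alt_ids first.

    Raises
    ------
    KeyError
        If the accession (or an alt_id of it) is not in the DAG.
    ValueError
        If the term is obsolete.
    """
    canonical = dag.resolve(term)
    if canonical is None:
        raise KeyError(f"unknown ontology accession {term!r}")
    if dag.terms[canonical].obsolete:
        raise ValueError(f"term {canonical!r} is obsolete")
    return frozenset(nx.descendants(dag.graph, canonical)) | {canonical}


def term_counts_toward_trait(
    dag: OntologyDAG,
    annotation_term: str,
    mapped_terms: Iterable[str],
    use_closure: bool = True,
) -> bool:
    """Does an annotation to ``annotation_term`` count as evidence for a
    trait mapped to ``mapped_terms``?

    True iff the closure of the annotation term intersects the mapped set,
    i.e. the annotation is to a mapped term or a descendant of one.  With
    ``use_closure=False`` (the ChEBI default: only exact compound matches)
    only accession equality, after alt_id resolution, counts.

    Unknown and obsolete annotation terms return False with a warning —
    real annotation files routinely lag the ontology release.
    """
    mapped = set(mapped_terms)
    canonical = dag.resolve(annotation_term)
    if canonical is None:
        logger.warning("annotation term %s not in ontology; skipped", annotation_term)
        return False
    if dag.terms[canonical].obsolete:
        logger.warning("annotation term %s is obsolete; skipped", annotation_term)
        return False
    if not use_closure:
        return canonical in mapped or annotation_term in mapped
    # mapped accessions may themselves be alt_ids
    mapped_resolved = {dag.resolve(t) or t for t in mapped} | mapped
    return bool(ancestor_closure(dag, canonical) & mapped_resolved)
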