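"""GAF / ChEBI-xref annotation loading, evidence scoring and trait seeds.

Evidence policy: experimentally derived GO annotations start at score 1.0;
electronically inferred (IEA) annotations are accepted only through a
trusted allow-list, at 0.95; ChEBI cross-references count as direct
compound evidence at 1.0; everything else is dropped.  A gene supported by
several sources keeps the maximum of the initial scores.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .ontology import OntologyDAG, term_counts_toward_trait

logger = logging.getLogger(__name__)

__all__ = [
    "SOURCE_GOA",
    "SOURCE_CHEBI",
    "EXPERIMENTAL_CODES",
    "TRUSTED_IEA_REFERENCES",
    "Annotation",
    "TraitSeed",
    "EvidencePolicy",
    "GafParseError",
    "parse_gaf",
    "parse_chebi_xrefs",
    "parse_trait_map",
    "score_annotation",
    "build_trait_seeds",
]

SOURCE_GOA = "GOA"
SOURCE_CHEBI = "CHEBI"

# GO experimental evidence codes accepted at full score
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})

# Default trusted-IEA allow-list: UniProt keyword / EC / InterPro mapping
# pipelines, identified by their GO_REF. Configurable; real studies supply
# their own curated list.
TRUSTED_IEA_REFERENCES = frozenset(
    {"GO_REF:0000002", "GO_REF:0000003", "GO_REF:0000004", "GO_REF:0000037",
     "GO_REF:0000038", "GO_REF:0000041"}
)

_ACCESSION_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\S+$")


class GafParseError(ValueError):
    """Raised for a malformed GAF body row."""


@dataclass(frozen=True)
class Annotation:
    """One gene-to-term association with its provenance."""

    gene_id: str
    term: str
    evidence_code: str
    source: str = SOURCE_GOA
    qualifiers: tuple[str, ...] = ()
    reference: str = ""
    assigned_by: str = ""

    @property
    def negated(self) -> bool:
        return "NOT" in self.qualifiers


@dataclass(frozen=True)
class TraitSeed:
    """Initial per-gene score for one trait, before propagation."""

    gene_id: str
    trait_id: str
    initial_score: float

    def __post_init__(self) -> None:
        if not 0.0 < self.initial_score <= 1.0:
            raise ValueError(f"initial_score must be in (0, 1], got {self.initial_score}")


@dataclass
class EvidencePolicy:
    """Maps annotation evidence to an initial score, or drops it.

    ``trusted_references`` / ``trusted_assigned_by`` together form the
    allow-list predicate for IEA annotations: an IEA row is trusted when its
    DB:Reference or its Assigned_by column is listed.
    """

    experimental_codes: frozenset[str] = EXPERIMENTAL_CODES
    experimental_score: float = 1.0
    trusted_electronic_score: float = 0.95
    xref_score: float = 1.0
    trusted_references: frozenset[str] = TRUSTED_IEA_REFERENCES
    trusted_assigned_by: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for score in (self.experimental_score, self.trusted_electronic_score,
                      self.xref_score):
            if not 0.0 < score <= 1.0:
                raise ValueError(f"evidence scores must be in (0, 1], got {score}")

    def is_trusted_electronic(self, annotation: Annotation) -> bool:
        return annotation.evidence_code == "IEA" and (
            annotation.reference in self.trusted_references
            or annotation.assigned_by in self.trusted_assigned_by
        )


def score_annotation(annotation: Annotation, policy: EvidencePolicy) -> float | None:
    """Initial score for an annotation, or ``None`` when it is dropped.

    Experimental -> 1.0; trusted IEA -> 0.95; ChEBI xref -> 1.0; anything
    else (untrusted IEA, ISS, ND, ...) is default-deny.
    """
    if annotation.negated:
        return None
    if annotation.source == SOURCE_CHEBI:
        return policy.xref_score
    if annotation.evidence_code in policy.experimental_codes:
        return policy.experimental_score
    if policy.is_trusted_electronic(annotation):
        return policy.trusted_electronic_score
    return None


def parse_gaf(stream: IO[str] | Iterable[str]) -> list[Annotation]:
    """Parse GAF 2.x rows into :class:`Annotation` objects.

    ``!``-comment lines are skipped; rows with fewer than 15 tab-separated
    columns (the GAF 2.x mandatory body; 2.1/2.2 pad to 17) are fatal.
    NOT-qualified rows are excluded here: negative evidence must never seed
    a positive trait score.
    """
    out: list[Annotation] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise GafParseError(
                f"GAF line {lineno}: expected >=15 tab-separated columns, got {len(cols)}"
            )
        qualifiers = tuple(q for q in cols[3].split("|") if q)
        annotation = Annotation(
            gene_id=cols[1],
            term=cols[4],
            evidence_code=cols[6],
            source=SOURCE_GOA,
            qualifiers=qualifiers,
            reference=cols[5],
            assigned_by=cols[14] if len(cols) > 14 else "",
        )
        if annotation.negated:
            continue
        out.append(annotation)
    return out


def parse_chebi_xrefs(stream: IO[str] | Iterable[str]) -> list[Annotation]:
    """Parse a two-column TSV of (gene/protein id, ChEBI accession) into
    CHEBI-source annotations with the synthetic evidence code ``XREF``.

    Malformed accessions are skipped with a warning; duplicate rows are
    deduplicated.
    """
    seen: set[tuple[str, str]] = set()
    out: list[Annotation] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2 or not cols[0] or not _ACCESSION_RE.match(cols[1]):
            logger.warning("chebi xref line %d malformed; skipped: %r", lineno, line)
            continue
        key = (cols[0], cols[1])
        if key in seen:
            continue
        seen.add(key)
        out.append(Annotation(gene_id=cols[0], term=cols[1],
                              evidence_code="XREF", source=SOURCE_CHEBI))
    return out


def parse_trait_map(stream: IO[str] | Iterable[str]) -> dict[str, dict[str, set[str]]]:
    """Parse the trait->term mapping TSV.

    Columns: trait_id, term accession, optional source (GOA/CHEBI).  When
    the source column is absent it is inferred from the accession prefix
    (``CHEBI:`` -> CHEBI, anything else -> GOA).

    Returns ``{trait_id: {source: {accessions}}}``.
    """
    mapping: dict[str, dict[str, set[str]]] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#") or line.lower().startswith("trait_id\t"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            logger.warning("trait map row skipped (need >=2 columns): %r", line)
            continue
        trait, term = cols[0], cols[1]
        source = cols[2].upper() if len(cols) > 2 and cols[2] else (
            SOURCE_CHEBI if term.startswith("CHEBI:") else SOURCE_GOA
        )
        mapping.setdefault(trait, {}).setdefault(source, set()).add(term)
    return mapping


def build_trait_seeds(
    annotations: Iterable[Annotation],
    trait_map: Mapping[str, Mapping[str, set[str]]],
    dags: Mapping[str, OntologyDAG],
    policy: EvidencePolicy | None = None,
    closure_by_source: Mapping[str, bool] | None = None,
) -> dict[str, dict[str, float]]:
    """Reduce annotations to per-trait per-gene seed scores.

    An annotation contributes to a trait iff its term counts toward one of
    the trait's mapped terms in the matching ontology (GO via is_a closure,
    ChEBI by exact accession, unless overridden in ``closure_by_source``).
    Per (gene, trait) the seed is the **maximum** score over contributing
    annotations, so input order is immaterial and extra evidence can never
    lower a seed.

    Returns ``{trait_id: {gene_id: seed}}``; traits with no mapped terms
    are omitted with a warning.
    """
    policy = policy or EvidencePolicy()
    closure_by_source = dict(closure_by_source or {SOURCE_GOA: True, SOURCE_CHEBI: False})
    seeds: dict[str, dict[str, float]] = {}
    scored = [(a, s) for a in annotations
              if (s := score_annotation(a, policy)) is not None]
    for trait, by_source in trait_map.items():
        if not any(by_source.values()):
            logger.warning("trait %s has zero mapped terms; omitted", trait)
            continue
        per_gene: dict[str, float] = {}
        for annotation, score in scored:
            mapped = by_source.get(annotation.source)
            if not mapped:
                continue
            dag = dags.get(annotation.source)
            if dag is None:
                continue
            if term_counts_toward_trait(
                dag, annotation.term, mapped,
                use_closure=closure_by_source.get(annotation.source, True),
            ):
                prev = per_gene.get(annotation.gene_id, 0.0)
                if score > prev:
                    per_gene[annotation.gene_id] = score
        seeds[trait] = per_gene
    return seeds
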