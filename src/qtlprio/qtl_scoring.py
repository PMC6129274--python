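"""QTL member genes, uniform initial scores and score increases.

A QTL is an interval (chromosome, start, end) tied to a trait.  Its member
set Q contains every gene overlapping the interval even partially, under
strict inequalities: gene g is a member iff ``s < g.end and e > g.start``.
Each member starts at the uniform score S0 = 1/|Q| — the flat prior that a
single causal gene explains the QTL — which is combined with any
annotation-derived trait seed by taking the maximum.  After propagation
through the HOG forest each member's score increase

    dS = S1 - 1/|Q|

is the ranking statistic: how much more the gene looks trait-associated
than the flat prior, thanks to direct annotation or annotated homologs.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd

from .orthology import HOGNode, iter_nodes
from .propagation import PropagationParams, propagate

logger = logging.getLogger(__name__)

__all__ = [
    "GeneLocus",
    "QTL",
    "CandidateScore",
    "GeneIndex",
    "load_gene_loci",
    "load_qtl_table",
    "genes_in_qtl",
    "initial_qtl_scores",
    "score_qtl",
    "gene_to_tree_map",
]


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position: 1-based inclusive coordinates plus its rank
    (1-based) among the genes of its chromosome, ordered by start."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    index: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class QTL:
    """A trait-linked genomic interval (1-based, start < end)."""

    qtl_id: str
    trait_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"QTL {self.qtl_id}: start must be < end")


@dataclass(frozen=True)
class CandidateScore:
    """One QTL member's scores: uniform S0 = 1/|Q|, post-propagation S1,
    and the increase delta = S1 - S0 (>= 0 under the max-down rule)."""

    gene_id: str
    S0: float
    S1: float

    @property
    def delta(self) -> float:
        return self.S1 - self.S0


class GeneIndex:
    """Per-chromosome ordered gene lists with O(1) id lookup."""

    def __init__(self, by_chromosome: Mapping[str, list[GeneLocus]]):
        self.by_chromosome = dict(by_chromosome)
        self.by_id = {
            locus.gene_id: locus
            for loci in self.by_chromosome.values()
            for locus in loci
        }

    @property
    def n_genes(self) -> int:
        return len(self.by_id)

    def chromosomes(self) -> list[str]:
        return sorted(self.by_chromosome)


_GFF_ID_RE = re.compile(r"ID=(?:gene:)?([^;]+)")
_GFF_NAME_RE = re.compile(r"Name=([^;]+)")

_GFF_COLUMNS = ["seqid", "source", "type", "start", "end",
                "score", "strand", "phase", "attributes"]


def _index_loci(raw: list[GeneLocus]) -> GeneIndex:
    by_chromosome: dict[str, list[GeneLocus]] = {}
    for locus in sorted(raw, key=lambda g: (g.chromosome, g.start, g.end, g.gene_id)):
        chrom = by_chromosome.setdefault(locus.chromosome, [])
        chrom.append(GeneLocus(locus.gene_id, locus.chromosome,
                               locus.start, locus.end, index=len(chrom) + 1))
    return GeneIndex(by_chromosome)


def load_gene_loci(path_or_stream: str | IO[str], fmt: str | None = None) -> GeneIndex:
    """Load gene coordinates from GFF3 (``type == gene`` rows) or BED.

    BED's half-open 0-based intervals are converted to 1-based inclusive.
    ``fmt`` is "gff3" or "bed"; inferred from the filename when omitted.
    """
    if fmt is None:
        name = getattr(path_or_stream, "name", str(path_or_stream)).lower()
        fmt = "bed" if name.endswith(".bed") else "gff3"
    raw: list[GeneLocus] = []
    if fmt == "gff3":
        frame = pd.read_csv(path_or_stream, sep="\t", comment="#", header=None,
                            names=_GFF_COLUMNS, dtype=str)
        genes = frame[frame["type"] == "gene"]
        for _, row in genes.iterrows():
            attrs = row["attributes"] or ""
            match = _GFF_ID_RE.search(attrs) or _GFF_NAME_RE.search(attrs)
            gene_id = match.group(1) if match else f"{row['seqid']}:{row['start']}"
            raw.append(GeneLocus(gene_id, row["seqid"], int(row["start"]), int(row["end"])))
    elif fmt == "bed":
        frame = pd.read_csv(path_or_stream, sep="\t", comment="#", header=None, dtype=str)
        for i, row in frame.iterrows():
            gene_id = row[3] if len(row) > 3 and pd.notna(row[3]) else f"{row[0]}:{row[1]}"
            # BED: 0-based half-open -> 1-based inclusive
            raw.append(GeneLocus(gene_id, row[0], int(row[1]) + 1, int(row[2])))
    else:
        raise ValueError(f"unknown gene coordinate format {fmt!r}")
    return _index_loci(raw)


def load_qtl_table(path_or_stream: str | IO[str]) -> list[QTL]:
    """Load the QTL TSV (qtl_id, trait_id, chromosome, start, end); a
    header row naming the first column ``qtl_id`` is tolerated."""
    frame = pd.read_csv(path_or_stream, sep="\t", comment="#", header=None,
                        names=["qtl_id", "trait_id", "chromosome", "start", "end"],
                        dtype=str)
    frame = frame[frame["qtl_id"].str.lower() != "qtl_id"]
    return [
        QTL(row.qtl_id, row.trait_id, row.chromosome, int(row.start), int(row.end))
        for row in frame.itertuples()
    ]


def genes_in_qtl(index: GeneIndex, chromosome: str, s: int, e: int) -> list[GeneLocus]:
    """Member genes Q of the interval (s, e): ordered genes with
    ``s < gene.end and e > gene.start`` — partial overlap counts, but a
    gene touching only the boundary does not (strict inequalities)."""
    if s >= e:
        raise ValueError("QTL start must be < end")
    if chromosome not in index.by_chromosome:
        raise KeyError(f"unknown chromosome {chromosome!r}")
    return [g for g in index.by_chromosome[chromosome] if s < g.end and e > g.start]


def initial_qtl_scores(members: list[GeneLocus]) -> dict[str, float]:
    """Uniform initial scores S0 = 1/|Q| for every member gene."""
    if not members:
        raise ValueError("no genes in interval")
    s0 = 1.0 / len(members)
    return {g.gene_id: s0 for g in members}


def gene_to_tree_map(forest: Iterable[HOGNode]) -> dict[str, HOGNode]:
    """Map each gene id to its root HOG (a gene is in at most one HOG)."""
    mapping: dict[str, HOGNode] = {}
    for tree in forest:
        for node in iter_nodes(tree):
            if node.is_leaf:
                if node.gene_id in mapping and mapping[node.gene_id] is not tree:
                    raise ValueError(f"gene {node.gene_id!r} appears in two HOGs")
                mapping[node.gene_id] = tree
    return mapping


def score_qtl(
    qtl: QTL,
    index: GeneIndex,
    trait_seeds: Mapping[str, float],
    forest: Iterable[HOGNode] | Mapping[str, HOGNode],
    params: PropagationParams | None = None,
) -> list[CandidateScore]:
    """Score one QTL in isolation.

    Every member leaf is seeded with ``max(1/|Q|, trait seed)``; non-member
    genes keep their trait seeds; the forest is propagated; members are
    returned sorted by delta descending (ties: genomic position, then
    gene id).

    ``trait_seeds`` maps gene_id -> annotation-derived seed for the QTL's
    trait.  ``forest`` may be a list of root HOGs or a prebuilt
    ``gene_to_tree_map`` result (cheaper when scoring many pseudo-QTL).

    Raises
    ------
    ValueError
        If the interval contains no genes.
    """
    members = genes_in_qtl(index, qtl.chromosome, qtl.start, qtl.end)
    return score_member_genes(members, trait_seeds, forest, params)


def score_member_genes(
    members: list[GeneLocus],
    trait_seeds: Mapping[str, float],
    forest: Iterable[HOGNode] | Mapping[str, HOGNode],
    params: PropagationParams | None = None,
) -> list[CandidateScore]:
    """Score an explicit member-gene list (the engine behind
    :func:`score_qtl`, also used on resampled pseudo-QTL windows)."""
    params = params or PropagationParams()
    s0_scores = initial_qtl_scores(members)
    s0 = 1.0 / len(members)

    seeds = dict(trait_seeds)
    for gene_id in s0_scores:
        seeds[gene_id] = max(s0, seeds.get(gene_id, 0.0))

    # only trees containing a member can change a member's final score
    gene_to_tree = forest if isinstance(forest, Mapping) else gene_to_tree_map(forest)
    member_ids = set(s0_scores)
    trees = []
    seen: set[int] = set()
    for gene_id in member_ids:
        tree = gene_to_tree.get(gene_id)
        if tree is not None and id(tree) not in seen:
            seen.add(id(tree))
            trees.append(tree)
    finals = propagate(trees, seeds, params, genes_of_interest=member_ids)

    scores = [
        CandidateScore(g.gene_id, S0=s0, S1=finals.get(g.gene_id, seeds[g.gene_id]))
        for g in members
    ]
    position = {g.gene_id: (g.chromosome, g.start, g.gene_id) for g in members}
    scores.sort(key=lambda c: (-c.delta, position[c.gene_id]))
    return scores
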