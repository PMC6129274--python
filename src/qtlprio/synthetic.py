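"""Self-consistent synthetic study fixtures.

Generates a toy multi-species world — genome coordinates, a HOG forest
with controlled duplication, a small GO-like ontology plus a ChEBI slice,
GAF / xref annotations, a trait map and a QTL table — written in the real
file formats so every reader in the package is exercised end to end.

Two modes matter scientifically:

* ``planted_causal=True`` (default): each QTL has one designated causal
  member gene whose cross-species ortholog (never the member itself)
  carries a trait annotation.  Background annotations are placed only on
  genes whose HOGs contain no designated member, so the planted signal is
  identifiable by construction and recovery can be asserted.
* ``planted_causal=False``: a fully null world — annotations land
  uniformly at random, QTL are placed independently — used to check that
  empirical p-values are conservative.

All outputs are deterministic functions of ``rng_seed``.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .orthology import (GENE_LEAF, ORTHOLOG_GROUP, PARALOG_GROUP, GeneCatalogue,
                        HOGNode, write_orthoxml)
from .qtl_scoring import GeneIndex, GeneLocus

__all__ = ["FixtureSpec", "StudyFiles", "gen_genome", "gen_hog_forest",
           "gen_annotations", "gen_qtl_study", "gen_study", "write_study"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic world.

    Defaults encode the reference recovery scenario: 3 species, two
    100-gene chromosomes, 20% duplication probability, one trait, QTL of
    20 genes with a planted causal gene each.
    """

    n_species: int = 3
    genes_per_chromosome: tuple[int, ...] = (100, 100)
    duplication_probability: float = 0.2
    n_traits: int = 1
    seeds_per_trait: int = 5
    fraction_experimental: float = 0.7
    qtl_count: int = 4
    qtl_gene_count: tuple[int, int] = (20, 20)
    planted_causal: bool = True
    fraction_chebi: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.duplication_probability, self.fraction_experimental,
                  self.fraction_chebi):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.n_species < 1 or self.n_traits < 1 or self.qtl_count < 0:
            raise ValueError("counts must be >= 1 (qtl_count >= 0)")
        if not self.genes_per_chromosome or min(self.genes_per_chromosome) < 1:
            raise ValueError("need at least one gene per chromosome")


@dataclass
class StudyFiles:
    """The complete in-memory study (text per format + parsed helpers)."""

    gff3: str
    orthoxml: str
    go_obo: str
    chebi_obo: str
    gaf: str
    chebi_xrefs: str
    trait_map: str
    qtl_table: str
    index: GeneIndex
    planted: dict[str, str] = field(default_factory=dict)  # qtl_id -> causal gene
    qtl_members: dict[str, list[str]] = field(default_factory=dict)


def _gene_id(species: int, chrom: int, pos: int) -> str:
    return f"SP{species}C{chrom}G{pos:04d}"


def gen_genome(spec: FixtureSpec, rng: np.random.Generator) -> tuple[GeneIndex, str]:
    """Study-species gene loci (non-overlapping, ordered) plus GFF3 text."""
    lines = ["##gff-version 3"]
    by_chrom: dict[str, list[GeneLocus]] = {}
    for c, n_genes in enumerate(spec.genes_per_chromosome, start=1):
        chrom = f"chr{c}"
        loci: list[GeneLocus] = []
        cursor = 1
        for i in range(1, n_genes + 1):
            cursor += int(rng.integers(100, 1000))  # intergenic gap
            length = int(rng.integers(500, 3000))
            gene = _gene_id(0, c, i)
            loci.append(GeneLocus(gene, chrom, cursor, cursor + length - 1, index=i))
            lines.append("\t".join([chrom, "synth", "gene", str(cursor),
                                    str(cursor + length - 1), ".", "+", ".",
                                    f"ID=gene:{gene};Name={gene}"]))
            cursor += length
        by_chrom[chrom] = loci
    return GeneIndex(by_chrom), "\n".join(lines) + "\n"


def _random_species_tree(species_leaves: list[HOGNode], p_dup: float,
                         rng: np.random.Generator, hog_id: str) -> HOGNode:
    """Random binary merge of the species' leaves; the root is always an
    ortholog group, inner merges are duplications with probability p_dup."""
    nodes = list(species_leaves)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        kind = PARALOG_GROUP if rng.random() < p_dup else ORTHOLOG_GROUP
        nodes.append(HOGNode(kind, children=[left, right], hog_id=hog_id))
    if len(nodes) == 1:
        return nodes[0]
    return HOGNode(ORTHOLOG_GROUP, children=nodes, hog_id=hog_id)


def gen_hog_forest(spec: FixtureSpec, rng: np.random.Generator
                   ) -> tuple[list[HOGNode], GeneCatalogue, str]:
    """One HOG per genome position, grouping that position's orthologs
    across all species; duplication nodes appear with the configured
    probability.  Returns the forest, catalogue and OrthoXML text."""
    catalogue = GeneCatalogue()
    internal = 0
    forest: list[HOGNode] = []
    hog_n = 0
    for c, n_genes in enumerate(spec.genes_per_chromosome, start=1):
        for i in range(1, n_genes + 1):
            hog_n += 1
            hog_id = f"HOG:{hog_n:06d}"
            leaves = []
            for s in range(spec.n_species):
                internal += 1
                gene = _gene_id(s, c, i)
                catalogue.add(str(internal), gene, f"species{s}")
                leaves.append(HOGNode(GENE_LEAF, gene_id=gene, hog_id=hog_id))
            if spec.n_species == 1:
                forest.append(HOGNode(ORTHOLOG_GROUP, children=leaves, hog_id=hog_id))
            else:
                tree = _random_species_tree(leaves, spec.duplication_probability,
                                            rng, hog_id)
                if tree.is_leaf:
                    tree = HOGNode(ORTHOLOG_GROUP, children=[tree], hog_id=hog_id)
                forest.append(tree)
    buf = io.StringIO()
    write_orthoxml(forest, catalogue, buf)
    return forest, catalogue, buf.getvalue()


def _trait_terms(t: int) -> dict[str, str]:
    base = 900000 + t * 100
    return {
        "go_leaf": f"GO:{base + 1:07d}",
        "go_mid": f"GO:{base + 2:07d}",
        "go_root": f"GO:{base + 3:07d}",
        "chebi": f"CHEBI:{90000 + t}",
    }


def _build_obo(header: str, stanzas: list[str]) -> str:
    return f"format-version: 1.2\nontology: {header}\n\n" + "\n\n".join(stanzas) + "\n"


def gen_annotations(
    spec: FixtureSpec,
    forest: list[HOGNode],
    index: GeneIndex,
    planted: dict[str, str],
    rng: np.random.Generator,
    qtl_members: dict[str, list[str]] | None = None,
) -> tuple[str, str, str, str, str]:
    """OBO (GO + ChEBI), GAF, xref TSV and trait-map TSV text.

    Each trait gets a 3-term is_a chain (leaf -> mid -> root) in the GO
    slice plus one ChEBI compound; the trait maps to the *mid* GO term (so
    annotations to the leaf only count through the closure) and to the
    ChEBI compound exactly.  Planted causal annotations go to a
    cross-species HOG co-member of each designated QTL member; background
    annotations avoid every designated member's HOG.
    """
    go_stanzas, chebi_stanzas, trait_rows = [], [], []
    traits = [f"trait{t + 1}" for t in range(spec.n_traits)]
    for t, trait in enumerate(traits):
        terms = _trait_terms(t)
        go_stanzas += [
            f"[Term]\nid: {terms['go_root']}\nname: {trait} root process",
            f"[Term]\nid: {terms['go_mid']}\nname: {trait} process\n"
            f"is_a: {terms['go_root']} ! {trait} root process",
            f"[Term]\nid: {terms['go_leaf']}\nname: {trait} biosynthetic process\n"
            f"is_a: {terms['go_mid']} ! {trait} process",
        ]
        chebi_stanzas.append(
            f"[Term]\nid: {terms['chebi']}\nname: {trait} compound")
        trait_rows += [f"{trait}\t{terms['go_mid']}\tGOA",
                       f"{trait}\t{terms['chebi']}\tCHEBI"]

    # in planted mode background noise must stay out of the tested windows:
    # any HOG holding a QTL member gene is off-limits
    from .orthology import leaf_genes
    from .qtl_scoring import gene_to_tree_map

    gene_to_tree = gene_to_tree_map(forest)
    protected: set[str] = set()
    if spec.planted_causal:
        shielded = set(planted.values())
        for members in (qtl_members or {}).values():
            shielded |= set(members)
        for member in shielded:
            tree = gene_to_tree.get(member)
            if tree is not None:
                protected |= leaf_genes(tree)

    all_genes = sorted(gene_to_tree)
    gaf_rows: list[str] = []
    xref_rows: list[str] = []

    def annotate(gene: str, t: int) -> None:
        terms = _trait_terms(t)
        if rng.random() < spec.fraction_chebi:
            xref_rows.append(f"{gene}\t{terms['chebi']}")
            return
        if rng.random() < spec.fraction_experimental:
            evidence, ref, assigned = "IDA", "PMID:1", "SynthDB"
        else:
            evidence, ref, assigned = "IEA", "GO_REF:0000002", "UniProt"
        gaf_rows.append("\t".join([
            "SynthDB", gene, gene, "", terms["go_leaf"], ref, evidence, "",
            "P", "", "", "protein", "taxon:0000", "20260101", assigned, "", "",
        ]))

    for t, trait in enumerate(traits):
        if spec.planted_causal:
            for member in planted.values():
                tree = gene_to_tree.get(member)
                if tree is None:
                    continue
                homologs = sorted(g for g in leaf_genes(tree) if g != member
                                  and not g.startswith("SP0"))
                if homologs:
                    annotate(homologs[int(rng.integers(0, len(homologs)))], t)
        pool = [g for g in all_genes if g not in protected]
        if spec.seeds_per_trait and pool:
            picks = rng.choice(len(pool), size=min(spec.seeds_per_trait, len(pool)),
                               replace=False)
            for p in sorted(picks):
                annotate(pool[int(p)], t)

    gaf = "!gaf-version: 2.2\n" + ("\n".join(gaf_rows) + "\n" if gaf_rows else "")
    xrefs = ("\n".join(xref_rows) + "\n") if xref_rows else ""
    trait_map = "\n".join(trait_rows) + "\n"
    return (_build_obo("go-syngoverned", go_stanzas),
            _build_obo("chebi-synth", chebi_stanzas),
            gaf, xrefs, trait_map)


def gen_qtl_study(spec: FixtureSpec, index: GeneIndex, rng: np.random.Generator
                  ) -> tuple[str, dict[str, str], dict[str, list[str]]]:
    """QTL TSV text plus the designated causal member per QTL.

    Each interval is drawn to contain exactly the requested number of
    consecutive genes (boundaries placed between neighbouring genes so the
    strict-overlap rule keeps exactly that window).
    """
    lo, hi = spec.qtl_gene_count
    if lo > hi or lo < 1:
        raise ValueError("invalid qtl_gene_count range")
    chroms = [(c, loci) for c, loci in sorted(index.by_chromosome.items())]
    rows = []
    planted: dict[str, str] = {}
    qtl_members: dict[str, list[str]] = {}
    taken: dict[str, set[int]] = {}
    traits = [f"trait{t + 1}" for t in range(spec.n_traits)]
    for q in range(spec.qtl_count):
        k = int(rng.integers(lo, hi + 1))
        eligible = [(c, loci) for c, loci in chroms if len(loci) >= k]
        if not eligible:
            raise ValueError(f"requested QTL gene count {k} exceeds every chromosome")
        counts = np.array([len(l) for _, l in eligible], dtype=float)
        for attempt in range(1000):
            chrom, loci = eligible[int(rng.choice(len(eligible),
                                                  p=counts / counts.sum()))]
            start_i = int(rng.integers(0, len(loci) - k + 1))
            ranks = set(range(start_i, start_i + k))
            # planted worlds keep the tested windows gene-disjoint so each
            # causal signal is identifiable; null worlds place independently
            if not spec.planted_causal or not (ranks & taken.get(chrom, set())):
                taken.setdefault(chrom, set()).update(ranks)
                break
        else:
            raise ValueError("could not place gene-disjoint QTL windows")
        window = loci[start_i:start_i + k]
        s = window[0].start - 1 if start_i == 0 else loci[start_i - 1].end
        e = window[-1].end + 1 if start_i + k == len(loci) else loci[start_i + k].start
        qtl_id = f"QTL{q + 1}"
        trait = traits[q % len(traits)]
        rows.append(f"{qtl_id}\t{trait}\t{chrom}\t{s}\t{e}")
        planted[qtl_id] = window[int(rng.integers(0, k))].gene_id
        qtl_members[qtl_id] = [g.gene_id for g in window]
    table = "qtl_id\ttrait_id\tchromosome\tstart\tend\n" + \
        ("\n".join(rows) + "\n" if rows else "")
    return table, planted, qtl_members


def gen_study(spec: FixtureSpec | None = None, rng_seed: int | None = None) -> StudyFiles:
    """Generate the complete study in memory (deterministic per seed)."""
    spec = spec or FixtureSpec()
    if rng_seed is not None:
        spec = replace(spec, rng_seed=rng_seed)
    rng = np.random.default_rng(spec.rng_seed)
    index, gff3 = gen_genome(spec, rng)
    forest, _catalogue, orthoxml = gen_hog_forest(spec, rng)
    qtl_table, planted, qtl_members = gen_qtl_study(spec, index, rng)
    go_obo, chebi_obo, gaf, xrefs, trait_map = gen_annotations(
        spec, forest, index, planted, rng, qtl_members)
    return StudyFiles(gff3=gff3, orthoxml=orthoxml, go_obo=go_obo,
                      chebi_obo=chebi_obo, gaf=gaf, chebi_xrefs=xrefs,
                      trait_map=trait_map, qtl_table=qtl_table,
                      index=index, planted=planted, qtl_members=qtl_members)


_FILENAMES = {
    "gff3": "genome.gff3",
    "orthoxml": "hogs.orthoxml",
    "go_obo": "go.obo",
    "chebi_obo": "chebi.obo",
    "gaf": "annotations.gaf",
    "chebi_xrefs": "chebi_xrefs.tsv",
    "trait_map": "trait_map.tsv",
    "qtl_table": "qtl.tsv",
}


def write_study(study: StudyFiles, outdir: str | Path) -> dict[str, Path]:
    """Write every study file to ``outdir`` in its real format; returns the
    path per logical name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for attr, filename in _FILENAMES.items():
        path = outdir / filename
        path.write_text(getattr(study, attr))
        paths[attr] = path
    return paths
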