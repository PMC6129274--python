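import io

import numpy as np
import pytest

from qtlprio.orthology import GENE_LEAF, ORTHOLOG_GROUP, PARALOG_GROUP, HOGNode
from qtlprio.qtl_scoring import GeneIndex, GeneLocus

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000004
name: top

[Term]
id: GO:0000002
name: left
is_a: GO:0000004 ! top

[Term]
id: GO:0000003
name: right
is_a: GO:0000004 ! top

[Term]
id: GO:0000001
name: bottom
alt_id: GO:0999999
is_a: GO:0000002 ! left
is_a: GO:0000003 ! right

[Term]
id: GO:0000005
name: sibling
is_a: GO:0000002 ! left

[Term]
id: GO:0000006
name: gone
is_obsolete: true
"""

ORTHOXML_SMALL = """<?xml version="1.0"?>
<orthoXML xmlns="http://orthoXML.org/2011/" version="0.3" origin="test" originVersion="1">
  <species name="spA" NCBITaxId="1">
    <database name="db" version="1"><genes>
      <gene id="1" protId="A"/>
      <gene id="2" protId="B"/>
    </genes></database>
  </species>
  <species name="spB" NCBITaxId="2">
    <database name="db" version="1"><genes>
      <gene id="3" protId="C"/>
    </genes></database>
  </species>
  <groups>
    <orthologGroup id="HOG:1">
      <geneRef id="1"/>
      <paralogGroup>
        <geneRef id="2"/>
        <geneRef id="3"/>
      </paralogGroup>
    </orthologGroup>
  </groups>
</orthoXML>
"""


@pytest.fixture
def diamond_dag():
    from qtlprio.ontology import parse_obo

    return parse_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture
def small_forest():
    """root{A(leaf), P=paralog{B, C}} — the canonical hand-trace tree."""
    leaf_a = HOGNode(GENE_LEAF, gene_id="A")
    leaf_b = HOGNode(GENE_LEAF, gene_id="B")
    leaf_c = HOGNode(GENE_LEAF, gene_id="C")
    paralog = HOGNode(PARALOG_GROUP, children=[leaf_b, leaf_c])
    root = HOGNode(ORTHOLOG_GROUP, children=[leaf_a, paralog], hog_id="HOG:1")
    return [root]


def make_index(n_per_chrom, gene_length=100, gap=50):
    """Deterministic gene index: genes of fixed length separated by a gap."""
    by_chrom = {}
    for c, n in enumerate(n_per_chrom, start=1):
        chrom = f"chr{c}"
        loci = []
        pos = 1
        for i in range(1, n + 1):
            loci.append(GeneLocus(f"{chrom}g{i}", chrom, pos, pos + gene_length - 1, i))
            pos += gene_length + gap
        by_chrom[chrom] = loci
    return GeneIndex(by_chrom)


@pytest.fixture
def two_chrom_index():
    return make_index([10, 5])


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
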