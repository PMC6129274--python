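import io
import random

import pytest

from qtlprio.annotations import (Annotation, EvidencePolicy, GafParseError,
                                 SOURCE_CHEBI, SOURCE_GOA, TraitSeed,
                                 build_trait_seeds, parse_chebi_xrefs,
                                 parse_gaf, parse_trait_map, score_annotation)
from qtlprio.ontology import parse_obo

from conftest import DIAMOND_OBO


def gaf_row(gene="G1", term="GO:0000001", evidence="IDA", qualifier="",
            ref="PMID:1", assigned="UniProt"):
    cols = ["DB", gene, gene, qualifier, term, ref, evidence, "", "P", "", "",
            "protein", "taxon:1", "20180201", assigned, "", ""]
    return "\t".join(cols)


def gaf_text(*rows):
    return "!gaf-version: 2.1\n" + "".join(r + "\n" for r in rows)


class TestParseGaf:
    def test_single_row(self):
        anns = parse_gaf(io.StringIO(gaf_text(gaf_row())))
        assert len(anns) == 1
        a = anns[0]
        assert (a.gene_id, a.term, a.evidence_code, a.source) == (
            "G1", "GO:0000001", "IDA", SOURCE_GOA)

    def test_not_qualifier_excluded(self):
        text = gaf_text(gaf_row(qualifier="NOT|involved_in"), gaf_row(gene="G2"))
        anns = parse_gaf(io.StringIO(text))
        assert [a.gene_id for a in anns] == ["G2"]

    def test_comment_only_file(self):
        assert parse_gaf(io.StringIO("!gaf-version: 2.1\n! more\n")) == []

    def test_wrong_column_count_fatal_with_line(self):
        with pytest.raises(GafParseError, match="line 2"):
            parse_gaf(io.StringIO("!header\nDB\tG1\tonly-three\n"))


class TestParseChebiXrefs:
    def test_basic_row(self):
        anns = parse_chebi_xrefs(io.StringIO("G1\tCHEBI:28260\n"))
        assert len(anns) == 1
        assert anns[0].source == SOURCE_CHEBI
        assert anns[0].evidence_code == "XREF"
        assert anns[0].term == "CHEBI:28260"

    def test_empty_file(self):
        assert parse_chebi_xrefs(io.StringIO("")) == []

    def test_duplicates_collapsed_and_malformed_skipped(self, caplog):
        text = "G1\tCHEBI:1\nG1\tCHEBI:1\nG2\tnot an accession\n"
        anns = parse_chebi_xrefs(io.StringIO(text))
        assert len(anns) == 1
        assert "skipped" in caplog.text


class TestScoreAnnotation:
    policy = EvidencePolicy()

    @pytest.mark.parametrize("evidence,expected", [
        ("IDA", 1.0), ("EXP", 1.0), ("IMP", 1.0),
        ("ISS", None), ("ND", None),
    ])
    def test_go_evidence(self, evidence, expected):
        a = Annotation("G1", "GO:1", evidence, reference="PMID:1")
        assert score_annotation(a, self.policy) == expected

    def test_trusted_iea(self):
        trusted = Annotation("G1", "GO:1", "IEA", reference="GO_REF:0000002")
        untrusted = Annotation("G1", "GO:1", "IEA", reference="GO_REF:9999999")
        assert score_annotation(trusted, self.policy) == 0.95
        assert score_annotation(untrusted, self.policy) is None

    def test_chebi_xref_full_score(self):
        a = Annotation("G1", "CHEBI:28260", "XREF", source=SOURCE_CHEBI)
        assert score_annotation(a, self.policy) == 1.0

    def test_negated_dropped(self):
        a = Annotation("G1", "GO:1", "IDA", qualifiers=("NOT",))
        assert score_annotation(a, self.policy) is None

    def test_policy_rejects_out_of_range_scores(self):
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                EvidencePolicy(experimental_score=bad)


def test_trait_seed_range_enforced():
    with pytest.raises(ValueError):
        TraitSeed("G1", "t", 0.0)
    with pytest.raises(ValueError):
        TraitSeed("G1", "t", 1.2)


class TestBuildTraitSeeds:
    @pytest.fixture
    def dags(self, diamond_dag):
        chebi = parse_obo(io.StringIO("[Term]\nid: CHEBI:28260\nname: galactose\n"))
        return {SOURCE_GOA: diamond_dag, SOURCE_CHEBI: chebi}

    trait_map = {"galactose": {SOURCE_GOA: {"GO:0000002"}, SOURCE_CHEBI: {"CHEBI:28260"}}}

    def test_max_over_sources(self, dags):
        anns = [
            Annotation("G1", "GO:0000001", "IDA", reference="PMID:1"),
            Annotation("G1", "GO:0000001", "IEA", reference="GO_REF:0000002"),
        ]
        seeds = build_trait_seeds(anns, self.trait_map, dags)
        assert seeds["galactose"]["G1"] == 1.0

    def test_trusted_iea_alone(self, dags):
        anns = [Annotation("G1", "GO:0000001", "IEA", reference="GO_REF:0000002")]
        seeds = build_trait_seeds(anns, self.trait_map, dags)
        assert seeds["galactose"]["G1"] == 0.95

    def test_sibling_term_gives_no_seed(self, dags):
        # GO:0000003 is a sibling of the mapped GO:0000002, not a descendant
        anns = [Annotation("G1", "GO:0000003", "IDA")]
        assert build_trait_seeds(anns, self.trait_map, dags)["galactose"] == {}

    def test_chebi_exact_only(self, dags):
        hit = Annotation("G1", "CHEBI:28260", "XREF", source=SOURCE_CHEBI)
        miss = Annotation("G2", "CHEBI:99999", "XREF", source=SOURCE_CHEBI)
        seeds = build_trait_seeds([hit, miss], self.trait_map, dags)
        assert seeds["galactose"] == {"G1": 1.0}

    def test_unmapped_trait_omitted(self, dags, caplog):
        seeds = build_trait_seeds([], {"ghost": {SOURCE_GOA: set()}}, dags)
        assert "ghost" not in seeds
        assert "zero mapped terms" in caplog.text

    def test_order_invariance_and_monotone_max(self, dags):
        anns = [
            Annotation("G1", "GO:0000001", "IEA", reference="GO_REF:0000002"),
            Annotation("G1", "GO:0000002", "IDA"),
            Annotation("G2", "CHEBI:28260", "XREF", source=SOURCE_CHEBI),
        ]
        baseline = build_trait_seeds(anns, self.trait_map, dags)
        shuffled = anns[:]
        random.Random(0).shuffle(shuffled)
        assert build_trait_seeds(shuffled, self.trait_map, dags) == baseline
        # adding an annotation can never lower a seed
        more = anns + [Annotation("G1", "GO:0000001", "IEA", reference="GO_REF:0000002")]
        extended = build_trait_seeds(more, self.trait_map, dags)
        for gene, score in baseline["galactose"].items():
            assert extended["galactose"][gene] >= score
        assert all(0 < s <= 1 for s in extended["galactose"].values())


def test_parse_trait_map_infers_source():
    text = "trait_id\tterm\tsource\nsugar\tGO:0000001\nsugar\tCHEBI:28260\nfat\tGO:0000002\tGOA\n"
    mapping = parse_trait_map(io.StringIO(text))
    assert mapping["sugar"][SOURCE_GOA] == {"GO:0000001"}
    assert mapping["sugar"][SOURCE_CHEBI] == {"CHEBI:28260"}
    assert mapping["fat"][SOURCE_GOA] == {"GO:0000002"}
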