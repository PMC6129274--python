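import numpy as np
import pytest

from qtlprio.orthology import GENE_LEAF, ORTHOLOG_GROUP, HOGNode
from qtlprio.propagation import PropagationParams
from qtlprio.qtl_scoring import QTL
from qtlprio.significance import (NullDistribution, ResampleParams, bh_adjust,
                                  empirical_null, empirical_pvalue,
                                  sample_window, spurious_window_curve)

from conftest import make_index


class TestSampleWindow:
    def test_chromosome_drawn_by_gene_count(self, rng):
        index = make_index([100, 300])
        draws = [sample_window(index, 5, rng)[0].chromosome for _ in range(4000)]
        frac_chr2 = draws.count("chr2") / len(draws)
        assert frac_chr2 == pytest.approx(0.75, abs=0.03)

    def test_window_is_consecutive(self, rng):
        index = make_index([20])
        members = sample_window(index, 7, rng)
        indices = [g.index for g in members]
        assert indices == list(range(indices[0], indices[0] + 7))

    def test_full_chromosome_forces_start(self, rng):
        index = make_index([6, 3])
        members = sample_window(index, 6, rng)
        assert [g.gene_id for g in members] == [f"chr1g{i}" for i in range(1, 7)]

    def test_too_large_window_fatal(self, rng):
        with pytest.raises(ValueError, match="cannot resample"):
            sample_window(make_index([4]), 10, rng)

    def test_seeded_rng_reproducible(self):
        index = make_index([30, 10])
        seq1 = [tuple(g.gene_id for g in sample_window(index, 4, np.random.default_rng(5)))
                for _ in range(1)]
        seq2 = [tuple(g.gene_id for g in sample_window(index, 4, np.random.default_rng(5)))
                for _ in range(1)]
        assert seq1 == seq2


class TestEmpiricalNull:
    def test_size_contract(self, rng):
        index = make_index([12])
        qtl = QTL("q", "t", "chr1", 0, 450)  # 3 genes
        null = empirical_null(qtl, index, {}, [], resample_params=ResampleParams(2),
                              rng=rng)
        assert len(null) == 6  # n_resamples * k pooled gene-level values

    def test_no_seeds_all_zero(self, rng):
        index = make_index([12])
        qtl = QTL("q", "t", "chr1", 0, 450)
        null = empirical_null(qtl, index, {}, [], resample_params=ResampleParams(10),
                              rng=rng)
        assert np.all(null.values == 0.0)

    def test_max_pooling_size(self, rng):
        index = make_index([12])
        qtl = QTL("q", "t", "chr1", 0, 450)
        null = empirical_null(qtl, index, {}, [],
                              resample_params=ResampleParams(5, pooling="max"), rng=rng)
        assert len(null) == 5

    def test_null_mass_follows_seeds(self, rng):
        """With seeds concentrated on one chromosome, the null mass comes
        from windows drawn there (windows elsewhere contribute zeros)."""
        from qtlprio.qtl_scoring import score_member_genes

        index = make_index([100, 100])
        seeds = {f"chr1g{i}": 1.0 for i in range(1, 21)}
        by_chrom = {"chr1": [], "chr2": []}
        for _ in range(1000):
            members = sample_window(index, 5, rng)
            deltas = [c.delta for c in score_member_genes(members, seeds, [])]
            by_chrom[members[0].chromosome].extend(deltas)
        assert np.mean(by_chrom["chr1"]) > 0.0
        assert np.mean(by_chrom["chr2"]) == 0.0


class TestEmpiricalPvalue:
    def test_observed_above_all(self):
        null = NullDistribution(np.zeros(999))
        assert empirical_pvalue(0.5, null) == pytest.approx(1 / 1000)

    def test_observed_below_all(self):
        null = NullDistribution(np.full(999, 0.9))
        assert empirical_pvalue(0.1, null) == 1.0

    def test_count_formula(self):
        values = np.concatenate([np.full(4, 0.8), np.zeros(995)])
        assert empirical_pvalue(0.5, NullDistribution(values)) == pytest.approx(0.005)

    def test_unsmoothed_ecdf(self):
        null = NullDistribution(np.zeros(100))
        assert empirical_pvalue(0.5, null, smoothing=False) == 0.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(0.1, NullDistribution(np.array([])))

    def test_bounds_and_monotonicity(self, rng):
        null = NullDistribution(rng.uniform(0, 1, size=500))
        observations = np.sort(rng.uniform(-0.1, 1.1, size=50))
        pvals = [empirical_pvalue(o, null) for o in observations]
        assert all(1 / 501 <= p <= 1 for p in pvals)
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))  # larger dS, smaller p


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_permutation_equivariance(self, rng):
        p = list(rng.uniform(0.001, 1, size=9))
        adjusted = bh_adjust(p)
        order = list(rng.permutation(9))
        permuted = bh_adjust([p[i] for i in order])
        assert permuted == pytest.approx([adjusted[i] for i in order])

    def test_pointwise_geq_and_order_preserving(self, rng):
        p = sorted(rng.uniform(0.0001, 1, size=20))
        adjusted = bh_adjust(p)
        assert all(a >= x for a, x in zip(adjusted, p))
        assert all(a <= b for a, b in zip(adjusted, adjusted[1:]))

    def test_invalid_inputs_rejected(self):
        for bad in ([0.0], [1.2], [-0.5]):
            with pytest.raises(ValueError):
                bh_adjust(bad)


class TestSpuriousWindowCurve:
    def test_no_annotated_genes(self):
        index = make_index([10])
        curve = spurious_window_curve(index, set(), [1, 5])
        assert curve == {1: 0.0, 5: 0.0}

    def test_every_gene_annotated(self):
        index = make_index([10])
        all_genes = set(index.by_id)
        curve = spurious_window_curve(index, all_genes, [1, 3, 10])
        assert all(v == 1.0 for v in curve.values())

    def test_single_annotated_gene_enumeration(self):
        # 1 annotated gene at rank 5 of 10; w=2 -> windows starting at ranks
        # 4 and 5 hit -> 2/9
        index = make_index([10])
        curve = spurious_window_curve(index, {"chr1g5"}, [2])
        assert curve[2] == pytest.approx(2 / 9)

    def test_monotone_in_window_size(self, rng):
        index = make_index([40])
        annotated = {f"chr1g{i}" for i in rng.choice(np.arange(1, 41), 6, replace=False)}
        curve = spurious_window_curve(index, annotated, list(range(1, 30)))
        values = [curve[w] for w in sorted(curve)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_oversized_window_skipped(self, caplog):
        curve = spurious_window_curve(make_index([5]), {"chr1g1"}, [3, 99])
        assert 99 not in curve and 3 in curve
        assert "skipped" in caplog.text
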