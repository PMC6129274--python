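"""Empirical significance for QTL candidate scores.

A wide QTL overlaps annotated genes (or genes with annotated homologs) by
chance alone, so a raw score increase is not interpretable across QTL of
different sizes.  The null model here preserves the gene *count* of the
observed QTL: pseudo-QTL of the same number of consecutive genes are
placed at random (chromosome drawn proportional to its gene count, start
uniform), re-scored with the same trait seeds, and the member score
increases pooled into an empirical null.  Observed increases get
add-one-smoothed empirical p-values; study-level control takes each QTL's
smallest p-value and applies Benjamini-Hochberg FDR across QTL.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .orthology import HOGNode
from .propagation import PropagationParams
from .qtl_scoring import QTL, GeneIndex, genes_in_qtl, score_member_genes

logger = logging.getLogger(__name__)

__all__ = [
    "ResampleParams",
    "NullDistribution",
    "CandidateResult",
    "sample_window",
    "empirical_null",
    "empirical_pvalue",
    "bh_adjust",
    "spurious_window_curve",
]


@dataclass(frozen=True)
class ResampleParams:
    """Null-distribution settings.

    n_resamples:
        Number of random pseudo-QTL per QTL-trait pairing (default 1000).
    pooling:
        ``"pooled"`` (default) pools every member gene's increase from every
        resample; ``"max"`` keeps only each resample's maximum increase.
    smoothing:
        Add-one smoothing of the empirical p (default True); when False the
        raw ECDF exceedance fraction is used and p may be 0.
    """

    n_resamples: int = 1000
    pooling: str = "pooled"
    smoothing: bool = True

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.pooling not in ("pooled", "max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


@dataclass
class NullDistribution:
    """Pooled null score increases for one QTL-trait pairing."""

    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CandidateResult:
    """A member gene's scores plus its empirical p and the BH-adjusted
    minimum p of its QTL."""

    gene_id: str
    S0: float
    S1: float
    p: float | None = None
    p_bh_qtl: float | None = None

    @property
    def delta(self) -> float:
        return self.S1 - self.S0


def sample_window(index: GeneIndex, k: int, rng: np.random.Generator) -> list:
    """Draw a pseudo-QTL of ``k`` consecutive genes.

    The chromosome is drawn with probability proportional to its gene count
    among chromosomes holding >= k genes; the start rank is uniform over
    the valid positions.  Returns the member :class:`GeneLocus` list.
    """
    eligible = [(chrom, loci) for chrom, loci in sorted(index.by_chromosome.items())
                if len(loci) >= k]
    if not eligible:
        raise ValueError(f"no chromosome has >= {k} genes; cannot resample")
    counts = np.array([len(loci) for _, loci in eligible], dtype=float)
    chrom_i = rng.choice(len(eligible), p=counts / counts.sum())
    loci = eligible[chrom_i][1]
    start = int(rng.integers(0, len(loci) - k + 1))
    return loci[start:start + k]


def empirical_null(
    qtl: QTL,
    index: GeneIndex,
    trait_seeds: Mapping[str, float],
    forest: Iterable[HOGNode] | Mapping[str, HOGNode],
    params: PropagationParams | None = None,
    resample_params: ResampleParams | None = None,
    rng: np.random.Generator | None = None,
    k: int | None = None,
) -> NullDistribution:
    """Null distribution of score increases for one QTL-trait pairing.

    Each resample places a pseudo-QTL of the same gene count ``k`` (taken
    from the observed QTL when not given), scores it exactly as the
    observed one (member seeds 1/k, same trait seeds, same propagation
    parameters) and pools the member increases.
    """
    resample_params = resample_params or ResampleParams()
    rng = rng if rng is not None else np.random.default_rng()
    if k is None:
        k = len(genes_in_qtl(index, qtl.chromosome, qtl.start, qtl.end))
    from .qtl_scoring import gene_to_tree_map

    if not isinstance(forest, Mapping):
        forest = gene_to_tree_map(forest)
    values: list[float] = []
    for _ in range(resample_params.n_resamples):
        members = sample_window(index, k, rng)
        scores = score_member_genes(members, trait_seeds, forest, params)
        deltas = [c.delta for c in scores]
        if resample_params.pooling == "max":
            values.append(max(deltas))
        else:
            values.extend(deltas)
    return NullDistribution(np.asarray(values, dtype=float))


def empirical_pvalue(
    observed: float, null: NullDistribution, smoothing: bool = True
) -> float:
    """Empirical p-value of an observed score increase.

    With add-one smoothing (default), ``p = (1 + #{null >= obs}) / (1 + N)``
    so p is never 0 and is bounded below by 1/(N+1); without smoothing the
    raw exceedance fraction is returned.
    """
    n = len(null)
    if n == 0:
        raise ValueError("empty null distribution")
    exceed = int(np.count_nonzero(null.values >= observed))
    if smoothing:
        return (1 + exceed) / (1 + n)
    return exceed / n


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Input: one minimum p per QTL, each in (0, 1].  Output in input order;
    adjusted values are >= the inputs and order-preserving.
    """
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in adjusted]


def spurious_window_curve(
    index: GeneIndex,
    annotated_genes: Iterable[str],
    window_sizes: Sequence[int],
) -> dict[int, float]:
    """Probability that a sliding window of w genes contains at least one
    trait-annotated gene, for each requested window size.

    Every start position on every chromosome (step 1 gene) contributes one
    window; the probability is the hit fraction pooled over chromosomes.
    Sizes larger than every chromosome are skipped with a warning.
    """
    annotated = set(annotated_genes)
    curve: dict[int, float] = {}
    flags_by_chrom = {
        chrom: np.array([g.gene_id in annotated for g in loci], dtype=int)
        for chrom, loci in index.by_chromosome.items()
    }
    for w in window_sizes:
        if w < 1:
            raise ValueError("window size must be >= 1")
        hits = 0
        total = 0
        for flags in flags_by_chrom.values():
            n = len(flags)
            if n < w:
                continue
            cumulative = np.concatenate([[0], np.cumsum(flags)])
            window_counts = cumulative[w:] - cumulative[:-w]
            hits += int(np.count_nonzero(window_counts > 0))
            total += n - w + 1
        if total == 0:
            logger.warning("window size %d exceeds every chromosome; skipped", w)
            continue
        curve[w] = hits / total
    return curve
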