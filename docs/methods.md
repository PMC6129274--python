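# Methods

## Model

The package treats candidate-gene prioritization as label propagation over
hierarchical orthologous groups (HOGs).  A HOG is a tree whose leaves are
genes and whose internal nodes are speciation (ortholog-group) or
duplication (paralog-group) events; a gene belongs to at most one HOG, and
genes outside every HOG behave as singletons.

For one trait, per-gene seed scores propagate in two passes per tree:

* **Up**: post-order; an internal node's score is the sum over children of
  `child_score × f(edge)`.
* **Down**: pre-order; a child's final score is
  `max(own up-score, parent_final × f(edge))`; the root's final score is
  its up-score.

The edge factor is `f = 1 − d` with decay `d = 0.2` by default, and
`(1 − d)²` for edges *below* a duplication node — the duplication event
separates its children into paralogous lineages, so both child edges pay
the double decay.  Two consequences follow directly from the max rule:
every gene's final score is at least its seed, and a single seed reaches
any other leaf as `seed × Π f(edge)` along the leaf-to-leaf path (the
brute-force oracle the tests use).  Scores are not probabilities: sums at
internal nodes can exceed 1 when several homologs are seeded.

Trait independence: traits are opaque labels; each propagates alone.

## Seeds

* QTL membership uses strict inequalities (`s < g_end`, `e > g_start`);
  each member starts at the uniform prior `1/|Q|`.
* Annotation evidence: experimental GO codes (EXP, IDA, IPI, IMP, IGI,
  IEP) score 1.0; IEA scores 0.95 only through an allow-list over the
  GAF DB:Reference / Assigned_by columns (default: the UniProt keyword,
  EC and InterPro mapping GO_REFs — configurable, since curated lists are
  study-specific); ChEBI cross-references score 1.0; everything else is
  dropped, as are NOT-qualified rows (negative evidence must not create
  positive seeds).  Multiple sources reduce by maximum, so seed building
  is order-independent and monotone.
* GO terms match a trait through the reflexive is_a closure; ChEBI only by
  exact accession (closure available as a per-source switch).  Unknown or
  obsolete annotation terms are skipped with a warning, never fatal.
* At a member leaf the QTL prior and any annotation seed combine by
  maximum, not sum.  This is validated by the worked example: a directly
  annotated member of a 309-gene QTL shows ΔS = 1 − 1/309 = 0.996764
  exactly; summing would give ΔS = 1.

## Significance

Pseudo-QTL preserve the member gene *count*, not the bp length: a
chromosome is drawn with probability proportional to its gene count among
chromosomes long enough, the start rank uniformly, and the k consecutive
genes are re-scored with the same seeds and parameters.  Member increases
are pooled across resamples (gene-level pooling, `n_resamples × k`
values); per-resample-maximum pooling is available as an option.  The
empirical p is add-one smoothed, `p = (1 + #{null ≥ ΔS}) / (1 + N)`, so it
is never 0 and never below `1/(N+1)`; the raw ECDF variant is an option.
Study-level control: BH (via statsmodels `multipletests`) applied to each
QTL's smallest p across the study; per-gene p-values within a QTL stay
unadjusted.  Skipping the permutation step changes no ΔS.

The down pass does not subtract a child's own up-contribution before
propagating back to it.  Self-inflation is bounded — an edge traversed
twice costs `(1−d)²` and the child takes a max with its own score — and
the plain sum-up/max-down reading keeps the kernel monotone.

## Synthetic worlds

The generator emits real files (GFF3, OrthoXML, OBO, GAF, TSV) so every
reader is exercised.  The default world: 3 species, two 100-gene
chromosomes (gene lengths 500–3000 bp, gaps 100–1000 bp), one HOG per
genome position spanning the orthologs of all species, duplication nodes
with probability 0.2, one trait mapped to a mid-level GO term (annotations
go to its child, exercising the closure) and a ChEBI compound, QTL of 20
genes.  Annotation evidence mixes experimental GAF rows, trusted-IEA rows
and ChEBI xrefs (70% experimental among GAF rows, 30% ChEBI overall) —
values chosen once as a plausible mix for a well-annotated model organism.

Planted-causal mode states the world the method is designed for: each QTL
designates one member whose cross-species homolog (never the member
itself) is annotated; QTL windows are gene-disjoint and the 5 background
annotations per trait avoid every member's HOG, so the causal signal is
identifiable by construction and rank-1 recovery is a meaningful check.
Null mode removes all structure: annotations land uniformly anywhere and
QTL are placed independently.

What a green planted-recovery test does **not** establish: robustness to
trait-relevant background annotation inside the QTL window, to genes
shared between overlapping QTL, or to misannotation — in real studies
competing annotated members are expected and the p-values, not the raw
rank, carry the inference.

## Numerical and design choices

* "Double decay" on paralog edges is read as the decay applied twice,
  `(1−d)²`, attached to the edges below the duplication node; a
  doubled-rate variant `1−2d` (floored at 0) is selectable.
* Ranking ties break by genomic position, then gene id — deterministic
  output for reproducible runs.
* Each QTL is scored in isolation, even when QTL for the same trait
  overlap; other QTLs' uniform priors are never co-seeded.
* Coordinates are 1-based inclusive internally; BED input is converted on
  read.  Strand is ignored for membership.
* All randomness flows through one seeded NumPy generator per run; the
  seed is a config/CLI value and logged.
* Runtime scaling in the test suite: the null-world conservativeness check
  runs 200 replicates at 150 resamples each (not the 1000 default) on the
  two-chromosome world; the p-value floor scales accordingly and the
  one-sided KS comparison is unaffected.

## Known limitations

* Scoring is not probabilistic; S¹ values above 1 are meaningful only
  relatively.
* Only is_a edges are traversed; part_of and regulation relations are
  ignored.
* The permutation null is the dominant cost (linear in resamples); no
  parametric approximation is provided.
* QTL intervals are inputs; no LOD-based detection or cM→bp conversion.
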