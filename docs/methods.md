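# Methods

## The problem

Deep single-cell RNA-seq surveys of mouse hippocampal CA1 assign each
neuron to a leaf type in a four-level transcriptomic taxonomy
(class → subclass → supertype → type; two classes, GABAergic and
glutamatergic). Given such a taxonomy and a gene × cell count matrix,
`neurosig` distills per-gene *type-mean expression signatures*,
quantifies how type-specific each gene's expression is, tallies how
many genes of a curated neuromodulatory panel individual cells
co-express, asks whether expressed neuropeptide precursor (NPP) genes
are accompanied by expressed cognate receptor (NP-GPCR) genes, and
checks that the signatures are statistically stable. The taxonomy is
an input throughout; no clustering is performed.

## Pipeline and statistics

**CPM normalization.** Each cell's counts are scaled to counts per
million over *all* genes present in the input matrix, so every cell
column sums to 1e6. Because the denominator is the full per-cell
total, any subsetting to a gene panel must happen after normalization;
subsetting first would change the denominator and every downstream
number. No pseudocounts are added anywhere.

**Cell and gene filtering.** Cells are restricted to a target region
(default `CA1`) and to leaf types with at least `min_cells_per_type`
such cells (default 16, boundary inclusive). A gene is "expressed"
when its maximum type-mean CPM is *strictly* greater than
`expression_threshold` (default 10 CPM); the filter reports a
candidates → detected → retained cascade. Both conventions are
boundary-tested.

**Type-mean signatures.** The signature of a gene is the vector of
untrimmed arithmetic means of per-cell CPM within each retained type.
Trimmed or winsorized means are deliberately not offered: robustness
concerns are surfaced by the explicit diagnostics below instead of
being silently folded into the estimator.

**The delta statistic.** For a signature (μ₁, …, μₙ) with maximum
μ_max > 0,

    delta = (n − Σᵢ μᵢ/μ_max) / (n − 1).

delta is 0 when all type means are equal, 1 when exactly one type has
nonzero expression, invariant to positive rescaling and to permutation
of types, and is the tissue-specificity index τ applied to neuron
types. Numerically, each mean is divided by μ_max *before* summing;
this makes both endpoints exact in floating point for any n. When
μ_max = 0 delta is undefined: such genes carry a NaN and a
`defined=False` flag and are excluded from orderings, never coerced
to 0 (the formula divides by μ_max). Display order is descending
delta, ties broken by descending μ_max then lexicographic symbol;
`log10(rowmax)` annotations use base 10 and are undefined for zero
rows.

**Co-expression.** A cell's co-expression count for a panel is the
number of distinct panel genes strictly above the threshold (the same
strict >10 CPM semantics as the gene filter, one shared parameter).
Counts are binned in unit-width integer histograms, overall and per
neurotransmitter class; the mode is the smallest count attaining the
maximal frequency (a deterministic tie-break). Panels can be merged;
a symbol appearing in two panels with different categories is an
error, and merged counts are exactly the sum of disjoint sub-panel
counts.

**Cognate pairing.** Panels carry a `cognate_group` key shared by an
NPP gene and the NP-GPCR gene(s) whose receptor binds its peptide
(e.g. Sst ↔ Sstr2 under "SST"). An expressed NPP is *paired* when at
least one cognate receptor is also expressed anywhere in the area;
the headline statistic is `paired_fraction` = paired / expressed
NPPs. NPPs without a cognate key are reported unresolvable and
excluded from the denominator. The cognate dictionary is user-supplied
data, not hard-coded pharmacology. A stricter type-resolved mode —
receptor above threshold in at least one type where the NPP itself is
above threshold — is available but is not the headline statistic,
because the underlying claim is area-level (peptides diffuse beyond
the releasing type).

**Within-type diagnostics.** By-eye judgements on within-type CPM
histograms are replaced by two explicit rules, evaluated per
(gene, type) subset with at least `min_cells` cells (default 16):

- *high outlier*: a cell with log2(CPM+1) above Q3 + 3·IQR of the
  subset's log2(CPM+1) values (quartiles by linear interpolation —
  the flag depends on the quantile definition, so it is fixed and
  documented);
- *low anomaly*: zero fraction above 0.25 while the median of the
  nonzero values still exceeds the 10 CPM expression threshold, i.e.
  the gene is clearly on in the type yet many cells report nothing.

Both rules are descriptive, not inferential; no zero-inflation model
is fitted. The high-outlier fence is only asymptotically scale-free:
the +1 offset inside the log breaks exact invariance under joint
rescaling of CPM and threshold, which matters only at CPM values near
1. For figure panels, the displayed pair of types for a gene is the
max-mean type plus the type whose mean is nearest 25% of that
maximum.

**Subsampling stability.** Per replicate, the cells of every type
(with ≥ 2 cells) are split into two disjoint random halves;
signatures are recomputed on each half and, per gene, the Pearson
correlation across types between the two half-signatures is recorded.
The report gives per-gene median and IQR over replicates (default 50),
is seed-reproducible, and reports constant genes as undefined rather
than 0. A 50/50 split was chosen as the most conservative disjoint
subsample; correlations increase stochastically with cells per type,
which the tests verify at 20 vs 200 cells/type.

## The synthetic generator

Real data at the scale of the motivating surveys is an external
download, so every stage is exercised on synthetic data with a planted
design. The generator emulates the *structure* of a deep SMART-Seq
style CA1 survey:

- a deterministic 2/6/14/42 class/subclass/supertype/type hierarchy by
  default (near-even nested splits; classes alternate GABAergic /
  glutamatergic);
- uneven cells per type, uniform on [16, 300] by default, so the
  ≥16-cell filter is exercised at its boundary;
- four planted gene specificity classes: one-type markers (baseline 0
  outside the target type by default, i.e. exact one-hot profiles with
  delta = 1 in expectation; a `marker_baseline > 0` variant exercises
  intermediate deltas), supertype programs, class-restricted genes,
  and ubiquitous genes (flat profiles, delta = 0 in expectation);
- negative-binomial counts with per-gene dispersion (default 0.5;
  Poisson at 0), expected count = profile × library/1e6, log-normal
  per-cell library sizes (μ = log 1e6, σ = 0.35) so CPM normalization
  is non-trivial, and independent Bernoulli dropout (default 0.05,
  low, as appropriate for a deep full-length protocol).

Defaults not fixed by the emulated study design (baseline 50 CPM,
marker fold 20, the library-size and dropout parameters) were chosen
once as realistic for deep full-length scRNA-seq and are not tuned.
The planted profile is a *relative* abundance on a CPM-like scale:
realized CPM equals it up to the per-type normalizing sum, which is
immaterial for delta (scale-invariant) and is accounted for exactly in
the mean-recovery tests.

What the generator does **not** emulate: read-level artifacts (gene
length bias, exon/intron split — simulation starts at the count
matrix), correlated dropout, batch or donor structure, doublets, or
continuous within-type gradients. Passing tests therefore demonstrate
correctness of the statistics under a clean overdispersed count model
with known truth, not robustness to every artifact of real data.

## Numerical choices and degenerate inputs

- delta: divide-by-μ_max-first evaluation (exact endpoints); n < 2 or
  negative means are errors; all-zero rows are flagged undefined.
- Quantiles: linear interpolation throughout (numpy default), stated
  because the outlier fence depends on it.
- Zero-total-count cells make CPM undefined and raise, listing the
  offending cell IDs.
- Empty filter results are a warning (empty outputs), not an error;
  an empty *cell* filter result (no type survives) is an error.
- Figures are rendered deterministically (fixed SVG hash salt, no
  timestamp metadata) so vector output is byte-comparable.

## Problem sizes

The test suite and acceptance checks run the full pipeline on the
planted 42-type dataset at 100 cells/type (112 genes × 4,200 cells),
with 50 stability replicates; the whole suite completes in a few
seconds on one CPU.

## Known limitations

- The package consumes a taxonomy; it offers no help constructing one.
- Pairing quality is bounded by the user-supplied cognate dictionary.
- The low-anomaly rule cannot distinguish technical dropout from
  genuine bimodal subpopulations; it only localizes where the
  question arises.
- Categories, thresholds and panels default to the hippocampal
  neuromodulation setting (CA1, 10 CPM, 16 cells) but all are
  parameters; nothing restricts the pipeline to that system.
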