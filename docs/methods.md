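# Methods

## The classifier

Each gene is treated independently as a vector of positive expression
values over N ≥ 2 cell states. The vector is sorted in descending order
(stable sort; ties keep the user-supplied state order, which never affects
the category because a tie's ratio is 1 < T, but makes the recorded
descending order deterministic). Consecutive sorted pairs are scanned from
the top, and the first pair whose ratio `v(k)/v(k+1)` is **greater than or
equal to** the threshold T defines the cut: the gene is enriched in the k
states above it. If no pair triggers, the gene is Even when the overall
`max/min < T` and Gradient when `max/min ≥ T` (equality at this boundary is
Gradient, because Even is defined by a strict inequality).

Floating-point comparisons are exact — no epsilon. An epsilon would
silently move genes between categories; the pseudocount already guarantees
well-defined ratios, and exactness makes category counts bit-reproducible.

The category space is a fixed partition of all genes: the `2^N − 2` proper
non-empty state subsets plus Gradient and Even (32 categories at N = 5).
Structural consequences asserted as properties: the enriched gene set
shrinks weakly and the Even set grows weakly as T increases; permuting
state columns permutes enriched labels identically; rescaling one gene's
whole vector changes nothing; and at N = 2 Gradient is unreachable (the
only consecutive ratio *is* max/min).

## Preprocessing

Fixed order, matching how FPKM tables from an isoform-level quantifier are
usually consumed:

1. **aggregate** — per gene and sample, sum the isoforms whose quality
   status equals the usable token (default `"OK"`; exactly one token is
   treated as usable). A gene whose isoforms are all unusable in a sample
   contributes 0 there; it is only removed if zero in *every* sample.
2. **filter** — drop genes that are zero in all samples.
3. **normalize** — rescale each sample column to a fixed total
   (default 10⁶), i.e. expression per million of the per-sample sum.
4. **pseudocount** — add 1 to every value.

The order is pinned because filtering changes column sums. The pseudocount
comes *after* scaling; this damps fold changes of low-abundance genes
(a ratio `(a+1)/(b+1)` is always closer to 1 than `a/b`), which keeps
threshold decisions stable near the detection floor. Consequences used as
invariants: per-sample scale invariance (multiplying a raw column by any
c > 0 changes nothing downstream) and column conservation (the
post-normalization column sums, minus pseudocounts, equal the target).

Tunable parameters (`PreprocessConfig`): `target_total` (> 0, default 10⁶),
`pseudocount` (≥ 0, default 1), `ok_status_token` (default `"OK"`).
Missing values are a hard error everywhere: the chain produces none, so an
NA in an input table indicates an upstream problem rather than something to
impute.

## Threshold calibration

The threshold trades two error rates measured from user-supplied control
lists present in the classified matrix:

- **false-positive rate** — fraction of housekeeping-like negative
  controls assigned *any* enriched pattern (Even and Gradient are both
  correct for a control);
- **false-negative rate** — fraction of marker-like positive controls
  assigned *no* enriched pattern. Capture by default means "any enriched
  pattern", not the biologically expected one; a strict mode
  (`expected=` mapping) additionally requires the expected state subset.

Denominators are controls actually present among the classified genes;
absent ids are reported separately and never counted, so unmeasured
controls cannot deflate a rate. Rates are exact rational counts, reported
unrounded (with a 0.1% rounding helper for display). `threshold_sweep`
classifies the matrix at each grid value (default grid 1.5, 2, 2.5, 3) and
recommends the argmin of FPR + FNR; on the cardiovascular panel this
procedure selects 2.5, which is the package default.

## Shuffle null

`shuffle_matrix` permutes a prepared matrix while conserving the value
multiset exactly, with two modes:

- `global` (default): all values permuted across the whole matrix. This is
  the null that can collapse a lineage-enrichment distribution, and is
  therefore the meaningful control.
- `within_gene`: each gene's vector permuted across states. Because a
  gene's category depends only on its own value multiset (up to *which*
  states come out enriched), this mode provably conserves every gene's
  enriched-vs-not status — kept precisely to demonstrate that distinction
  in a property test.

Both modes are deterministic given a seed (numpy `default_rng`).

## Synthetic fixtures

The generator emulates the structure of a multi-state differentiation
panel: blocks of genes enriched in chosen state subsets at controlled
fold-change margins, geometric-decay Gradient genes, near-flat Even genes,
housekeeping-like negatives, and isoform tables with planted switches.

Plants are specified on the **classifier-ready scale** — the values the
classifier will actually see. An enriched plant places its enriched block
a factor `margin` above the non-enriched block, with at most
`within_block_spread` (< T) of spread inside each block, so the scan cuts
exactly at the block boundary. The raw matrix is then built as an exact
fixed point of the preprocessing chain: a ballast gene tops each column of
(targets − pseudocount) up to the normalization target (its own profile is
near-flat by construction and checked against a 1.45-fold bound, so it is
always Even), and random per-sample scale factors in [0.5, 2] distort the
raw columns, which normalization removes again. With zero noise this gives
100% category recovery by construction while still exercising the
normalization's scale invariance on every fixture.

Noise, when requested, is multiplicative log-normal with a given
coefficient of variation — simple, positive, scale-free; mean-one so it
does not bias levels. Normalization introduces relative float rounding of
order 10⁻¹³, so fixtures that must be recovered exactly use margins a few
percent above the design threshold; exact-at-T behaviour is asserted
directly on constructed vectors instead.

Housekeeping-like negatives are flat except for one randomly boosted state
with a boost drawn uniformly from [1, spread]; a gene is classified
enriched exactly when its boost reaches T, so the expected false-positive
rate is the analytic exceedance `(spread − T)/(spread − 1)` — a binomial
oracle for calibration tests. Marker-like positives are built the same way
with the boost drawn from a margin range, giving an analytic
false-negative curve.

What passing these fixtures does *not* show about real data: the generator
has no count noise, no gene-length or GC bias, no correlated genes, no
batch structure, and its housekeeping model is one boosted state rather
than empirical housekeeping variability. Results on real matrices depend
on upstream quantification quality in ways the fixtures cannot probe.

## Problem sizes

The test suite and the acceptance run use matrices of a few hundred to a
few thousand genes and ~10⁵ random vectors for the brute-force oracle
comparison; the classifier is linear in genes (an N·log N sort per gene)
and handles transcriptome-scale tables (tens of thousands of genes) in
seconds. The acceptance study plants 25 genes per single-state category at
three margins (2.6, 3.5, 5), 12 per composite category, 300 Gradient,
1200 Even, 600 grid-straddling negatives and 300 positives with margins in
[2, 4] under 15% multiplicative noise — controls deliberately straddle the
threshold grid so the calibration sweep has a visible trade-off to
measure.

## Known limitations and open choices

- The published isoform-status vocabulary beyond `OK` (LOWDATA, FAIL, …)
  is not interpreted; exactly one configurable token counts as usable.
- Gradient/Even genes have no natural "decision fold change"; the max/min
  ratio is recorded in that output column as an audit value only.
- Isoform-level runs normalize over the isoform matrix itself rather than
  inheriting gene-level totals; with complete isoform tables the two
  differ only by the usable-status filtering.
- Isoform-switch detection operates on isoform-level categories (≥ 2
  discordant labels, at least one enriched); exon-level read-stack
  analysis is out of scope.
- External-list distributions are reported at full category granularity
  with an optional user-defined grouping map; no canonical coarse grouping
  is imposed.
- lncRNA (or any biotype) subsetting is driven entirely by a user-supplied
  annotation list; the package does not classify biotypes.
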