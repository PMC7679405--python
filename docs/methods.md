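# Methods

This note documents the models, conventions, and defaults behind
`pirnaflow`, what the synthetic generator does and does not emulate, and
the design choices made where the design was genuinely open.

## Coordinates and conventions

All internal coordinates are 0-based half-open `[start, end)`; GFF3
(1-based inclusive) is converted at the I/O boundary, BED6 is emitted
natively.  A read's 5′ coordinate is `start` on the plus strand and
`end − 1` on the minus strand.  "Sense" always means the read strand
equals the annotated feature strand.

## Synthetic genomes

`synthgen.build_genome` lays features at non-overlapping positions with
random background gaps (100–300 nt), round-robin across two contigs.
Gene models are `5′UTR | CDS (intron CDS)* | 3′UTR`, parts abutting
without gaps, genomic part order reversed for minus-strand genes.
Defaults: 30 genes × 3 exons (UTR5 200 nt, CDS 300, intron 200, UTR3
250), 8 transposon families (classes split evenly LTR/LINE, 4 copies each
of 800–2000 nt, both orientations), 6 satellite loci of 260 nt, and 3
loci each of tRNA/rRNA/snRNA/snoRNA (80–150 nt) — roughly 120 kb total.

**k-mer uniqueness.** Sequence is drawn base-by-base under the constraint
that every 18-mer window is unique genome-wide *canonically* (a window
may not repeat another window or its reverse complement; a colliding base
is redrawn, with a bounded retry budget).  Any read of ≥ 18 nt therefore
has exactly one exact placement, which is what lets every classification
test compare against planted truth without multimapping ambiguity.  Two
deliberate consequences:

- *Satellite loci are not literal tandem repeats.*  Real satellite DNA
  repeats a unit; repeated units would multimap.  Here a satellite locus
  is unique placeholder sequence carrying the `satellite_DNA` annotation —
  the category logic only needs the annotation, not the repetitiveness.
- *Transposon copies of a family share annotation, not sequence.*  Family
  identity lives in the `family`/`class` attributes.  Multimapping policy
  is still exercised by tests that deliberately duplicate a segment.

## Simulated read populations

`synthgen.simulate_reads` draws, per read: a category from the category
mixture, a feature from the matching pool (for genic reads, the gene-part
class from the genic feature mixture first), a length from the 23–29 nt
distribution (support is validated to lie in 18–35), a position uniform
within the feature, and a strand (sense with probability
`te_sense_fraction` for transposon reads, `genic_sense_fraction` —
default 0.5 — for genic reads, 0.5 otherwise).  The read sequence is the
exact genomic substring, reverse-complemented for minus-strand reads.

**Ping-pong pairs.**  With probability `pingpong_pair_fraction`, a
transposon read additionally emits an opposite-strand partner whose 5′
end overlaps its own 5′ end by exactly 10 nt (the germline slicer
signature: cleavage opposite guide nucleotides 10–11).  The mate is
placed so both reads fit inside the element.  Partners consume read
slots and are always transposon reads, so a pair fraction *f* inflates
the transposon share: the planted share of category *c* among emitted
reads is `m_c · (1 + f·[c = transposon])`, renormalized
(`ReadProfile.expected_category_shares`).  Recovery tests compare against
these analytic values, not the raw mixture.

**Abundance.**  Each unique read gets a lognormal total abundance
(meanlog `log 24`, sdlog 0.7, floored at 1), split across samples as
independent Poisson draws.  This produces a realistic skewed count table
in which the min-count filter actually removes something (~10–15% of
reads), while keeping weighted composition unbiased because abundance is
independent of category.  When a `DEPlan` is attached, a `de_fraction`
of reads have their group-B Poisson rate scaled by
`2^(±log2fc_magnitude)`, with the planted direction recorded in the
truth label.

**Presets.**  `brain`: category mix transposon .10 / satellite .002 /
genic .878 / blacklist .02; genic features exon .62 / intron .11 /
utr5 .05 / utr3 .22; sense fraction 0.70; no ping-pong.  `ovary`:
transposon .90 / satellite .023 / genic .057 / blacklist .02; genic
features exon .12 / intron .66 / utr5 .15 / utr3 .07; sense fraction
0.30; ping-pong pair fraction 0.30.  `brain_tud` is the brain preset
with the sense bias eliminated (0.5) — the mutant phenotype.  The
percentages printed for wild-type compositions anchor these mixtures;
the brain intron/5′UTR split, both numeric sense fractions, and the
ping-pong pair fraction are artifact defaults chosen here (flagged as
such in the preset docstrings), not published measurements.  DE presets
plant 85% (brain) or 39% (ovary) of DE features as downregulated, with
`de_fraction` 0.3, |log2FC| 3, baseline mean 100, dispersion 0.1, 3+3
replicates.

What the generator does **not** emulate: sequencing errors, adapters,
quality-score structure, chimeras, true tandem repetition, family-level
sequence similarity, genome-scale feature density.  A green
plant-recovery test therefore establishes that the pipeline's logic is
correct on clean, unambiguous data — not that it is robust to noisy
mapping or repeat-induced multimapping.

## Screening

Filters are pure per-read predicates and commute; the fixed order
(blacklist → length/whitelist → min-count) only attributes removals.
Blacklist removal triggers on ≥ 1 nt overlap of *any* placement with
*any* blacklisted ncRNA locus on either strand — the strictest rule,
appropriate for contamination.  The min-count rule keeps reads whose
counts sum to ≥ 10 over **all** samples of both conditions (`pooled`
scope); since the wording "across the samples" is ambiguous, a
`per_group` scope is available.  The length gate (23–29 nt) stands in
for database membership; an exact-sequence whitelist can be supplied
where a reference set exists.

## Categorization

A read is categorized over all its placements with precedence
transposon > satellite > genic > unannotated; a placement only counts
for a feature when at least 50% of the read lies inside it
(configurable), which blocks 1-nt grazing assignments.  The deciding
placement maximizes overlap with a feature of the winning category (ties:
leftmost `(contig, start)`); its strand vs. the feature's strand gives
the sense call.  Genic reads take the gene-part class of maximal overlap
with ties broken 3′UTR > 5′UTR > exon > intron; "exon" means CDS-exon,
disjoint from the UTRs.  Composition percentages are read-weighted
(pooled counts) by default; `weighting="unique"` counts each sequence
once.  The hierarchy guarantees that annotating a new gene over a
transposon-assigned read never changes its category.

## Strand bias

The spectrum tallies weighted sense/antisense counts per length in
[18, 35].  The bias statistic is the weighted sense fraction with an
exact two-sided binomial test against 0.5 (counts rounded to integers);
exact rather than normal because desk-scale totals can be small.  The
exact test's sampling unit is the read, so its null calibration is
checked with unit weights; with count weighting the p-value is
interpretable only as a descriptive index.

## Ping-pong z-score

For every plus/minus read pair on one contig, the 1-based overlap is
`k = five_prime(minus) − five_prime(plus) + 1`:

```
+ read 5'→  100 101 ... 109 ...
- read              ...  ← 109 (5')
k = 109 − 100 + 1 = 10
```

Pairs with `1 ≤ k ≤ 20` accumulate the product of the two reads' weights
(a `min` mode is available); each unordered pair is counted once.  The
z-score compares `O(10)` with the mean and sample standard deviation
(n−1) of `{O(k) : k ≠ 10}`; a flat histogram raises rather than
returning a meaningless z.  The pipeline computes the histogram over
transposon-assigned reads, where the mechanism lives.  z is invariant
under coordinate translation, contig relabeling, and uniform weight
scaling.

## Differential expression

The count model is NB with `Var = μ + φμ²` and a single dispersion
shared across features — 2–3 replicates per group cannot support
per-feature dispersions.  φ is estimated by method of moments (per
feature: pooled within-group variance and overall mean of normalized
counts; `φ_f = max(0, (v−m)/m²)`; median over features with `m > 1`,
floored at 0.01).  Each feature is tested by a likelihood-ratio test of
one common mean (scaled by size factors) against separate group means,
fitted by per-feature Newton iteration on log μ at fixed φ, with
`2·(llₐ − ll₀)` referred to χ²₁.  This is a deliberate, fully specified
substitute for exact-test frameworks, validated by simulation: at the
true φ the type-I error at 0.05/0.01 is nominal to within binomial
noise on 2,000 null features.  Fold changes are `log2(μ_B/μ_A)` with a
10⁻⁸ mean floor.  Significance defaults mirror the two-tissue analysis:
raw p < 0.01 (brain piRNAs) or BH FDR ≤ 0.05 (ovary piRNAs, genes).

**Size factors.**  The default estimator is the kernel-density **mode**
of per-sample log-ratios to feature geometric means (zero-free
features).  Rationale: with strong, one-sided differential expression
(the brain preset plants 25% of features down), *total-count* factors
are composition-biased (every null feature appears shifted the other
way), and both median-of-ratios and trimmed-mean (TMM) estimators still
drift because the median/symmetric trim cuts into the null block.  The
mode estimator only assumes non-DE features form the largest coherent
block at a common offset, and recovers the planted direction mixtures
where the others do not.  `total`, `median_ratio`, and `tmm` remain
selectable.  The mode assumption fails if a majority of features shift
coherently; in that regime no internal normalization is identifiable
and spike-ins would be required.

## Concordance

Significant piRNAs are paired with significant DE genes they map
antisense to (sense filter configurable; pairing-step restriction by
default).  Quadrant counts use the signs of the two fold changes,
excluding zero fold changes with a tally; the headline fraction — among
piRNA-down pairs, the gene-up share — carries an exact Clopper-Pearson
95% CI.  Multi-target piRNAs contribute one pair per target gene (a
collapse mode exists).  Gene-level DE is an *input* table
(`gene_id, log2fc, q`); the synthetic generator fabricates it jointly
with the piRNA plant at a configurable concordance (default 0.8).

## Numerical and degenerate-input choices

- Newton mean fits converge quadratically; all-zero features go to the
  mean floor directly; non-convergence raises naming the feature.
- BH is the standard step-up, capped at 1, validated against an
  independent implementation.
- Weighted-share tolerances in recovery tests use the effective sample
  size `(Σw)²/Σw²`, since lognormal weights inflate binomial variance.
- Reads containing N are dropped (with a tally), not corrected: an
  exact mapper cannot place them.
- Empty inputs raise where a statistic would be undefined (empty
  composition, empty spectrum in `bias_test`, flat ping-pong histogram,
  empty pair set) rather than returning NaNs.

## Known limitations

Exact matching only — no mismatches, so real (error-containing) reads
would under-map; the screen's length gate is a crude database surrogate;
the common-dispersion NB model underfits tagwise variability in real
libraries; the ping-pong z-score has no resampling confidence interval;
and printed z-scores from real libraries are not reproducible here
because they depend on the deposited sequencing data, not on the method.
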