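# pirnaflow

Desk-scale characterization of Piwi-interacting RNA (piRNA) populations,
built around the contrast between two tissue archetypes: a *somatic* (brain)
population dominated by genic, sense-biased piRNAs without ping-pong
amplification, and a *germline* (ovary) population dominated by
antisense-biased transposon piRNAs with a strong ping-pong signature.

The package is aimed at small-RNA analysts who want every stage of such an
analysis as inspectable, tested code — and at method developers who need a
fully synthetic, planted-truth test bed instead of a sequencing run.  It
implements:

- **Synthetic data with planted truth** (`pirnaflow.synthgen`): forged
  genomes whose canonical k-mers are globally unique (so exact mapping is
  unambiguous), with gene models (5′UTR/CDS/intron/3′UTR), LTR/LINE
  transposon copies, satellite loci, and a tRNA/rRNA/snRNA/snoRNA
  blacklist; simulated read populations with configurable category
  mixtures, strand bias, 23–29 nt length distribution, planted ping-pong
  pairs, and negative-binomial replicate counts with planted differential
  expression.
- **Exact mapping** (`pirnaflow.mapping`): a k-mer seed index with
  full-length verification, reporting all placements on both strands.
- **Candidate screening** (`pirnaflow.filters`): ncRNA blacklist removal,
  a 23–29 nt length gate, an optional sequence whitelist, and the
  minimum-pooled-count rule (total ≥ 10 across all samples).
- **Hierarchical categorization** (`pirnaflow.annotate`):
  transposon > satellite > genic > unannotated over all of a read's
  placements, with strand-sense calls and, for genic piRNAs, the
  exon/intron/5′UTR/3′UTR class by maximal overlap.
- **Strand bias** (`pirnaflow.strandbias`): length-by-strand spectra and an
  exact binomial test of the sense fraction against parity.
- **Ping-pong signature** (`pirnaflow.pingpong`): the 5′–5′ overlap
  histogram of opposite-strand read pairs and the z-score of the 10-nt
  overlap against the other overlap lengths,
  `z = (O(10) − mean(bg)) / sd(bg)`.
- **Differential expression** (`pirnaflow.de`): a two-group
  negative-binomial likelihood-ratio test (`Var = μ + φμ²`, shared
  dispersion, χ²₁ reference) with composition-robust size factors and
  Benjamini–Hochberg correction.
- **Antisense concordance** (`pirnaflow.concordance`): pairing of
  significant piRNAs with the significant DE genes they map antisense to,
  and the quadrant structure of the two fold changes.

## Worked example

Everything below runs from synthetic data in a few seconds; no downloads.

```python
from pirnaflow import synthgen, pipeline

genome = synthgen.build_genome(synthgen.GenomeSpec(seed=7))
res, profile, truth = pipeline.tissue_roundtrip(genome, "ovary", seed=1,
                                                n_reads=20000)

print(res.report.kept_n)                  # 17076 reads survive screening
print(res.composition.category_pct)       # transposon 93.8, genic 4.6, satellite 1.6
print(res.composition.genic_feature_pct)  # intron 65.0, utr5 17.4, exon 9.9, utr3 7.6
print(res.bias.sense_fraction)            # 0.387  -> antisense bias, p_parity ~ 0
print(res.pingpong.z)                     # 30.9   -> strong ping-pong signature
```

The numbers mean: of 19,632 unique simulated ovary-preset sequences, 17,076
pass the blacklist/length/min-count screen; 93.8% of the retained
read-weighted population maps to transposable elements (the preset plants
90% before ping-pong partners are added); the transposon piRNAs are
antisense-biased (sense fraction 0.387, exact binomial p ≈ 0); and the
10-nt 5′-overlap z-score of 30.9 reflects the planted 30% ping-pong
pairing.  The same call with the `"brain"` preset instead gives a genic-
dominated population (89.4% genic; exon 62.1%, 3′UTR 22.1%), a *sense*
bias (0.711), and no ping-pong signature (z = 0.22).

The same pipeline is scriptable from the shell:

```
pirnaflow demo --outdir demo --seed 1          # forge genome + 2x4 FASTQ samples
pirnaflow all --config demo/brain_config.yaml  # collapse->map->filter->assign->...
```

Subcommands `forge, simulate, collapse, map, filter, assign, spectrum,
pingpong, de, concord` expose each stage on files (TSV/BED6/FASTA/GFF3).

## Acceptance script

`scripts/acceptance.py` re-runs the full synthetic round trip from scratch
— forge the default genome, simulate 20,000 reads per tissue preset, push
them through collapse → map → filter → assign, and run the differential-
expression presets — and writes the measured composition and
direction-mixture percentages as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/pirnaflow/   library (one module per stage)
tests/           pytest suite, including planted-recovery acceptance tests
docs/methods.md  models, conventions, parameter defaults, limitations
scripts/         acceptance script
```
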