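# Methods

## Problem and model

A mosaic (post-zygotic) SNV is present in only a fraction of an
individual's cells, so in bulk sequencing it appears at a sub-heterozygous
allele fraction — exactly the regime where a site is hard to distinguish
from recurrent sequencing error or a mis-genotyped germline variant.
Linked-read sequencing provides the discriminating signal: the short reads
of one long DNA molecule share a barcode, molecules can be phased onto the
two assembled haplotypes through the heterozygous variants their reads
cover, and a true mosaic allele must then appear **only on reads of one
haplotype** (its molecules descend from the mutated cell lineage), whereas
sequencing errors scatter across both haplotypes at random.  Reads that
carry the candidate allele while their molecule is confidently assigned to
a haplotype are *haplotype-discordant reads*; they are the core evidence
unit of this caller.

The pipeline proceeds in six steps:

1. **Site scan** — every genomic position with sufficient data (depth,
   candidate-allele count, allele fraction inside a plausible mosaic
   window, phased-read fraction) becomes a candidate; positions already
   called as germline variants are excluded because they serve as
   training negatives.
2. **Spike-in** — synthetic mosaic variants are introduced *in silico*
   into the sample's own pileups at hom-ref positions: a target haplotype
   and target MAF are chosen, and whole molecules (never individual reads)
   on that haplotype are switched to the mosaic allele with probability
   min(1, 2·MAF) (unassigned molecules with probability MAF).  Editing at
   molecule granularity is what reproduces the haplotype-discordant
   signature in the training data; the 2·MAF factor makes the expected
   allele fraction over *all* reads equal the target in a balanced diploid
   pileup.
3. **Training** — a random forest of 100 trees is fit on the spiked
   positives against real het/hom-alt germline sites as negatives, using
   the sample's own data, so the model adapts to the library's depth,
   error and phasing characteristics.
4. **Scoring** — every candidate site is scored with the forest's
   positive-class probability (its resemblance to the synthetic mosaic
   sites).
5. **Region filters** — calls in user-supplied masks (repeats, segmental
   duplications, non-diploid copy-number intervals) are labelled, never
   deleted: filter provenance is preserved per call.
6. **Alignment-error filter** — a heuristic veto against misalignment
   artifacts (see below), plus the discordant-read floor: a PASS call
   needs at least 4 haplotype-discordant reads by default.

### Phasing details

Molecules are reconstructed by grouping reads that share a barcode,
splitting a barcode into separate molecules when consecutive reads are
more than `max_gap` = 50 kb apart (standard molecule-reconstruction
practice; barcodes recur across distant loci by design of the library).
Each molecule votes at every phased het its reads cover with base quality
≥ 20: a base matching the haplotype-1 allele votes H1, the haplotype-2
allele H2, anything else abstains; a het covered by both mates counts
once, the higher-quality base winning.  Assignment is by strict majority;
ties are unassigned (never random).  H1/H2 labels are only comparable
within one phase set, so votes are kept per phase set, and at a candidate
site only the votes in the phase set local to that site (the phase set of
the nearest het) count — a molecule spanning a phase-set boundary cannot
leak labels across it.

Three model variants differ only in how reads are assigned:

* **full** — a read inherits its long molecule's haplotype;
* **short_only** — the "molecule" is redefined as the read pair, so a
  read is assigned only when its own pair overlaps a phased het (this
  quantifies what paired-end data alone could do);
* **no_phasing** — all reads unassigned; the model uses only the
  site-level features.

One consequence worth stating: the invariant *phased_fraction(short_only)
≤ phased_fraction(full)* holds exactly on error-free data, because pair
votes are then a subset of molecule votes.  With base errors a conflicted
molecule can tie its votes overall while one of its pairs has a local
majority, so rare violations are possible; the property test asserts the
ordering in the error-free regime.

### Features

The feature list is this package's own (the three families — read
quality, phasing, linked-read characteristics — are fixed; their exact
realization is versioned inside the model artifact, and scoring refuses a
mismatched list).  Site-level features (all modes): depth; MAF; mean/SD
base quality and mean mapping quality for candidate vs other reads;
candidate strand fraction; mean normalized position-in-read; soft-clip
fraction; mean per-read mismatch count excluding the candidate base.
Fragment-level features (full, short_only): phased fraction; candidate
read counts and fractions per haplotype; discordant-read count; haplotype
concentration (majority-haplotype share of assigned candidate reads: 1.0
is the mosaic signature, ~0.5 the error signature); candidate allele
fraction on the majority haplotype; number of distinct candidate-carrying
molecules; mean het votes per candidate molecule.  Undefined ratios are
encoded as 0 plus a 0/1 presence indicator, keeping every value finite
without NaN handling inside the forest.

### Alignment-error heuristic

The step-6 filter fails a call when candidate reads look misaligned:
fraction with a soft-clip ≥ 5 bp exceeding 0.5; mean mismatches per
candidate read (candidate base excluded) exceeding 3; improperly-paired
fraction exceeding 0.5; or the site lying in a reference homopolymer run
≥ 10 bp.  All four thresholds are configurable and the per-call
diagnostics are reported.  This is a summary heuristic, not a
realignment.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| site scan: min depth / candidate reads | 16 / 2 | lets a 30X library pass comfortably while suppressing singleton errors |
| site scan: MAF window | [0.03, 0.75] | below: indistinguishable from error; above: germline het/hom territory |
| site scan: min phased fraction | 0.25 | waived in no_phasing mode (identically 0 there) |
| mapq / base-quality floors | 30 / 20 | conventional uniqueness and error floors |
| molecule split gap | 50 kb | standard linked-read molecule reconstruction |
| forest size | 100 trees | the pipeline's stated ensemble size |
| forest depth / features per split | unlimited / sqrt | common defaults, recorded in the artifact |
| training set | balanced 1:1, negatives split evenly het/hom-alt | balanced classes keep the 0.5 score threshold interpretable |
| spike-in MAF | U(0.05, 0.5] | covers the detectable mosaic range |
| score threshold | 0.5 | natural operating point for balanced training |
| discordant-read floor | 4 | the caller's stated default; relaxing it trades precision for recall |
| deep validation | ≥ 50 reads, ≥ 4 alt | the orthogonal-validation rule |

## The simulator

`simdata` generates the study conditions end to end: a random reference; phased
hets at rate 1e-3/bp (plus hom-alts at 5e-4/bp so the negative class has
both genotypes); mosaic sites at hom-ref positions ≥ 300 bp apart, each
on one haplotype with MAF cycled through {0.1, 0.2, 0.3, 0.4}; lognormal
molecule lengths with mean 16,176 bp and SD 54,387 bp (a heavy-tailed fit
to typical linked-read libraries) sequenced internally at 0.1-fold by
100 bp proper pairs (insert 350 ± 50); i.i.d. base errors at 0.002; 30X
total coverage.  A molecule from the mosaic haplotype at a mosaic locus
descends from a mutated cell with probability 2·MAF, in which case *all*
its reads covering the locus carry the allele.  Reads are written with
their true coordinates into a sorted, indexed BAM with BX tags; germline
truth is written as a phased VCF.

What the simulator deliberately does **not** model: aligner behaviour
(reads carry true coordinates, isolating caller logic from alignment
artifacts), cycle- or context-dependent error profiles, GC bias, chimeric
molecules, barcode collisions, CNVs, and indels.  Passing tests therefore
demonstrate the correctness of the phasing/training/calling machinery and
its behaviour under sampling noise — not robustness to real alignment
error, which is exactly what the step-5/6 filters and the masks exist
for on real data.  Benchmark numbers on this synthetic substrate are
systematically more favourable than on real genomes.

## Benchmark problem sizes

The packaged simulation study (`samovar_lr.benchmark.run_benchmark`, also
driven by `scripts/acceptance.py`) uses a 2 Mb region at 30X (~600,000
reads), 200 mosaic truth sites, and 200 spike-in positives + 200 germline
negatives for training, with spike-ins kept ≥ 1 kb from every truth site
so training and evaluation sites are disjoint.  Recall is reported
against truth sites with ≥ 4 written alt reads (alongside the
all-truth denominator): a site the sequencer never covered with 4 alt
reads is unrecoverable by a caller that requires 4 discordant reads.
Unit tests use 150–300 kb regions with the same per-base rates.

## Numerical and degenerate-input choices

* All internal coordinates are 0-based half-open; conversion happens only
  at the VCF/SAM file boundary.
* Candidate allele at a site: most frequent non-reference base, ties
  broken alphabetically (deterministic).
* Duplicate, secondary and supplementary reads are kept in the data model
  but excluded from depth and allele counts.
* Zero-depth sites: MAF and phased fraction are 0; spike-ins at such
  sites are skipped with a warning; training positives whose post-edit
  pileup fails the site filter are dropped and logged.
* Candidates scoring below threshold stay in the output labelled
  `low_score`, so every scored candidate appears exactly once with full
  filter provenance.
* Seeds: the CLI splits one global seed into per-stage seeds by hashing
  stage names (CRC32), so stages are individually reproducible; identical
  seeds yield byte-identical model artifacts and VCFs.

## Known limitations

SNVs only (no indels — they would need indel-specific features to
separate true events from alignment noise); autosomal diploid assumption
(no sex-chromosome ploidy handling); two haplotypes per phase set; no
CRAM; the exact feature list and scan thresholds are this package's
declared choices, configurable rather than claimed canonical.
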