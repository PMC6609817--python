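# samovar-lr

Single-sample mosaic SNV calling for linked-read whole-genome sequencing.

## What it does, and for whom

A mosaic SNV arises after fertilization and is therefore carried by only a
fraction of an individual's cells: in bulk sequencing it shows up at a
minor allele fraction (MAF) well below the heterozygous 0.5, where it is
easily confused with sequencing error.  Detecting such variants has
traditionally required a matched tumor/normal pair or a trio.  Linked-read
libraries offer a single-sample alternative: the short reads of one long
DNA molecule (tens of kb) share a molecular barcode (`BX` tag), molecules
can be phased onto the two assembled haplotypes H1/H2 via the phased
heterozygous variants their reads cover, and a true mosaic allele must
then sit on reads of **one** haplotype only — its molecules descend from
the mutated cell lineage — while sequencing errors scatter evenly across
both.  Reads carrying the candidate allele on a confidently phased
molecule are *haplotype-discordant reads*, the caller's core evidence.

The tool is aimed at anyone with barcoded linked-read alignments (BAM with
`BX` tags) and a phased germline VCF — the standard outputs of a
linked-read preprocessing pipeline such as Long Ranger — who wants mosaic
SNV calls from that single sample.

## The method in brief

For a candidate site with allele counts split by haplotype, the caller
works in six steps: (1) scan for sites with sufficient data (depth,
candidate reads, MAF ∈ [0.03, 0.75], phased-read fraction); (2) build
sample-specific training positives by *spiking in* synthetic mosaic
variants: at a hom-ref site with target haplotype h and target MAF m,
each molecule assigned to h is switched to the mosaic allele with
probability min(1, 2m) — whole molecules, never single reads, so the
haplotype-discordant signature is reproduced faithfully; (3) train a
100-tree random forest against real het/hom-alt germline sites as
negatives; (4) score all candidates with the forest's positive-class
probability; (5) label calls inside repeat/CNV masks; (6) veto
alignment-error signatures and require ≥ 4 haplotype-discordant reads.
The key discriminating feature is the *haplotype concentration* — the
majority-haplotype share among phased candidate reads: 1.0 is the mosaic
signature, ≈ 0.5 the error signature.

Three model variants quantify the value of the linked reads: `full`
(molecule-level phasing), `short_only` (phasing from read pairs alone)
and `no_phasing` (site-level features only).

A built-in simulator (`samovar-lr simulate`) generates a diploid region
with phased hets, heavy-tailed long molecules (mean 16,176 bp, SD
54,387 bp) sequenced internally at 0.1-fold by barcoded read pairs, base
errors, and mosaic truth restricted to one haplotype — so the entire
pipeline is testable with no external data.

## Worked example

Simulate 500 kb at 30X with 50 mosaic sites, train on 200 spike-ins that
avoid the truth sites, call, and evaluate:

```bash
cat > sim.cfg <<EOF
region_length = 500000
n_mosaic = 50
seed = 42
EOF
samovar-lr simulate --out-dir sim --config sim.cfg
samovar-lr train --bam sim/reads.bam --vcf sim/germline.vcf --ref sim/ref.fasta \
    --region chrS --out model.pkl --n-pos 200 --n-neg 200 --seed 7 \
    --exclude-tsv sim/mosaic_truth.tsv
samovar-lr call --bam sim/reads.bam --vcf sim/germline.vcf --ref sim/ref.fasta \
    --region chrS --model model.pkl --out calls.vcf
samovar-lr evaluate --calls calls.vcf --truth sim/mosaic_truth.tsv --min-support 4
```

The `call` step prints its stage report:

```json
{
  "mode": "full",
  "n_candidates": 346,
  "n_scored": 346,
  "n_pass": 36,
  "n_fail_low_score": 0,
  "n_fail_min_discordant": 310,
  "n_fail_alignment_error": 0
}
```

346 sites had enough data to score; 310 of them (mostly recurrent
sequencing errors) lacked the 4 haplotype-discordant reads a PASS call
requires, leaving 36 calls.  `evaluate` then reports:

```json
{
  "precision": 1.0,
  "recall": 0.923,
  "f": 0.96,
  "tp": 36, "fp": 0, "fn": 3,
  "denominator": "support>=4"
}
```

All 36 PASS calls are true mosaic sites, and 36 of the 39 truth sites
that the sequencer actually covered with ≥ 4 alt reads were recovered
(the `--min-support 4` denominator: a site with 3 alt reads in the data
cannot be called by a caller requiring 4 discordant reads).  A typical
PASS record in `calls.vcf`:

```
chrS  21539  .  A  G  .  PASS  SCORE=0.98;MAF=0.210526;DP=38;DISC=8;HAP=H1
```

— a candidate at MAF 0.21 with 8 discordant reads, all concentrated on
haplotype H1.

The same pipeline is scriptable from Python (`simulate_dataset`,
`RegionPileup`, `select_training_sites`/`train_model`, `call_variants`,
`precision_recall`); the `examples/` directory walks through each
capability.

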