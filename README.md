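# haplobin

Haplotype-resolved assembly of a heterozygous diploid requires deciding,
for every long read or assembly unitig, which of the two parental
haplotypes it came from. Aligning reads to a haploid reference biases this
decision toward the haplotype that resembles the reference; `haplobin`
instead implements the alignment-free route: bin sequences by
**haplotype-specific k-mers** derived from phased variants, so both
haplomes come out balanced even at high heterozygosity (one SNV per 20 bp
and beyond). It is written for assembly practitioners working on
outcrossing plant genomes and similar highly heterozygous material.

The package covers the bespoke computational stages around an assembly
workflow — everything between variant phasing and scaffolding:

- **`haplobin.simdip`** — synthetic diploid genomes, mosaic haploid
  references, phased VCFs with injectable phase-flip errors, and
  error-bearing long reads, all with complete ground truth.
- **`haplobin.kmerlib`** — canonical k-mer counting and presence/absence
  subtraction (a k-mer is canonical when it is the lexicographic minimum
  of itself and its reverse complement).
- **`haplobin.hapconsensus`** — haploid reference + phased VCF → the two
  haplotype consensus sequences (heterozygous, biallelic sites with
  MQ ≥ 20 and DP ≥ 10).
- **`haplobin.sortbin`** — three-way classification of reads/unitigs into
  haplotype 1 / haplotype 2 / unassigned, plus the 50 kb ultra-long read
  filter and partition reports.
- **`haplobin.purge`** — allelic-contig pairing from three evidence lines
  (alignment coverage, micro-synteny with >5 shared collinear genes,
  ≥1 shared single-copy ortholog) and redundancy purging with
  duplication/loss metrics.
- **`haplobin.phaseval`** — phasing-quality statistics: per-1 Mb-window
  non-reference allele ratios, the phase-switch-rate estimate, phase-block
  statistics, longest-block selection, and discordance between two
  phasings.
- **`haplobin.hapcompare`** — cross-haplome 27-mer coverage repeat
  masking, alignment filtering presets, and CIGAR decomposition of
  between-haplome alignments into SNV / INDEL (<50 bp) / PAV (≥50 bp) /
  soft-clip categories with per-alignment identity.

## The core statistic

For each haplotype *h* with consensus sequence *H_h*, the specific k-mer
set is

    S_h = K21(H_h) \ K21(H_other)

where `K21(·)` is the canonical 21-mer set. A query sequence *q* scores

    score_h(q) = |{windows of q whose canonical 21-mer ∈ S_h}| / |S_h|

and is labelled `hap1` if `score_1 > score_2`, `hap2` if
`score_2 > score_1`, and `unassigned` on a tie (including 0–0).
Normalising by |S_h| compensates for unequal divergence of the two
haplotypes from the reference.

Per-alignment identity in the between-haplome comparison is

    identity = matched bases / (matched + mismatched + inserted + deleted + soft-clipped bases)

with insertions/deletions ≥ 50 bp counted as PAVs, and terminal soft
clips ≥ 50 bp counted as PAVs as well.

## Worked example

Simulate a two-chromosome diploid at one heterozygous SNV per 20 bp, build
consensus haplotypes from its phased VCF, extract haplotype-specific
21-mers and bin 1,000 noisy (10% error) long reads:

```sh
haplobin simulate --outdir sim --seed 42 --n-chromosomes 2 \
    --chrom-length 200000 --snv-rate 0.05 --n-switches 0 \
    --n-reads 1000 --read-length-mean 8000 --error-rate 0.1
# wrote 20140 variants, 1000 reads to sim

haplobin consensus --ref sim/reference.fasta --vcf sim/phased.vcf --out-prefix cons
# applied 20140 variants (0 outside the designated phase blocks)

haplobin kmers --hap1 cons_hap1.fasta --hap2 cons_hap2.fasta -k 21 --out-prefix spec
# hap1-specific: 272281 k-mers; hap2-specific: 272280 k-mers

haplobin bin --reads sim/reads.fastq --spec1 spec_hap1.txt \
    --spec2 spec_hap2.txt --outdir bins
# {
#   "hap1": 51.220206480788725,
#   "hap2": 48.779793519211275,
#   "unassigned": 0.0
# }
```

The 20,140 phased SNVs yield ~272 k specific 21-mers per haplotype (each
SNV contributes up to 21, minus chance collisions). The binning summary
shows the percentage of read **bases** per bin: the two haplomes come out
balanced (51.2% vs 48.8% is sampling noise at 1,000 reads), with nothing
unassigned because at this SNV density every read overlaps many
haplotype-specific 21-mers. `bins/binning.tsv` holds per-read hit counts
and scores; `sim/truth.tsv` holds the simulator's ground truth for
checking them.

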