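# Methods

## Problem setting

A diploid individual carries two haplotypes per chromosome. Given a
haploid reference, a phased VCF of heterozygous variants, long reads, and
a primary (partially redundant) assembly, the stages implemented here
(1) reconstruct the two haplotype consensus sequences, (2) extract the
k-mers unique to each haplotype, (3) bin reads/unitigs by those k-mers,
(4) purge allelic duplicates from a primary assembly, (5) quantify
phasing quality, and (6) categorise the sequence differences between the
finished haplomes. Variant calling, phasing itself (HapCUT2/WhatsHap
class tools), alignment, assembly and scaffolding are out of scope; their
outputs are inputs here.

## Models and procedures

### Canonical k-mers (`kmerlib`)

A k-mer is identified with its reverse complement; the canonical form is
the lexicographic minimum of the pair. K-mers are packed 2 bits/base into
uint64 (k ≤ 32; the binning and coverage defaults are k = 21 and k = 27),
sets are stored as sorted code arrays so membership tests and subtraction
are vectorised `searchsorted` operations. Any window containing a
non-ACGT symbol is skipped entirely. Subtraction uses presence/absence
semantics — haplotype specificity is a membership question, so counts in
the subtrahend are ignored. No count floor is applied to specific k-mers
by default (`min_count=1`); a floor is exposed for noisy inputs.

### Consensus haplotypes (`hapconsensus`)

Sites are filtered to biallelic heterozygous records with site mapping
quality ≥ 20 and depth ≥ 10 (both inclusive); records missing either
annotation are rejected with a warning rather than an error. Only records
in the designated chromosome-level phase set per chromosome are applied
(small residual blocks cannot be integrated and are counted, not
applied); by default that set is the one with the greatest genomic span,
ties broken by site count then smallest phase-set id. Alleles are
substituted left-to-right with a running coordinate offset; every REF
allele is checked against the reference and overlaps are errors. SNV-only
application is the default in the CLI since phasing pipelines primarily
phase SNPs; indel application is supported (`--with-indels`). The
round-trip validator re-derives the inter-haplotype differences by
coordinate walk: blind position scan for SNV-only inputs (exact
recovery), guided walk with left-normalised alleles for mixed inputs.

### Binning (`sortbin`)

Hit counts are occurrence counts: a specific k-mer seen twice in a read
contributes 2, since longer shared spans carry more evidence. Scores are
normalised by specific-set size to correct for unequal haplotype
divergence. Ties in the normalised score — including zero hits on both
sides — are conservatively unassigned. No absolute minimum hit count is
required by default (`--min-hits` exposes one). The partitioner can
append unassigned records to both haplotype files (`--unassigned-to-both`)
for downstream per-haplome assembly; the report always counts them once,
as unassigned. The ultra-long filter keeps reads ≥ 50,000 bases
(inclusive).

### Allelic purging (`purge`)

Three parallel evidence lines form edges between contigs:

- **synteny**: more than 5 (strict) shared genes lying in a collinear
  run. Collinearity is made explicit (the usual external synteny tools
  leave it implicit): shared genes ordered along one contig must appear
  in the same or fully reversed order on the other, allowing up to 5
  intervening shared genes between consecutive chain members; the chain
  is found by quadratic DP, adequate at contig scale.
- **marker**: at least 1 shared single-copy ortholog (BUSCO-class gene).
- **alignment**: merged alignment intervals cover ≥ `min_coverage_fraction`
  (default 0.5) of the shorter contig of a pair, from PAF input.

Any single evidence type suffices (`--require-n-evidences` intersects).
Within each connected component of the resulting graph exactly one contig
is kept — the longest, ties broken by lexicographically smaller id — and
the rest are purged with a logged decision. Keeping one contig per
component is the policy even for components larger than two, which keeps
the result identical to a connected-components + argmax oracle and makes
purging idempotent. A purge is successful when the duplicated-marker rate
is strictly below 10% of retained markers and the distinct-marker loss is
strictly below 5%.

### Phasing evaluation (`phaseval`)

Windows tile each chromosome from position 0 (default 1 Mb; the last,
partial window is kept if it has ≥ 1 site). The per-window non-reference
allele ratio r is the fraction of phased sites at which the chosen
haplotype carries ALT. When the sample's haplotype is known to match or
oppose the reference chromosome-wide (doubled-haploid reference), r near
0 or 1 indicates correct phasing, and the **switch-rate estimate** is the
median over windows of the folded ratio min(r, 1−r). Folding makes the
estimator invariant to which haplotype matches the reference and to
global flips; the unfolded mode reproduces the oriented statistic.
Windows with zero sites are excluded, not imputed — switches concentrate
where SNP density is low, and imputing 0 there would bias the median
down. Chromosome selection (avoiding recombination and long homozygous
runs) is the caller's responsibility. Phase blocks are groups of sites
sharing a PS tag; block span is last − first site position. Two phasings
are compared on sites matched by (chrom, pos, ref, alt) after per
chromosome global orientation of the second to the first (the orientation
minimising mismatches), which makes the discordance count symmetric and
flip-invariant.

### Between-haplome comparison (`hapcompare`)

Cross-haplome coverage assigns to each position the source-multiset count
of the canonical 27-mer starting there; positions without a valid start
(trailing k−1 bases, windows touching N) inherit the last valid start's
count, and N bases themselves get 0. Repetitive sequence is coverage ≥ 2
(self mode, source == target, uses the same rule). Masking to N, BED
extraction of masked and unmasked runs, and per-window
repetitive/nonrepetitive/N base counts follow; the three categories sum
to the window length by construction, and overlapping input BEDs are an
error.

CIGAR decomposition requires extended operators (=/X; an ambiguous M is
an error advising `--eqx`). Categories: `=` match; `X` SNV; I/D runs
< 50 bp small indel, ≥ 50 bp PAV; `S` soft-clip, additionally counted as
a PAV event when ≥ 50 bp. Soft-clip bases are tallied once (in the
soft-clip category) so that match + SNV + indel + internal-PAV +
soft-clip = total exactly; identity = match/total. Hard clips are
ignored (the alignment commands this consumes do not produce them).
Alignment filtering uses the query span uniformly as "length"; presets:
`synteny` (≥ 2 kb, MQ ≥ 60), `dotplot` (≥ 2 kb, MQ > 0), `unitig`
(≥ 100 bp, MQ ≥ 50), all bounds at their printed strictness.

## Synthetic data (`simdip`)

The generator emulates a highly heterozygous outcrossing grass genome at
desk scale: 7 chromosomes by default (a 2n = 14 karyotype), heterozygous
SNVs at 0.05/bp (one per 20 bp), optional small indels (< 50 bp), PAVs
(≥ 50 bp, modelled as presence in one haplotype/absence in the other),
and planted identical multicopy repeats. Haplotype 1 is the coordinate
baseline; haplotype 2 is derived by applying the sampled variants, which
are placed by rejection sampling without overlap so the truth is never
ambiguous. Event counts are binomial in (length, rate). The mosaic
reference alternates haplotype blocks at uniform switch points that never
split a variant's reference span. The emitted VCF (1-based, `GT|` with
one PS per chromosome, MQ=60/DP=30 annotations) flips each site's phase
independently with probability `switch_error_rate` and records every flip
position. Reads are sampled evenly from both haplotypes and strands;
lengths are log-normal with sigma 1.3 on the log scale — chosen so the
length-weighted median (N50) is ~2–3× the mean, the shape typical of
long-read datasets — clipped to [min, max] and the chromosome length.
Errors are applied per base at a flat rate with a 60:20:20
substitution:insertion:deletion split, a generic long-read profile.
`depth` targets total read bases = depth × diploid genome size, i.e.
~depth-fold coverage of each haplome.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: non-uniform heterozygosity
(regions of low SNP density are where real phasing and binning fail),
divergent repeat families and segmental duplications, coverage and GC
biases, chimeric reads, and base-quality structure. In particular,
because het sites are uniform at 1/20 bp, every simulated read of ≥ 1 kb
overlaps abundant specific k-mers and the unassigned bin stays empty,
whereas real datasets leave a few percent of reads unassigned in
SNP-poor regions.

## Numerical and design choices

- All internal coordinates are 0-based half-open; VCF I/O is 1-based.
- Determinism: every stochastic operation takes an explicit seed
  (numpy `default_rng`); identical seed + config gives byte-identical
  outputs.
- Degenerate inputs: empty sequences bin as unassigned with zero hits;
  k longer than every sequence yields an empty k-mer set (not an error);
  an empty binning table, empty alignment list, or a phasing comparison
  with no shared sites are errors.
- Tie-breaks are always explicit: binning ties → unassigned; purge ties →
  lexicographically smaller contig id; phase-block ties → site count,
  then smaller PS id.
- Problem sizes in the test suite (7 × 1 Mb genomes, 2,000 reads,
  20-seed Monte-Carlo runs with 3,000 sites per window) are chosen so
  binomial/Monte-Carlo tolerances are tight while the whole suite runs on
  a single CPU in minutes; the switch-rate recovery grid uses
  snv_rate 0.02 over 150 kb chromosomes so ε·n is integral for the
  tested ε values and the median of the window ratio is unbiased at the
  asserted precision.

## Known limitations

- In-memory k-mer hashing only; genome-scale counting (KMC/Jellyfish
  territory) is a non-goal.
- The collinearity DP is O(n²) in shared genes per contig pair.
- Indel round-trip validation normalises alleles by prefix/suffix
  trimming only; fully realigned normalisation is out of scope.
- Unassigned-bin behaviour on real, unevenly heterozygous genomes is not
  reproduced by the uniform-rate simulator (see above).
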