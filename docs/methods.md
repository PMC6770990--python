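# Methods

## The k-mer spectrum model

Shotgun reads of a diploid genome, chopped into overlapping k-mers and
counted canonically (each k-mer identified with its reverse complement),
produce a depth histogram with a reproducible anatomy:

* a spike at depth ~1 from sequencing errors — almost every error creates
  up to k novel k-mers seen once;
* a heterozygous peak **α** near half the sequencing depth: a SNP splits
  the k-mers spanning it into two haplotype-specific variants, each
  sampled from only one of the two haplotypes;
* a homozygous peak **β** at the full k-mer depth, formed by single-copy
  sequence shared by both haplotypes;
* a high-depth tail from repeats, whose shared k-mers accumulate the
  coverage of all their copies.

From the landmarks of this histogram the package derives, without any
assembly:

| quantity | formula | meaning |
|---|---|---|
| base coverage | `N = M·L/(L−k+1)` | k-mer depth M corrected for the L−k+1 windows per read of length L |
| genome size | `G = T/N` | total sequenced bases over per-base coverage |
| single-copy size | `SC = Σ_{c=lo}^{hi} c·freq_c / B` | unique-region spectrum area divided by the β depth B |
| repeat fraction | `1 − SC/G` | complement of the single-copy fraction |
| heterozygosity | `1 − (1 − H)^{1/k}`, `H = A_α/(A_α + 2A_β)` | per-base SNP rate from the α/β distinct-k-mer areas |

The heterozygosity mapping follows from counting: a k-mer overlapping a
heterozygous site contributes **two** distinct entries to the α area
while a homozygous k-mer contributes one to the β area, so the fraction
of k-mer loci that are heterozygous is `H = A_α/(A_α + 2A_β)`, and a
per-base rate h makes a k-mer heterozygous with probability
`1 − (1 − h)^k`; inverting gives the estimator. The raw peak-height
ratio α/β is reported as well, since it is the directly observable
quantity proportional to heterozygosity.

### Numerical choices

* **M is the β mode, not the spectrum mean.** The error spike dominates
  the mean; the mode is robust. Ties in the argmax resolve to the
  smaller depth so output is deterministic.
* **Sub-bin refinement of β.** The histogram bins depth to integers; at
  modest coverage (B ≈ 50) an integer mode can bias N by ~1%, a
  noticeable share of the genome-size error budget. The reported M is
  the vertex of the parabola through the smoothed spectrum at
  (B−1, B, B+1), which recovers the continuous peak position to well
  under a tenth of a bin for the near-Gaussian peaks this data produces.
* **Smoothing.** A centered moving average (default window 3 bins) is
  applied before extremum detection only; all area sums (SC, A_α, A_β)
  use raw bins.
* **Error cutoff** is the first depth > 1 at which the smoothed spectrum
  stops decreasing (the local minimum between the error spike and the
  genomic peaks). A spectrum that never stops decreasing has no genomic
  peak and raises an error rather than returning nonsense.
* **α acceptance threshold.** α is the largest local maximum in
  [0.35 B, 0.65 B], but a candidate below 1% of the β height is rejected:
  in a fully homozygous sample the Poisson left tail of β contains bins
  of 1–2 distinct k-mers that would otherwise masquerade as a peak. Real
  heterozygous signal sits far above this (0.14% heterozygosity at k=19
  yields an α/β height ratio around 14%).
* **SC bounds** default to [0.5 B, 1.5 B]. The classic fixed window
  [150, 450] corresponds to exactly these multiples for a spectrum
  peaking at 300; relative bounds generalize to any coverage. Both
  bounds are exposed as parameters. Note the lower bound deliberately
  includes the α peak, so heterozygous single-copy sequence is counted
  as single-copy.
* **Overflow bin.** Depths above `max_depth_bin` (default 10,000)
  accumulate in one bin; all profiling happens at depths ≤ ~3 B, far
  below it at any realistic coverage.
* The counter packs k-mers into 2-bit codes (k ≤ 31 in a uint64),
  assembles window codes by binary doubling (O(log k) vector passes) and
  counts by sort + run-length encoding. Windows containing a non-ACGT
  symbol are skipped, never substituted; input is case-insensitive.

## What the simulator emulates — and what it does not

`synthesize_diploid` builds a haploid sequence as unique background
(i.i.d. bases at a target GC, default 41%) interleaved with repeat
copies: `n_repeat_families` random seed units (default 20 × 500 bp) are
copied until the requested repeat fraction (default 45%) is met, each
copy independently mutated at `repeat_copy_divergence` (default 0.5%,
i.e. young, homogeneous families whose copies share ~91% of their
19-mers). Gap lengths between copies are drawn from a multinomial, so
the realized repeat fraction matches the request to within one repeat
unit. The second haplotype differs by i.i.d. substitutions at
`het_rate` (default 0.14%). `simulate_reads` draws read pairs
uniformly, 50/50 from either haplotype, with normal insert sizes and
i.i.d. substitution errors (default 0.2%). Identical seeds give
byte-identical FASTA/FASTQ.

Deliberately **not** modelled: indels and structural variation,
technology-specific error profiles, GC coverage bias, chimeric pairs,
nested/truncated transposons, tandem-repeat expansion. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions (substitution-style
heterozygosity, uniform coverage), not robustness to every artifact of
real libraries. The defaults are the study conditions used by the
acceptance checks: a 2 Mb genome at 60× with 150 bp reads.

With 0.2% errors only `(1−0.002)^19 ≈ 96%` of read 19-mers are
error-free, which deflates the β depth and inflates G by ~4%; the same
dilution affects real pre-trimmed libraries, which is one reason k-mer
genome sizes carry a few percent of systematic uncertainty (the
estimates across k ∈ {17, 19, 21, 31} spread by ~3% on the synthetic
data for the same reason).

The simulator also provides `synthesize_gene_set`: a synthetic annotated
contig of 20 single-transcript genes — 12 clean, plus deliberate
violations of each structural filter rule (short CDS, broken frame,
missing start, missing stop, internal stop), mixing strands and
single/two-exon structures — used as the ground truth for the
annotation filter.

## Assembly metrics

Nx is "the length of the record at which the cumulative sum of
descending-sorted lengths first reaches x% of the total", ties
included; L50 is the number of records needed to reach 50%. Scaffolds
are split into contigs at runs of ≥ `min_gap_run` N (default 10, the
common gap convention; the threshold is a flag because annotation
pipelines differ). GC is computed over non-N bases only, with other
IUPAC ambiguity codes counted as non-GC non-N and tallied separately;
ungapped length excludes every N. Printed-style percentages round
half-up to the conventional precision (GC two decimals, ungapped share
one decimal).

## Gene-model filter

The spliced CDS is extracted by concatenating CDS segments in genomic
order, reverse-complementing for minus-strand models, and trimming the
phase of the transcription-first segment. The terminal stop codon is
treated as part of the CDS. Rules run in a fixed order — minimum length
(default 150 nt), frame (length divisible by 3), start codon ATG, stop
codon, no internal in-frame stop — and each removed model is attributed
to the first rule it fails, making reports deterministic; the frame rule
is a prerequisite of the codon tests. Filtering is per transcript; a
gene survives if at least one transcript does. Standard genetic code
only. Completeness summaries compute per-category percentages
(half-up, two decimals) from supplied counts and flag category sums
that do not reconcile with the stated total instead of guessing which
categories nest.

## Comparison operation

`pearson_correlation` is the sample Pearson coefficient with a
two-sided p-value from the t-distribution on n−2 degrees of freedom
(delegated to scipy). The bundled comparison table carries the three
published Percidae assemblies; larger cross-species tables are supplied
by the user as TSV. On three points a correlation is computable but
fragile — the operation is an analysis tool, not a claim about
Perciformes genome evolution.

## Problem sizes

Validation runs use genomes of 0.05–2 Mb and coverages of 25–60×: large
enough that the β peak is well separated from the error spike and
Poisson noise on bin heights is a fraction of a percent, small enough
for routine re-runs. Recovery tolerances (genome size within 5%, repeat
fraction within ±0.10, heterozygosity within a factor of two) reflect
the systematic biases discussed above, not measurement noise.

## Known limitations

* The profiler assumes a diploid, moderately heterozygous genome with a
  unimodal homozygous peak; higher ploidies and mixed samples are out of
  scope, as is full mixture-model fitting of the spectrum.
* Genome-size estimates inherit the error-dilution bias above; the
  package reports what the formulas give and does not attempt an error
  correction.
* The counter holds all window codes in memory (~8 bytes per read base);
  inputs beyond a few hundred Mbp of reads should be counted in slices
  and merged via `KmerCountTable`s.
* Histogram-level merging is exact only for disjoint k-mer sets; merge
  count tables when combining read files of one library.
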