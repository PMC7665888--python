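# Methods

This note records the models, parameter choices and numerical conventions
behind `ribopause`, and what the synthetic benchmarks do and do not
demonstrate.

## Coordinate and data conventions

All coordinates are 0-based, half-open, in transcript space; conversion to
1-based happens only at the SAM boundary. A footprint is
(read_id, transcript_id, five_prime_pos, length); libraries are data frames
with those columns. Per-transcript A-site counts live in a
`CodonCountMatrix` whose invariant (counts sum to total reads) is enforced
at construction. Every filtering step returns a `StageStats` record whose
constructor enforces input = retained + discarded, so conservation is not an
afterthought but a type-level property.

## The synthetic experiment

The generator emulates the translatome of a tRNA-deficiency model organism:
two genotypes ("control", "mutant"), three biological replicates each, one
transcript per gene so ground truth is unambiguous.

**Transcripts.** Each of `n_genes` (default 500) transcripts is
5′UTR (30 nt) + ATG + body + stop + 3′UTR (30 nt), with body length uniform
in 150–300 codons and body codons i.i.d. from a configurable usage vector
over the 61 sense codons (uniform by default — downstream statistics are
usage-agnostic, and uniform usage gives every codon identity comparable
sampling depth). Stop codons cannot occur inside the body by construction.
The fixed 30 nt UTRs give the metagene calibration flanking sequence.

**Footprints.** Reads are allocated to genes multinomially with weight
(RNA mean) × 2^(TE offset) × (body codons), each weight multiplied by a
Gamma(1/α, α) factor so per-gene footprint counts are overdispersed across
replicates like real libraries. Within a gene, A-site codon positions are
drawn multinomially over the decoded codons (indices 1 … n−2; the start
codon never occupies the A-site of an elongating ribosome and the stop codon
is decoded by release factors) with dwell weight w_c per instance. Two
positional effects are layered on the identity weights:

* an **initiation peak**: the first decoded codon's weight is multiplied by
  `init_dwell_multiplier` (default 5). Initiation is slow and
  elongation-arrested libraries universally show a 5′ peak; it is also what
  makes modal-offset calibration well-posed — without it the 5′-end
  distribution upstream of start codons is flat and the mode is a
  sampling-noise lottery.
* **implanted pauses**: in the mutant condition each gene independently (per
  replicate) receives, with probability p (default 0.5), a k-fold
  (default 50) dwell elevation at one uniformly chosen AGA instance. Genes
  selected but lacking any AGA are logged and skipped. Implantation is drawn
  for every gene regardless of its read count, so ground truth does not
  depend on sampling depth.

Read length is drawn from a 26–34 nt distribution peaked at 29–33, and the
5′ end is placed at (A-site nt) − true_offset(length), with offsets 15–17 nt
drifting with length, the geometry real monosome footprints show. Exactly
`reads_per_library` (default 500 000, ≈ 4 reads/codon mean density) reads
are emitted per library.

**RNA-seq.** Gene × sample counts are negative-binomial with dispersion
α = 0.01 (inbred-littermate-like variability; var = μ + αμ²), gene means
log-uniform in 200–2000. A `de_fraction` (0.1) of genes shift expression by
±0.693 natural-log units in the mutant; an independent `te_shift_fraction`
(0.1) shift TE by ±1 log₂ unit (applied to footprint allocation only).
Dispersion below 1e−8 switches to the Poisson limit. k and p are free
simulation parameters, not estimates of any real tissue.

**Randomness.** Every purpose (transcriptome, effects, each library, each
RNA sample) gets an independent `numpy` Generator seeded from
(master seed, purpose tag, condition, replicate), so runs are reproducible
across platforms and any stage can be regenerated in isolation.

What the generator does **not** model: sequencing error, rRNA contamination,
splice isoforms, genome-space mapping ambiguity, frame noise in footprint
placement (all reads are perfectly in frame), and codon-usage covariation
with expression. Passing benchmarks therefore demonstrate the correctness
and calibration of the statistics under the stated model, not performance on
real libraries, where offset calibration and pause detection face additional
noise sources.

## A-site calibration

For each read length L, reads whose 5′ end lies strictly upstream of an
annotated start codon while overlapping it (1 ≤ cds_start − five_prime_pos
< L) form the start-codon metagene. The mode of that distance is the P-site
offset (initiating ribosomes hold the start codon in the P-site); the A-site
offset is the mode + 3 nt. Ties in the mode break toward the smaller offset
(deterministic and conservative); lengths with fewer than `min_support`
(default 30) qualifying reads fall back to the global mode pooled across
lengths, with a warning. Calibration is order-invariant by construction.
Reads whose A-site falls in a UTR are excluded from all codon statistics and
counted separately.

## Occupancy

Expected counts are computed per transcript — total in-window reads divided
by window size — then summed per codon identity, matching the assumption
that reads are uniform across each transcript's coding region and making
the statistic robust to expression differences between transcripts. The
default analysis window excludes the first two codons (the start codon,
which cannot hold the A-site, and the first decoded codon, which carries
the initiation peak — positional, not identity, signal) and the stop codon.
For P-site/E-site occupancy the codon identity is shifted one/two codons
upstream of the A-site index. Replicate aggregation reports mean ± SEM.
Within a library, Σ observed = Σ expected exactly; ratios for codons never
observed in any window are reported as missing (NaN), not zero.

## Pause statistics

The pause z is standardised within each transcript over its own analysis
window (default: first 5 and last 5 codons trimmed; configurable to 0),
using the population (ddof = 0) standard deviation. This within-transcript
construction is the central methodological choice: it makes z invariant
under count scaling (depth and expression), and it is the simplest statistic
for which z ≥ 10 describes a spike that dwarfs a transcript's own
background — note z is bounded by √(n−1) for an n-codon window, so very
short CDSs cannot reach high z by construction. Transcripts with uniform
coverage (σ = 0) are skipped and logged. Density thresholding
(≥ 0.5 reads/codon in **all** samples, inclusive) fixes the analyzed
transcript universe before any scoring.

Gene calling: a gene is called in a replicate if any site with the target
codon identity reaches z ≥ z_min (both thresholds inclusive); the consensus
set requires ≥ `min_replicates` (default 2) replicates. Pairwise overlap
reports |A∩B|/|A| and |A∩B|/|B| plus the full three-set Venn partition,
since "fraction shared" can be read either pairwise or three-way.

For the pause-expression correlation the transcript-level statistic is the
maximum pause score in the window (the strongest stall), averaged over a
gene's transcripts per replicate and summed across replicates, then
Spearman-correlated with the expression effect size (natural-log scale
beta). The Spearman p-value uses exact permutation enumeration for n ≤ 10
and the t-approximation otherwise; ties get average ranks.

## Translational efficiency

Counts: footprints with A-site inside the CDS per gene; RNA counts pass
through the same gene filter (case-sensitive `Hist` prefix removal plus an
optional exclusion list). Both assays are normalised by median-of-ratios
size factors (geometric-mean reference over genes positive in all samples;
total-count fallback for degenerate tables). Per-sample
log₂ TE = log₂((fp + 0.5)/sf) − log₂((rna + 0.5)/sf); the 0.5 pseudocount
stabilises zeros. A per-gene Welch t-test compares conditions — deliberately
simpler than a negative-binomial interaction GLM: at three-vs-three with
moderate dispersion the question "did TE change" is answerable with a
t-test on log ratios, it adds no heavy dependency, and its calibration is
verified by simulation (type-I error at nominal 0.05 within [0.03, 0.07];
power > 0.8 at |Δlog₂TE| = 1, both at the nominal level). Genes with zero
variance in both groups get undefined p and q. BH correction runs across
all genes with defined p.

Codon-filtered TE removes a read iff any codon within ± `window` (default 1,
clipped at CDS boundaries, never wrapping) of its assigned A-site codon
matches the target identity; reads whose A-site lies outside the CDS carry
no A-site codon and are retained. For genes without the target codon the
filter is exactly the identity.

The internal differential-expression test (Welch t on size-factor-normalised
ln counts; beta = natural-log fold change) exists to exercise the synthetic
data and produce effect sizes for the correlation stage; it does not aim at
parity with transcript-abundance-resampling methods, and real analyses
should feed externally computed effect tables in through the documented TSV
interface.

## Pipeline

`run_pipeline` executes simulate → preprocess → asite → occupancy → pause →
te, serialising every intermediate as TSV in the run directory. Any stage
subset can be re-run; inputs absent from memory are loaded from the
serialized intermediates, and identical config + seed yield byte-identical
artifacts either way (verified by hashing). Config validation reports all
violations at once before any compute. The report JSON records per-stage
conservation counts, a config hash (analysis parameters only, excluding the
output location) and the package version; it contains no timestamps, so
reruns diff cleanly.

## Benchmark problem sizes

The acceptance script and the heavier tests use: null occupancy — 500 genes,
10⁶ footprints, one library; pause recovery — 500 genes, 5×10⁵ footprints,
three mutant (k = 50, p = 1) and three control libraries; replicate overlap
— 20 simulations of 150 genes × 1.5×10⁵ footprints × 3 replicates at
p = 0.5; offset round-trip — 200 genes, 2×10⁵ footprints; TE calibration —
20 simulations of 500 genes, 3 vs 3, using the generator's gene-level read
allocation directly (its marginal is identical to the read-level path, which
allocates reads to genes before placing codons). These sizes give each
statistic enough events (≈1500 implanted sites, ≈9000 null tests, 60
replicate pairs) for the stated tolerances to be meaningful.

## Known limitations

* Exact-match adapter search only; a mismatch budget is a config extension
  point, not implemented.
* Offset calibration assumes a start-proximal peak; libraries without
  initiation enrichment (e.g. harringtonine run-off) need externally
  supplied offsets via the offset-table TSV.
* The pause z saturates near √(window size); pause detection on very short
  CDSs is structurally impossible at z ≥ 10, which mirrors the intent of
  the density threshold but should be kept in mind when lowering trims.
* Multi-mapped reads are expected to be resolved upstream (primary
  placements only are ingested from SAM/BAM).
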