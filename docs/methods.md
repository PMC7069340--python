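# Methods

## Model and assumptions

A-to-I editing is observed indirectly: inosine pairs like guanosine during
reverse transcription, so an edited adenosine appears as an A→G mismatch
between an RNA-seq read and the reference genome. On the reverse strand —
or for the antisense-oriented mates of an unstranded library — the same
event appears as T→C in genome space. The toolkit's working model is that,
after per-base quality filtering, each informative read at a site is an
independent Bernoulli draw: edited with probability equal to the site's
editing level. Everything downstream (indices, binomial error bars in the
tests, the differential machinery) follows from that assumption. It ignores
read-pair correlation (an overlapping mate pair contributes two draws),
PCR duplicates, and allele-specific expression; those are the main ways
real data deviates from the model.

## Pileup filters

A base is counted only if its phred quality is ≥ `min_base_qual` (default
30 ≈ 0.1% error) and its 1-based query offset is more than `read_end_trim`
(default 6) from both read ends; offsets 1–6 and the last six are excluded.
The end distance is measured on the query, so soft-clipped bases count
toward it — the trim is a read property, not a reference one. Reads below
`min_mapq` (default 20) contribute no bases and are tallied separately so
downstream filters can reason about locus mapping quality. Deletions,
reference skips and insertions contribute nothing. Overlapping mate pairs
double-count (the generator emits single-end reads, so the test suite is
unaffected); duplicate removal is left to upstream tooling via the
pre-filtered read-stream hook.

## Filter cascade

Stages and defaults: (A) any surviving non-reference base; (B) WGS coverage
≥ 10, WGS non-reference fraction < 0.1 (the homozygosity test — a true het
SNP shows ~50% alternate in genomic reads), and absence from the SNP
exclusion set; (C) RNA coverage ≥ 10 and not inside a reference homopolymer
run longer than 5 (the run containing the site; a run of exactly 5 is
kept); (D) editing frequency ≥ 0.1, where frequency = variant/(ref+variant)
reads; (E) distance > 4 nt from any splice junction, and the fraction of
covering reads that are multi-mapped (NH > 1) or below the MAPQ floor must
not exceed 0.1.

Stage E's read-confidence test is a deliberate proxy for a Blat-style
realignment check: it preserves the intent (discard sites supported by
ambiguously placed reads) without an external aligner binary, and an
adapter hook accepts a per-read concordance verdict so a true realignment
pass can be plugged in. The splice window (4 nt) and low-confidence
fraction (0.1) are toolkit defaults — declared, logged in every run report,
and configurable — because no canonical values exist for "near splice
sites" or "poorly aligned".

The WGS homozygosity threshold (non-reference fraction < 0.1 at coverage
≥ 10) is likewise a declared default: at coverage 10 a true het site passes
it with probability ~P(Binom(10, 0.5) = 0) ≈ 1e-3, so programmed het SNPs
are removed essentially always, which the guarantees suite asserts exactly
on its fixed seeds.

Strand is inferred from the substitution (ref A, alt G → '+'; ref T, alt C
→ '−'); a catalog strand overrides the inference when a site is annotated.

## Spectrum-based FDR

Among the 12 substitution classes, only A→G and T→C carry editing signal.
With class counts c, the summary reports the signal fraction
(c_AG + c_TC)/Σc and estimates the false discovery rate as the mean of the
ten non-signal class counts divided by (c_AG + c_TC) — the expected number
of false calls per signal call if noise is class-uniform. It is 0 on
error-free simulations and undefined (None) when there is no signal at all.

## Indices

All indices are ratios of summed read counts reported in percent, i.e.
coverage-weighted averages of per-site levels:

- overall = 100 · Σ_sites G / Σ_sites (A+G) over a site catalog ('−' sites
  mirrored to C/(T+C)), with **no** per-site coverage cutoff — low-coverage
  sites contribute reads, not unstable frequencies;
- AEI = the same ratio over every reference adenosine inside the stranded
  repeat intervals, restricted to uniquely mapped reads (NH = 1) by
  default; the repeat annotation's strand decides the A/G vs T/C sense, so
  unstranded libraries work;
- REI = the overall index restricted to recoding sites.

The denominator counts only informative (ref + edited) reads; reads
showing a third base at a site are excluded from both numerator and
denominator, since they are evidence of error or genomic variation, not of
editing state. Undefined indices
(zero denominator) are reported as missing, never as 0. The subsampling
robustness check draws catalog subsets without replacement at each
requested size and reports the Pearson correlation (scipy) between
per-sample subset indices and full-catalog indices; zero-variance
replicates report a missing r rather than 0.

## Hyper-editing rescue

Reads failing normal alignment are transformed (A→G pass; additionally T→C
pass for unstranded data, both run by default) and aligned to the equally
transformed genome, which collapses the edited base pair and makes a
heavily edited read match its locus. The built-in aligner is a
seed-and-extend scheme: exact 20-mer seeds from three read offsets, full
read extension, both orientations, best (fewest transformed-space
mismatches) placement wins, with a mismatch budget of 10% of read length.
It exists so the test suite needs no external binary and is sufficient for
the small simulated genomes; the adapter interface accepts any
`align(seq) → (chrom, pos, strand, mismatches)` implementation for real
genomes. After placement, the original read is compared to the original
genome; a cluster passes with ≥ 4 edits, edit purity ≥ 60% of all
mismatches, and other mismatches ≤ 10% of read length. These thresholds
are toolkit defaults, fully configurable and echoed in the run report.
Rescued reads do not feed the AEI, whose read stream comes from the
standard alignment only.

## Differential editing

Eligibility: coverage ≥ 10 in at least ⌈0.5·n⌉ samples per group (the
fraction rule), or an absolute per-group count via `min_samples`. Missing
levels are dropped pairwise, never imputed. The Mann–Whitney U statistic is
U = #{x_i > y_j} + ½·ties; the two-sided p-value is exact — full
enumeration of all C(n₁+n₂, n₁) group assignments, p = 2·min(P(U≤u),
P(U≥u)) capped at 1 — when n₁+n₂ ≤ 12 and the pooled values are tie-free,
otherwise the normal approximation with tie and continuity corrections.
Benjamini–Hochberg runs over exactly the tested sites (m = number tested).
Δ editing = mean(group₂) − mean(group₁) in call order; with groups
(artery, cerebellum) an artery-high site is negative. The coverage-ranked
variant orders sites by total read coverage and gates testing on ≥ 5
qualifying samples per group.

## Synthetic data generator

The generator emulates the structural features that make editing detection
hard: editing concentrated in inverted repeat pairs (each copy diverged 5%
from the consensus so placements are unambiguous, as diverged Alu copies
are), het SNPs as confounders (alternate allele probability 0.5 per read
in both RNA and WGS), independent base errors (default 1e-3), and
hyper-edited reads (≥ 60% of sense adenosines edited) emitted as unmapped
records. Default study conditions: 50 kb genome, 2 inverted repeat pairs of
300 bp, 100 bp reads, 200× RNA / 30× WGS depth, phred 40 bases, programmed
uniform level 0.15 at catalog sites; the AEI checks switch to
`edit_all_alu_adenosines` with per-site Beta(1,9) levels (mean 0.1). Reads
are uniform over the genome — no transcripts, splicing, or coverage bias —
so passing tests certify the counting, filtering and statistics, not
aligner behaviour on real libraries. The differential cohort simulator
draws null levels from Beta(2,8) in both groups and raises the mean by the
programmed shift (same concentration) in group 2 at shifted sites,
coverage Poisson(100), n = 12 per group, 100 null + 10 shifted sites.

All randomness flows from one mandatory seed through named spawned
substreams, so adding a stage never perturbs earlier draws and identical
configs emit byte-identical files. `verify_truth` re-reads an emitted SAM
and recounts per-site tallies independently of the generator's
bookkeeping; it anchors every derived expectation used elsewhere.

## Problem sizes and numerics

The test suite and acceptance script run simulations at 8–20 kb genomes
and 60–200× depth — large enough that binomial error bars are tight
(3 SE ≈ 2 percentage points for the overall index at its default
denominator) and small enough to recount by brute force. Recovery
assertions allow 3 binomial standard errors plus 0.1–0.2 percentage points
for the base-error contribution at non-edited adenosines. Ties in the
most-frequent-alternative choice break alphabetically; undefined values
(empty denominators, zero-variance correlations) are explicit missing
markers throughout.

## Known limitations

No splicing-aware pileup (junction filtering is tested with synthetic
junction lists); no mate-pair overlap deduplication; the built-in rescue
aligner is not suitable for mammalian-scale genomes; SNP handling trusts
the exclusion list plus WGS homozygosity and does not genotype; the
bundled differential-recoding reference table is descriptive input data —
its adjusted p-values are reproduced as published, not recomputed.
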