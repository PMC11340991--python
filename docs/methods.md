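# Methods

This note records the models behind `numtpipe`, the defaults and why they
were chosen, and what the synthetic-data generator does and does not
emulate.

## Genome model

A `GenomeModel` is an ordered set of nuclear chromosomes, a circular
mitochondrial contig (default `chrM`, 16,569 bp, the rCRS length), an
optional genic annotation, and an optional ambiguity mask.  Annotation is
stored for the three genic categories only (CDS, UTR, intron) as disjoint
sorted intervals; intergenic is the complement, so the four categories tile
every chromosome exactly and base-pair fractions always sum to 1.
Overlaps between categories — e.g. an exon of one transcript inside the
intron of another — are resolved once, at construction, with the precedence
CDS > UTR > intron.  Overlapping intervals *within* a category after that
resolution indicate a malformed input and raise.

The `human_like_model` preset uses the true GRCh37 chromosome lengths and a
deterministic repeating gene structure per 100 kb (63,920 bp intergenic,
then a gene of two 17,460-bp introns, three 220-bp CDS exons and two 250-bp
UTRs).  This fixes the genome-wide fractions at intergenic 63.92%, intron
34.92%, CDS 0.66%, UTR 0.50% — the intergenic and intron values match
Ensembl-style genome-wide expectations for GRCh37, and the tiny coding
fraction is split between CDS and UTR in a plausible 4:3 ratio.  Real
annotation differs in gene-length heterogeneity and clustering; analyses
that depend on those features (e.g. per-gene burdens) are out of scope.

## Insertion events

An event is (chromosome, 0-based insertion point, mtDNA segment, length,
variant allele fraction, origin).  Positions are uniform over the
concatenated nuclear genome; the mtDNA segment start is uniform on the
circle and may wrap the origin (represented as `mt_end < mt_start`).

**Length model.**  Only summary statistics of detected non-reference Numts
are available (median 73 bp, mean 1,169 bp, sd ~1,900 bp, range
22 bp–8.2 kb), so the generator uses a two-component lognormal mixture
fitted once to those summaries: weight 0.6 on a short mode (median 38 bp,
σ = 0.6, truncated below at 22 bp by per-component rejection) and 0.4 on a
long tail (μ = 7.774, σ = 0.6, truncated at the mtDNA length).  500k draws
give median 73, mean ≈1,166, sd ≈1,790.  The truncation floor of 22 bp is
the smallest detected insertion; nothing below it is observable by the
junction logic anyway.

**VAF model.**  Mosaic insertions sit at low allele fractions.  Two Beta
presets reproduce the reported summaries: cohort tissue Beta(2.1, 38)
(median ≈0.045, mean 0.052, sd 0.035) and fibroblast Beta(1.4, 11)
(median ≈0.092).  Germline loci default to VAF 0.5.

## Cohort generator

Each sample carries (a) each of the cohort's shared germline loci with
carriage probability 0.925 (8 loci → mean 7.4 per sample), of which 30% are
also present in the simulated population reference, and (b) a
tissue-specific somatic count drawn Poisson around the tissue's mean.  The
default tissue table mirrors a large brain/blood cohort: DLPFC 466 samples
at mean 4.13 tissue-specific events, cerebellum 260 at 0.75, PCC 68 at
1.71, AC 4 at 4.13, whole blood 366 at 3.62, PBMC 23 at 0.26.  Blood's
tissue-specific mean is not separately reported; 3.62 makes the
cohort-weighted tissue-specific mean ≈3.0 and the total per-sample mean
≈10.4, both of which are reported.

**Overdispersion.**  Pure Poisson counts cannot reconcile the reported
means (4.13 vs 0.75) with the reported standardized mean difference
(Hedge's g ≈ 1.0): Poisson variances would give g ≈ 2.2.  The observed g
implies a pooled sd of ≈3.3, i.e. strong between-individual heterogeneity.
Somatic means are therefore multiplied by a gamma frailty with shape
k = 1.1 (variance μ + μ²/k), calibrated analytically from the two reported
quantities.  Set `dispersion=None` for pure Poisson counts.

**Age effect.**  In DLPFC the somatic mean shifts linearly with age at
death, centred at the cohort mean age (88 ± 7 years): −0.2 events/year for
cognitively unimpaired individuals (−2 per decade, the reported direction
and magnitude), −0.1 for mild impairment, 0 for dementia, floored at zero
before the Poisson draw.  Cognitive groups come from a simulated COGDX
score (1 → NCI, 2–3 → MCI, 4–5 → AD) with probabilities matching the
published DLPFC strata.

Somatic events are globally unique by rejection on (chromosome, position),
so the planted somatic set is tissue-exclusive by construction and the
merge → population-filter → exclusivity chain can be checked exactly
against ground truth.

## Longitudinal generator

Each series (donor × treatment) accrues new unique events as a Poisson
process at `rate_per_day` between consecutive collection days, starting at
day 0; events persist and are re-detected independently with a detection
probability (default 1.0, so rate-recovery tests are unconfounded — real
re-detection at ~25× and ~9% VAF is imperfect, and the parameter can be
lowered to study that).  The `lifespan_design` preset reproduces the
12-series lifespan experiment (3 donors × 3 arms + 3 SURF1 patients) with
the published first/last collection days and point counts; exact collection
days are not published, so days are evenly spaced over each range.  Pooled
OLS of count on day is unbiased for the arrival rate under any schedule.
Default per-day rates are the reported per-10-day rates ÷ 10: 0.079
(untreated), 0.107 (Dex), 0.215 (Oligo), 0.371 (SURF1).

## Read-pair evidence

Around a planted junction, sequenced molecules are drawn with fragment
starts Poisson at `depth / (2·read_len)` per bp over a ±1.5 kb window,
Gaussian fragment length (mean 450 bp, sd 100, truncated at twice the read
length; insert sizes are not published, these are typical PCR-free WGS
values), and carrier probability equal to the event VAF.  Carrier molecules
live on the allele `nuclear[0,p) + mt segment + nuclear[p,…)`; each read
maps to the side (left flank / insertion / right flank) holding the
majority of its bases and is clipped to it, so discordant pairs have a
nuclear anchor whose mate lies inside the insertion, with flank-consistent
orientation.  Read-length presets: 151 bp (cohort-style) and 149 bp
(lifespan-style).  Optional chimeric noise re-points a non-carrier mate at
a random mtDNA position.  No base-level sequences or sequencing errors are
simulated: the caller consumes only positions, strands, MAPQ and mate
contigs, so FASTQ-level realism would add nothing the downstream code can
see.

## Caller

Nuclear reads with MAPQ ≥ 10 whose mate maps to the mtDNA contig are
clustered per (chromosome, strand) by single linkage with a 750 bp window
(fragment mean + 3 sd).  A forward (left-flank) cluster pairs with the
nearest reverse cluster within the pairing window; the breakpoint estimate
is the midpoint between the rightmost forward anchor end and the leftmost
reverse anchor start, with the confidence interval spanning both.
One-sided events are emitted flagged, not dropped.  Filter flags:
`min_support` (< 4 pairs), `min_depth` (median per-base coverage in
±300 bp < 5×), `min_qual` (quality < 50), `one_sided`, `anchor_lt150`
(union of nuclear-aligned read segments < 150 bp, the
bacterial-contamination guard).  Call quality is the sum of supporting
anchor MAPQs capped at 99 — the threshold of 50 is prescribed, the score
computation is not, and this choice makes a 4-read MAPQ-60 cluster pass
comfortably while keeping the scale Phred-like.  VAF is supporting pairs
over local depth by default; a sample-mean-coverage denominator is
available (`vaf_denominator="sample"`), since the verbal definition admits
both readings.

Detection requires an mtDNA-mapped mate, so insertions much shorter than a
read length are invisible without split-read refinement, which is
deliberately not implemented (the CI conveys breakpoint uncertainty
instead).  Caller benchmarks therefore plant events ≥ 400 bp; recall on
the full length mixture would be bounded by the short mode, as it is for
any pure read-pair caller.

## Cohort operations

Merging is the transitive closure of "within ±50 bp on the same
chromosome" (single linkage); chains can exceed 50 bp end to end, which
matches the behaviour of VCF merging tools.  The representative breakpoint
is the median of members.  Population filtering removes loci within ±50 bp
of any reference entry, matching on breakpoint distance only because
population references publish genomic positions, not mt segments.
Exclusivity retains loci whose carriers all share one group label; a locus
recurring in many samples of one tissue is retained by default (annotated
with carrier count) because the germline/recurrent distinction is ambiguous
without matched tissues — `max_carriers` enables the stricter reading.

## Hotspot test

Chromosome-bounded 10 Mb bins (terminal bins shorter); the Z-score uses
the sample sd (ddof = 1) across bins, matching the worked reference values
used in the tests, with Z ≡ 0 when all counts are equal.  The null
re-places all sites uniformly over the concatenated nuclear genome
(default 50,000 iterations at production scale; tests use ~1,000).
Empirical p-values use the add-one estimator (1 + #{null ≥ obs}) /
(n_iter + 1), which is never zero and keeps the null super-uniform.  BH
adjustment is the standard step-up with monotonicity enforcement; bins
with q strictly below 0.05 are hotspots.  Shuffling ignores the ambiguity
mask by default; `respect_mask=True` re-draws masked positions.
Stratified scans repeat the whole procedure per stratum, BH within each.

## Rates and statistics

`fit_rate` is OLS with t-based confidence intervals (statsmodels under the
hood; tests verify equality with the closed-form normal equations to
1e-10).  Published per-10-day rates come from regressions on *raw* counts
pooled across donors within an arm; group-median normalization is applied
only when *comparing* slopes across arms, because normalization rescales
slopes (a group median of 0 falls back to a divisor of 1 with a warning).
`compare_slopes` tests the day×group interaction in the pooled model —
algebraically identical to the squared pooled-variance t statistic for the
slope difference, which the tests assert.  Hedge's g uses
J = 1 − 3/(4(n_A+n_B) − 9).  Fold changes are rounded half-even to one
decimal to match printed style.  Age strata are <85, 85–92, ≥93 years,
boundary-inclusive as stated.

## mtDNA copy number

`mtDNAcn = 2 · cov_MT / cov_autosomal` from median per-base coverages;
MAPQ-0 reads are excluded when building tracks, masked positions are
excluded from the autosomal median, and sex chromosomes are never counted
as autosomal.  Median is the default center (mean and mode give
indistinguishable estimates on WGS coverage and are exposed via `center`).
For cross-batch analysis the estimates are log10-transformed and then
z-standardized within each batch: the literal z-then-log order is undefined
for the negative half of a z-distribution, so the mathematically valid
order is the default and the literal order is available behind
`order="z_first"` with a min+1 shift.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: demo genomes of
3 × 2–20 Mb or two 50 Mb chromosomes, 1,000-iteration permutation nulls,
500-replicate rate recoveries, 100-replicate age-association cohorts, and a
50-event caller benchmark at 25× — sizes chosen so the full suite completes
in minutes while keeping Monte-Carlo error an order of magnitude below
every asserted tolerance.  All randomness flows from
`numpy.random.default_rng` seeds; identical seed and configuration give
byte-identical outputs, which the pipeline manifest (SHA-256 per output)
makes checkable.

## Known limitations

* No split-read refinement or assembly: short insertions (< read length)
  are undetectable, and breakpoints carry ±fragment-scale uncertainty.
* Uniform placement for the permutation null ignores mappability and GC
  structure; the mask option only excludes regions, it does not reweight.
* The generator does not simulate reference-Numt-mediated alignments,
  CRAM, base sequences, or heteroplasmy.
* Mixed-effects modelling across donors is not implemented; pooled OLS
  treats points within an arm as exchangeable, as the published analysis
  does.
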