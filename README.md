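# numtpipe

Detection and analysis of **somatic nuclear mitochondrial DNA insertions
(Numts)** from paired-end whole-genome sequencing, for researchers studying
mito-nuclear gene transfer ("numtogenesis") in human tissues and cell
models.

Numts are fragments of the 16,569-bp circular mitochondrial genome that
integrate into nuclear chromosomes.  Beyond the well-known germline
polymorphisms, Numts also arise somatically — postmitotic brain tissue
accumulates more of them than blood, and cultured fibroblasts gain roughly
one new Numt every ~13 days, several-fold faster in cells with mtDNA
instability.  `numtpipe` implements the full analysis stack needed to study
this process, together with a ground-truth synthetic-data generator that
makes every stage testable end to end:

* **simulation** — planted insertion events with a heavy-tailed length
  mixture (median ≈73 bp, mean ≈1,170 bp), low mosaic variant allele
  fractions, multi-tissue cohorts with shared germline loci, longitudinal
  Poisson accumulation, and junction-spanning paired-end read evidence
  written as SAM;
* **calling** — discordant read-pair clustering (nuclear anchor with an
  mtDNA-mapped mate, MAPQ ≥ 10), flank pairing, and quality filters
  (Phred ≥ 50, ≥ 4 supporting pairs, ≥ 5× local depth, ≥ 150 bp anchored
  nuclear sequence), emitted as VCF 4.2;
* **cohort operations** — ±50 bp single-linkage merging of per-sample call
  sets, removal of population-reference germline Numts, and extraction of
  tissue-/cell-line-exclusive somatic candidates;
* **hotspot testing** — 10 Mb genomic bins, Z-scores, uniform-shuffle
  permutation nulls, add-one empirical p-values, Benjamini–Hochberg FDR;
* **rates & statistics** — OLS accumulation rates (`Y = β₀ + β₁X + ε`, X =
  days in culture), slope comparison by interaction ANOVA, group-median
  normalization, fold-changes, Hedge's g, and age-at-death association by
  cognitive stratum;
* **mtDNA copy number** — `mtDNAcn = (cov_MT / cov_autosomal) × 2` from
  median per-base coverage (MAPQ-0 excluded), with within-batch
  log/z standardization.

## Worked example

Simulate the 12-series fibroblast lifespan design (3 healthy donors ×
{untreated, dexamethasone, oligomycin} + 3 SURF1-mutant patients) and fit
per-arm accumulation rates:

```python
import numpy as np
from numtpipe import fit_rate, fold_change, simulate_longitudinal, lifespan_design
from numtpipe.genome import GenomeModel

model = GenomeModel(chromosomes={"chr1": 50_000_000, "chr2": 50_000_000})
rng = np.random.default_rng(7)
cohort = simulate_longitudinal(rng, model, lifespan_design())

rates = {}
for arm, grp in cohort.counts.groupby("treatment"):
    fit = rates[arm] = fit_rate(grp["day"], grp["count"])
    print(f"{arm:6s}  slope = {fit.slope:.4f} Numts/day "
          f"({fit.rate_per_10_days:.2f} per 10 days), "
          f"r2 = {fit.r_squared:.2f}, p = {fit.pvalue:.2e}")

print("SURF1 vs control fold change:",
      fold_change(rates["SURF1"].rate_per_10_days, rates["none"].rate_per_10_days))
```

```
Dex     slope = 0.0824 Numts/day (0.82 per 10 days), r2 = 0.85, p = 1.44e-09
Oligo   slope = 0.1877 Numts/day (1.88 per 10 days), r2 = 0.81, p = 4.06e-07
SURF1   slope = 0.3917 Numts/day (3.92 per 10 days), r2 = 0.95, p = 3.37e-12
none    slope = 0.0700 Numts/day (0.70 per 10 days), r2 = 0.88, p = 1.05e-12
SURF1 vs control fold change: 5.6
```

Each arm's fitted slope scatters around its generating per-day rate
(0.079, 0.107, 0.215, 0.371 for untreated/Dex/Oligo/SURF1); a single
simulated cohort, like a single real experiment, lands within sampling
noise of the truth.  Averaged over many replicates the recovered rates
converge to 0.79 and 3.71 Numts per 10 days (see below).

The same library drives a CLI (`numtpipe run`, `simulate`, `call`,
`somatic`, `hotspot`, `rates`) whose `run` subcommand executes a seeded
end-to-end demo — simulation, calling on generated SAM evidence, merging,
population filtering, exclusivity, hotspot scan, genic annotation, and
rate fitting — and writes a `manifest.json` with parameters and SHA-256
checksums of every output.

## Layout

```
src/numtpipe/
  genome.py      GenomeModel, annotation, masks, human-like presets
  simulate.py    event/length/VAF models, cohorts, longitudinal series, read evidence
  caller.py      discordant-pair scanning, clustering, calling, filters
  callset.py     merging, population filtering, exclusivity, counts
  hotspots.py    binning, permutation nulls, empirical p, BH, hotspot flags
  annotation.py  genic classification and 2x2 enrichment tests
  stats.py       OLS rates, slope ANOVA, Hedge's g, age association
  copynumber.py  coverage summaries and mtDNA copy number
  io.py          SAM / VCF 4.2 / bedGraph / TSV / YAML boundaries
  pipeline.py    staged runs with manifests
  cli.py         click subcommands
docs/methods.md  model and design notes
```
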