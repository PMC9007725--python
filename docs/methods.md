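# Methods

## Region-level quantification

Input is a per-cytosine count table (chrom, 0-based position, sample,
methylated reads, total reads). Counts are summed into capture target
regions by half-open containment (start ≤ pos < end); regions without any
cytosine get (0, 0). Coordinates are BED-convention 0-based half-open
throughout the package; 1-based formats (GTF) are converted at the I/O
boundary. Strand is ignored: capture regions are strand-agnostic. The
beta value is meth/total, left undefined (NaN, never 0) where total = 0.

The pre-test filter keeps exactly the regions with total ≥ `min_total`
(default 1) in **every** sample of the contrasted groups. The default
threshold of a single read is deliberate: "covered" is a presence
criterion, not a depth criterion, and any stricter cutoff is a
reproducible configuration change rather than a silent default.

## The DMR caller

Per region: arithmetic group means of betas; log2 fold enrichment
LFC = log₂((m₁+ε)/(m₂+ε)) with a symmetric ε = 10⁻⁶ guarding zero means
(ε only matters below beta ≈ 10⁻⁴); a two-sided two-sample t-test on raw
betas; Bonferroni adjustment p·m clamped at 1, with m = the number of
regions actually tested after the coverage filter. Significance requires
both p_adj ≤ 0.05 and |LFC| strictly greater than 0.5; significant regions
split into H-DMRs (|LFC| > 2, strictly) and L-DMRs (the rest), so H and L
partition the significant set by construction.

Numerical choices:

- **Welch by default.** With 11 vs 10 samples and no variance pooling
  assumption to lean on, the unequal-variance test is the safer default;
  the pooled-variance Student variant is a config option
  (`test_variant="student"`). On the packaged cohort's age column the
  Welch p-value displays as 0.36.
- **Degenerate rows.** Both groups constant and equal: t = 0, p = 1. Both
  constant and different: p = 0 with a warning — the data are then purely
  deterministic and any nonzero p would be an artefact of the t model.
- **Ties in ordering.** Output is sorted by p_adj, then |LFC| descending,
  with a stable sort, so results are byte-reproducible.
- **Boundary values fail.** |LFC| = 0.5 is not significant; |LFC| = 2 is
  an L-DMR. Thresholds are exceedance thresholds.

## CpG-context annotation

Each chromosome is partitioned relative to its CpG islands: island, shore
(0–2 kb flank), shelf (2–4 kb flank), open sea, with N the
lower-coordinate and S the higher-coordinate flank (Illumina manifest
convention; strand plays no role). When flanks of adjacent islands
collide, every base belongs to the **nearer** island's context, distance
measured to the island edge; an equidistant base goes to the
lower-coordinate island. The implementation builds an explicit tile
partition per chromosome; the test suite checks it base-by-base against a
naive nearest-island scan.

A region possibly spanning several tiles (regions run up to 8,131 bp)
gets a single context by priority island > shore > shelf > open sea among
the contexts it overlaps; within a priority tier the larger base overlap
wins, ties N before S. Priority rather than majority is used because a
region touching an island by a single base is island-regulated in any
biological reading, and it makes enlargement monotone: growing a region
can never demote it below a context it already overlapped.

## Genic annotation

A deliberately simplified single-transcript annotator (no splicing
category, no isoform arbitration): precedence CDS-exonic > 5'UTR > 3'UTR >
ncRNA-exonic > intronic > ncRNA-intronic > upstream/downstream (≤ 1,000 bp
from the transcript boundary, strand-aware) > intergenic, with nearest
gene and distance (0 when overlapping). Overlap with any interval of a
category suffices; ties across genes break by smaller distance, then
lexicographic gene id. "Coding" means CDS-exonic overlap only — UTRs,
introns and ncRNA exons all count as noncoding, which is the dichotomy
used in the coding/noncoding methylation contrast. Because genic
proportions depend entirely on the gene catalogue supplied, they are
descriptive outputs, not fixed expectations.

## Group contrasts

Mann–Whitney U, two-sided. Small tie-free samples (n₁·n₂ ≤ 400) use the
exact null distribution; small samples *with* ties (pooled n ≤ 16) use
exact conditional enumeration over all group splits of the observed
multiset, because at such sizes the normal approximation visibly
disagrees with the permutation distribution; everything larger uses the
tie- and continuity-corrected normal approximation. The pooling unit for
"global methylation" is the per-region per-sample beta; DMR-restricted
strata compare the per-region group means instead (one value per region
per group), which is the reading consistent with comparing DMR methylation
levels between groups.

## Cohort statistics

Clinical cells parse into numeric, left-censored ("<x") or missing ("NA")
states. Default policy excludes censored and missing values from medians,
SDs (n−1 denominator) and t-tests; a substitute(x/2) policy is available.
Exclusion is the convention that reproduces the printed Ki-67 summary of
the packaged cohort (median 2, SD 1.81 over the 7 uncensored GH values).
Categorical 2×2 contrasts use the Yates-corrected chi-square implemented
directly as n·(max(|ad−bc|−n/2, 0))²/(r₁r₂c₁c₂) — the explicit floor
guarantees the corrected statistic never exceeds the uncorrected one,
which a generic "shift observed toward expected by 0.5" implementation
violates for tiny |ad−bc|. A patient with a blank invasion cell is counted
as non-invasive so group denominators stay at the full group size,
matching the cohort's printed 2/11 vs 4/10 proportions. p53 is summarised
descriptively only. Display output rounds half-even to 2 decimals; full
precision is preserved in the JSON summary.

## The simulator

The generator emulates the *structure* of targeted-capture bisulfite data,
not any particular dataset:

- **Genome.** 2 chromosomes × 3 Mb by default, 40 CpG islands per
  chromosome (log-normal lengths around 800 bp) placed ≥ 8 kb apart so
  shores and shelves never collide, and 30 single-transcript gene models
  per chromosome (70% coding) for the genic annotator.
- **Regions.** Non-overlapping, log-normal lengths truncated to
  [2, 8131] bp with mean ≈ 245 bp (the capture panel's printed geometry);
  15% of placements are anchored on islands to emulate a panel's island
  enrichment. The default desk scale is 5,000 regions; the full panel
  scale (437,792) is accepted but logged as beyond desk scale.
- **Methylation.** Region means start from context baselines (island
  0.03, shores 0.45/0.46, shelves 0.58/0.59, open sea 0.52 — the ordering
  and rough levels of capture methylomes) with a logit-normal region
  effect (sd 0.5). The NFPA group mean adds a global logit shift
  (default +0.8, matching the observed tumour-type contrast in order of
  magnitude); planted DMRs additionally add the logit offset that makes
  the expected NFPA/GH ratio exactly 2^±planted_lfc.
- **Planting feasibility.** A planted (region, direction) pair is only
  accepted if both the unshifted mean and the target mean lie in
  [0.05, 0.95]: a nominal 4-fold *decrease* on an island region with mean
  0.03 would be an absolute change of ~0.02, below the binomial noise
  floor at coverage 100 — not a planted effect in any meaningful sense.
  A consequence mirroring real capture studies is that islands almost
  never host planted DMRs. Infeasible draws are reassigned; a shortfall
  is logged.
- **Counts.** Totals are negative-binomial (mean 100, shape 10; ~10%
  coefficient of variation beyond Poisson). Methylated counts are
  beta-binomial: per cell a fraction is drawn from Beta(μc, (1−μ)c) with
  concentration c = 150 (dispersion ρ = 1/(c+1) ≈ 0.0066, a mild
  overdispersion plausible for surgical tumour tissue on a capture
  platform) and the count is Binomial(total, fraction). meth ≤ total holds
  by construction.
- **Cohort.** The null cohort generator draws both groups from identical
  distributions (so ~5% of tests reject at α = 0.05); Ki-67 below 1% is
  censored to "<1", and configurable censoring/missingness rates inject
  additional "<1"/"NA" cells. `fixture="table1"` returns the packaged
  21-patient table verbatim.

All stages draw from seeded, per-stage `numpy` Generator streams; a fixed
seed gives bit-identical outputs, including byte-identical files.

### What the simulator does not emulate

Real tumour methylomes have strong inter-patient heterogeneity *within* a
group (subclonal structure, purity differences, copy-number effects); the
simulator's within-group variation is purely beta-binomial around a shared
region mean. Two consequences: (i) the planted-recovery benchmark is an
upper bound on real-data sensitivity, and (ii) with a global group shift
applied uniformly, a large fraction of simulated regions is *genuinely*
differential, so the default study yields far more significant regions
(~1,400 of 5,000, almost all L-DMRs) than a real cohort of this size
would — in real data the between-patient variance absorbs most of the
global shift. There is also no bisulfite-conversion error, no M-bias, no
read-level structure, and no correlation between neighbouring regions.
Passing recovery tests therefore validate the caller's logic and
calibration, not its real-data power.

## Benchmark and problem sizes

The recovery benchmark uses 2,000 regions, 10 vs 10 samples, coverage
100, 5% planted |LFC| = 2 (sensitivity ≥ 0.9 with all recovered
directions correct); the null experiment repeats the same design with
nothing planted over 20 seeds and expects at most 1 seed with any
significant region (familywise control at the Bonferroni level). These
sizes keep a full benchmark run under ten seconds while leaving the
per-test Bonferroni threshold (2.5 × 10⁻⁵) stringent enough to be a real
test of calibration.

## Known limitations

- Single-transcript gene models; no splicing category or isoform logic.
- The Mann–Whitney exact-with-ties path is limited to pooled n ≤ 16;
  beyond that the corrected normal approximation is used even when ties
  are present.
- The coverage filter treats "covered" as ≥ 1 read by default; studies
  wanting depth guarantees must raise `min_total` explicitly.
- The cohort module assumes exactly two groups and the fixed clinical
  column set; it is a faithful reimplementation of one table's analysis,
  not a general clinical-statistics library.
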