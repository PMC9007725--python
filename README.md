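# capmeth

Targeted-capture methylome differential analysis for pituitary adenomas.

Nonfunctioning pituitary adenomas (NFPAs) tend to be globally
hypermethylated compared with GH-secreting tumours (GH-omas), and the
regions that differ carry potential prognostic information. `capmeth`
implements the full analysis chain used to ask that question from
region-level bisulfite capture data: methylation quantification per target
region, a differentially-methylated-region (DMR) caller, CpG-context and
genic annotation, group-level distribution contrasts, and the clinical
cohort statistics — plus a beta-binomial simulator so every stage is
testable without the original sequencing data.

## The statistics at the core

For each capture target region *r* and sample *s*, the methylation
fraction (beta value) is

&beta;<sub>rs</sub> = meth<sub>rs</sub> / total<sub>rs</sub> &isin; [0, 1],

undefined where total = 0. Only regions covered in **every** GH and NFPA
sample enter testing. Per region the caller computes

- group means &beta;&#772;<sub>NFPA</sub>, &beta;&#772;<sub>GH</sub>;
- log2 fold enrichment LFC = log₂((&beta;&#772;<sub>NFPA</sub> + &epsilon;) / (&beta;&#772;<sub>GH</sub> + &epsilon;)), &epsilon; = 10⁻⁶;
- a two-sided Welch t-test, Bonferroni-corrected over the m tested regions.

A region is a DMR iff p<sub>adj</sub> ≤ 0.05 **and** |LFC| > 0.5; DMRs
split into H-DMRs (|LFC| > 2) and L-DMRs (the rest). Each region gets one
CpG context (island / N,S shore 0–2 kb / N,S shelf 2–4 kb / open sea, by
overlap priority) and one genic category (ANNOVAR-style precedence,
CDS-exonic ⇒ coding). Group distribution contrasts use the Mann–Whitney U
test (exact for small samples, tie-corrected normal approximation
otherwise). Cohort tables with censored ("<1") and missing ("NA") entries
are summarised with medians and n−1 SDs, Welch t-tests, and Yates-corrected
chi-square tests.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data (outputs land in `results/`):

```sh
python analysis/01_simulate_methylome.py
python analysis/02_call_dmrs.py
python analysis/03_annotate_and_compare.py
python analysis/04_cohort_statistics.py
python analysis/05_planted_recovery.py
```

Step 02 prints the analysis funnel on the default 5,000-region simulation
(11 GH vs 10 NFPA, global NFPA hypermethylation, 2% planted DMRs):

```
funnel: 5000 regions -> 5000 covered in all tumour samples -> 1356 significant (3 H-DMR + 1353 L-DMR)
planted-DMR recovery: 92/100 (92.0%)
```

Step 03 shows the annotation mix of those DMRs (overwhelmingly open-sea
and noncoding, as expected when islands are lowly methylated) and the
Mann–Whitney contrasts; globally the simulated NFPAs are hypermethylated
(median beta 0.69 vs 0.51). Step 04 recomputes the clinical table of the
21-patient cohort:

```
          variable  p_value       test  GH_n  GH_median  GH_sd  NFPA_n  NFPA_median  NFPA_sd
               age     0.36    welch_t  10.0       47.0  17.69     9.0         46.0    13.94
           dmax_mm     0.03    welch_t  10.0       13.5  10.68     9.0         30.0     5.83
          ki67_pct     0.44    welch_t   7.0        2.0   1.81     5.0          2.0     0.84
       n_surgeries     0.38    welch_t  11.0        1.0   0.30    10.0          1.0     0.67
               sex     1.00 yates_chi2   ...
cavernous_invasion     0.53 yates_chi2  11.0       18.2           10.0         40.0
```

i.e. the only significant clinical difference is the maximum tumour
diameter (NFPA median 30 mm vs GH 13.5 mm), while cavernous-sinus invasion
(40% vs 18.2%) is not significant. Step 05 benchmarks the caller: at 10
vs 10 samples, coverage 100 and planted |LFC| = 2 it recovers 100/100
planted regions with every direction correct, and across 20 null datasets
no seed yields a single significant region.

A `capmeth` console command exposes the same stages
(`simulate`, `quantify`, `filter`, `dmr`, `annotate`, `compare`,
`cohort`, `run-all`); try `capmeth run-all --seed 7 --out run/`.

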