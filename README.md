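# coordx

Analysis toolkit for the coupling between **transcription** and
**translation** regulatory features encoded in mammalian genes — and for
the question of whether features that raise (or lower) mRNA synthesis
co-occur on the same genes with features that raise (or lower) protein
synthesis.

It is written for computational biologists who want to run, extend or
stress-test this kind of gene-set analysis: every stage is a library
function, the whole pipeline is a statsmodels-style model object, and a
calibrated synthetic cohort generator makes the entire analysis testable
without any external genome or expression download.

## What it computes

**Promoter side.** Each gene's core promoter is classified by scanning the
26-nt window at positions −40..−15 relative to the annotated TSS for the
TATA-box consensus `TATAWAG` (IUPAC, W = A/T). The minimum mismatch count
over all sub-windows assigns one of three classes: *canonical* (0
mismatches), *one-mismatch* (1), or *TATA-less* (≥ 2). Gene length
(txEnd − txStart) and exon count come from the annotation.

**Translation side.** 5′UTRs are scanned frame-agnostically for upstream
AUG triplets (uAUGs, which attenuate translation of the main ORF), and
5′UTR/3′UTR/CDS lengths are tabulated. From ribosome profiling:

- translation efficiency  `TE = footprint reads / mRNA reads`
- ribosomal density  `= TE / CDS length`  (per-nucleotide load of each mRNA)

From Gro-seq (nascent transcription): `rate = reads beyond TSS+1kb /
(gene length − 1 kb)` in reads/kb, the first kilobase excluded to dodge
promoter-proximal pausing, rates < 5 reads/kb flagged as background. From
a multi-tissue atlas: per-gene mean, max, and expression breadth (tissues
≥ 200 units).

**Statistics.** Group contrasts use Mann–Whitney U (two groups) or
Kruskal–Wallis (more), prevalence contrasts the Pearson chi-square,
monotone association Spearman's ρ; distributions are summarised as
boxplots with whiskers at the 12.5/87.5th percentiles and p-values starred
at 0.05/0.01/0.001.

**Synthetic cohorts.** `simulate_cohort` plants all of this structure —
promoter-class frequencies, the TATA↔uAUG dependence, group-dependent
log-normal lengths, and a Gaussian copula tying transcription rate, mRNA
level and ribosomal density to target Spearman correlations — and emits
annotation, FASTA regions, count tables, a tissue matrix and the ground
truth, byte-reproducibly from one seed.

## Worked example

```python
from coordx import SimConfig, simulate_cohort, RegulatoryCoordination

cohort = simulate_cohort(SimConfig(n_genes=5000, seed=1))   # mouse preset
results = RegulatoryCoordination.from_cohort(cohort).fit()
print(results.summary())
```

```
Regulatory coordination analysis
================================================
genes analysed: 5000

uAUG prevalence by promoter class (% uAUG):
  canonical        37.9%  (n=140)
  one_mismatch     28.8%  (n=292)
  tata_less        39.3%  (n=4568)
  chi-square: 12.87, p = 0.00161 **

hypothesis tests run: 43
significant at 0.05: 26
ribosomal_density by uAUG: uAUG_less > uAUG, p = 1.26e-52 ***
mrna_levels by uAUG: uAUG_less > uAUG, p = 9.2e-59 ***
groseq by uAUG: uAUG_less > uAUG, p = 1.34e-32 ***
```

The prevalence block shows the planted negative dependence between
TATA-box strength and uAUG presence (uAUG genes are rarer among TATA
promoters), confirmed by the chi-square. The three direction lines read
the central result off the expression layers: genes *without* a uAUG are
translated more densely, accumulate more mRNA and are transcribed faster.
Individual comparisons carry full detail:

```python
e = results.sections["lengths_by_uaug"]["utr5_length"]
e["groups"]["uAUG_less"]["median"], e["groups"]["uAUG"]["median"], e["stars"]
# (95.0, 252.0, '***')   — uAUG-less genes have much shorter 5'UTRs
```

`results.to_json("report.json")` serialises the full report;
`results.tests_frame()` returns every test as one tidy DataFrame row.

The same pipeline runs from files (refFlat annotation, per-region FASTA,
count TSVs) via `coordx.run_analysis(...)` or the CLI:

```bash
coordx simulate --outdir cohort/ --seed 1 --n-genes 5000
coordx run --cohort-dir cohort/ --outdir out/        # report.json, tests.tsv
coordx tata-scan --promoters cohort/promoters.fa --out calls.tsv
```

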