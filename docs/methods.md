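# Methods

## Promoter classification

The TATA-box is modelled as the degenerate 7-mer `TATAWAG` (IUPAC; W =
A/T). Each gene contributes one 26-nt core-promoter window covering
positions −40..−15 relative to the annotated TSS, both endpoints included
— the maximal reading of a "−40 to −15" region, and the one adopted here
(the alternative 25-nt reading that excludes −15 changes only which
boundary base is scanned, never a class in practice; it is a documented
convention, not a biological claim). Windows are extracted 5′→3′ on the
gene's strand: on `+` the TSS is `txStart` and position −k is genomic
index `TSS − k`; on `−` the TSS base is `txEnd − 1` and the window is the
reverse complement of `[txEnd+14, txEnd+40)`. Only the sense strand is
scanned, because TATA-box function is orientation-dependent.

Every length-7 sub-window is scored by mismatch count (window base not in
the pattern character's allowed set; `N` never matches anything). The
minimum over offsets assigns the class — 0 → canonical, 1 → one-mismatch,
≥ 2 → TATA-less — so the three classes are exhaustive and mutually
exclusive, and adding flanking sequence can never worsen a best match.
Ties between equally good offsets resolve to the most upstream one; this
affects the reported offset only. Windows with > 50% `N` are excluded.
Presence/class is all that downstream analyses use; multiple hits are not
counted.

Transcripts are collapsed to one record per gene symbol before promoter
analysis: the transcript with the longest spliced CDS is retained, ties
broken by lexicographically smaller accession — a deterministic rule
chosen because symbol-level collapsing by itself does not say which
transcript survives. Genes whose promoter window is unavailable (contig
edge) are dropped from TATA-stratified analyses but retained everywhere
else, since the data layers genuinely have different gene universes.

## uAUG detection

The 5′UTR is scanned for the literal triplet `ATG`, frame-agnostically:
any occurrence counts, including ones whose hypothetical uORF would
overlap the main start. A triplet spanning the 5′UTR/CDS boundary does
not count (the scan is confined to the UTR string). Genes split two ways
— uAUG (≥ 1 hit) vs uAUG-less — and an empty or missing 5′UTR is
uAUG-less, because the two-way split admits no third class. Complete
uORF calling (stop codons, Kozak context, secondary structure) is out of
scope by design: presence of the triplet is the feature of interest.

## Expression metrics

- **TE** = footprint/mRNA reads; undefined when mRNA reads are 0 (the
  gene is excluded rather than assigned an infinite ratio).
- **Ribosomal density** = TE / CDS length (nt⁻¹). Scale-invariant to
  joint resequencing depth; undefined for zero-length CDS.
- **Gro-seq rate** = reads beyond TSS+1 kb / ((gene length − 1000)/1000),
  reads/kb. The first kilobase is excluded so promoter-proximal pausing
  cannot inflate the rate; the input table carries the first-kb reads in
  a separate column precisely so tests can assert they never reach the
  rate. Genes ≤ 1 kb are excluded; rates < 5 reads/kb are flagged
  background and dropped from rate comparisons.
- **Tissue summaries**: mean and max over *all* tissues; breadth = number
  of tissues ≥ 200 units (inclusive boundary, fixed for determinism).
  The 200-unit threshold is applied as a gene-level filter — genes whose
  across-tissue mean is below it are excluded from expression-level
  comparisons (this was a genuinely open reading; the gene-level filter
  is the most direct one and is config-exposed).
- **Top/bottom expression split**: the cut is the linear-interpolation
  quantile at 1 − top_fraction; ties at the cut all go to the top set, so
  the split always partitions the cohort deterministically.

## Statistical layer

Skewed, heavy-tailed feature distributions motivate rank-based tests
throughout: Mann–Whitney U for two groups (midrank ties, tie-corrected
normal approximation with continuity correction; exact enumeration
available for small tie-free samples), Kruskal–Wallis for more, Pearson
chi-square without continuity correction for prevalence tables, Spearman
for monotone association. All p-values are two-sided (directions are
reported separately), starred at p < 0.05 / 0.01 / 0.001 with strict
inequalities, and deliberately uncorrected for multiple testing — the
report is a panel of individually interpreted contrasts, and raw
p-values keep it comparable with the conventional presentation of such
panels. Boxplot summaries use linear interpolation between order
statistics (type 7) at the 12.5/25/50/75/87.5th percentiles; one fixed
convention is required for the non-standard whisker positions.

## Synthetic cohort generator

The generator's default configuration *is* the study condition, chosen
once:

- **Class structure.** P(canonical) = 0.030, P(one-mismatch) = 0.055
  (TATA total 8.5%; the canonical/one-mismatch split is not separately
  constrained, and one-mismatch boxes are the larger class);
  P(uAUG | TATA) = 0.024/0.085 ≈ 0.282 and P(uAUG | TATA-less) =
  0.376/0.915 ≈ 0.411, solved exactly so the cohort marginals are
  uAUG = 40% with TATA at 6.0% among uAUG vs 10.2% among uAUG-less
  genes. A human preset (TATA 5%, uAUG 47%, 3.9% vs 5.7%) ships
  alongside.
- **Sequences.** Promoter windows are planted per class and verified by
  the scanner at generation time (canonical: exact instance; one-
  mismatch: exactly one violation, rejection-checked against chance
  exact matches; TATA-less: rejection-sampled to min mismatch ≥ 2).
  uAUG-less 5′UTRs are scrubbed of chance ATGs by mutating the G until
  the scan is clean; uAUG 5′UTRs get one ATG at a uniform position.
  Planting failures raise — a wrong label is never silently emitted.
- **Lengths.** Log-normal (strictly positive, right-skewed) with
  per-(uAUG × TATA)-group medians (e.g. 5′UTR 100 vs 250 nt, gene span
  14 kb vs 27 kb for uAUG-less vs uAUG; TATA groups shorter, with the
  TATA contrast damped inside the uAUG class) and a shared per-gene
  compactness factor (40% of log-scale variance) that makes the four
  lengths positively co-vary, the simplest mechanism for features that
  cluster on genes. Effect sizes are config-exposed choices made for
  realistic visual contrast, not asserted constants. Exon counts are
  1 + Poisson(gene length / 3 kb), so longer genes have more exons; the
  annotation is assembled so exons exactly tile 5′UTR+CDS+3′UTR and the
  spliced CDS length matches the planted one on both strands.
- **Expression.** Latent log-(transcription, mRNA, density) triples come
  from a Gaussian copula with target Spearman correlations (default
  ρ(density, mRNA) = 0.42, ρ(transcription, mRNA) = 0.60,
  ρ(transcription, density) = 0.25), converted to latent Pearson via
  r = 2 sin(πρ/6). Group shifts act additively on the log scale (uAUG:
  −0.45/−0.55/−0.35; TATA: +0.50/+0.40/+0.30, scaled by 0.3 inside the
  uAUG class). Observed counts are negative binomial around the latent
  means (dispersion 100 — gene-level aggregated counts from deep
  libraries are only mildly overdispersed, and the copula calibration is
  meant to survive the count layer; dispersion is config-exposed).
  TE = density × CDS length, footprint mean = TE × mRNA mean. The
  tissue matrix is log-normal around a per-gene level proportional to
  the mRNA latent, 79 tissues, additive floor 20 units.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: read-level alignment artefacts and library
normalisation, mRNA decay (steady-state level here is synthesis-driven
only), sequence composition beyond uniform background, TSS uncertainty,
isoform heterogeneity within a symbol, and any TE–length coupling beyond
the mechanical TE = density × CDS length identity — in this cohort the
TE–CDS-length rank correlation is therefore *positive* by construction,
unlike the small negative association real ribosome profiling shows;
density, not TE, is the calibrated quantity. Length–expression
correlations arise only indirectly through the shared uAUG/TATA group
structure.

For correlation-recovery and type-I-error checks a **calibration
config** (`SimConfig.null`) sets all group shifts to zero and equalises
length medians: the identity-copula case is a true null only when the
class shifts — which correlate all three latents with each other — are
off.

## Problem sizes and numerics

Default analyses run on 20,000-gene cohorts (the scale of a mammalian
RefSeq gene set after symbol collapsing), correlation calibration on
10,000, unit checks on 2,000 — sizes at which binomial 99% intervals and
Fisher-z bounds used in the tests are tight but cohort generation stays
interactive. All randomness flows from one integer-seeded PCG64
generator; emitted files are byte-identical across runs of the same seed,
and the analysis itself is deterministic (sorted-key JSON, fixed float
formatting). Degenerate inputs are handled explicitly: all-tied samples
return H = 0 / p = 1 (U = n₁n₂/2), constant vectors flag Spearman as
undefined rather than raising mid-report, zero marginals and sub-2×2
tables are errors, and empty strata are dropped with warnings before
prevalence tests.

## Known limitations

- genePred/refFlat is the only annotation dialect (header row required);
  no GTF/GFF, no liftover, no TSS refinement from CAGE.
- The promoter scan is presence-only; no PWM scoring, no other core
  promoter elements (Inr, DPE).
- Expression inputs are pre-aggregated per-gene counts; no BAM/read
  processing, no RPKM/TPM normalisation across libraries.
- No multiple-testing correction and no GO-enrichment layer, by scope.
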