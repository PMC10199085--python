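# Methods

## Scope and data model

`cholevar` implements the desk-reproducible portion of a candidate-gene
rare-variant workup for cholestatic liver disease: consequence
classification, inclusion filtering, ACMG-AMP verdict combining,
collapsed-carrier burden testing, and EHR phenotype linkage over five genes
(*ABCB4*, *ABCB11*, *ATP8B1*, *TJP2*, *NR1H4*). Everything is identity-keyed
by `GENE:protein_change` (cDNA label for splice variants, e.g.
`ABCB11:c.2611-2A>T`); genomic coordinates are carried through 1-based from
the VCF but never used for arithmetic, and no liftover is performed.
Upstream steps — sequencing, variant calling, transcript-effect prediction,
running the in-silico predictors themselves, and live literature/ClinVar
queries — are out of scope; their outputs are inputs here (consequence
labels, predictor scores, a static `literature_known` flag).

The packaged data under `cholevar/data/` are transcriptions of published
summary tables for these five genes: the gene panel (cytogenetic band, OMIM
id, exon count, length, PFIC subtype), 50 phenotype-associated non-synonymous
variants, 14 loss-of-function variants, and 15 per-volunteer ICP case
reports. Printed allele-frequency strings are preserved to all printed
digits. Three transcription choices worth knowing: the case-report table's
`NH1R4` gene label is stored as *NR1H4* (the two variants are *NR1H4* rows in
the variant table); one volunteer carries no bile-acid value and is stored
with a missing peak TSBA; and the *ATP8B1* D70N multi-phenotype row is
grouped under {cirrhosis, neoplasm} so that per-gene gallstone tallies match
the published per-phenotype counts.

## Consequence classification

Classification prefers an explicit consequence label, then the HGVS-p string
(`fs`/`fsTer` → frameshift, `Ter` substitution → stop-gained), then a cDNA
splice-acceptor pattern (−1/−2 intronic offset), then the one-letter short
label. Composite labels `frameshift & splice_region` count as frameshift and
`frameshift & start_lost` as a distinct start-lost/frameshift class that
tallies under frameshift — this is the assignment under which the packaged
LoF table reproduces its published 7 frameshift / 5 stop-gained / 2
splice-acceptor split. Unparseable rows classify as `other` with a warning,
never a silent drop.

## Inclusion filter

A missense or LoF variant is included when it passes the MAF < 5% gate and at
least one criterion fires: attached EHR phenotype; literature flag;
cohort-private (gnomAD frequency missing while a cohort frequency exists);
or unanimous deleteriousness across the seven predictors. Decisions the
source analysis left open, resolved here:

* **MAF gate source** — gnomAD global AF when recorded, else cohort AF. The
  published tables retain phenotype-linked variants with gnomAD or cohort AF
  above 5% (e.g. TJP2 Q105K at 5.15%), so variants failing the gate are kept
  when the phenotype criterion fires, flagged `maf_exempt`.
* **Unanimity** — "all seven predictors" is read strictly: seven non-missing,
  seven deleterious calls.
* **Predictor cutoffs** (none are published with the tables; each tool's
  standard recommended threshold is the default, all configurable):
  SIFT ≤ 0.05, PolyPhen-2 ≥ 0.446, CADD phred ≥ 20, REVEL ≥ 0.5,
  M-CAP ≥ 0.025, MetaLR/MetaSVM categorical "D" (or score ≥ 0.5).

The filter is idempotent, order-insensitive, and monotone in phenotype
evidence; all three properties are tested. Over the packaged tables, every
non-synonymous row passes; three LoF rows (ABCB4 Lys30GlyfsTer7, ABCB11
c.2611-2A>T, TJP2 M1MPVX) carry a recorded gnomAD frequency, no phenotype and
no literature flag, and their predictor scores are not printed, so no
criterion can fire for them from packaged data alone — they presumably passed
the original analysis through the in-silico route whose scores live in
unpublished supplementary material.

## ACMG-AMP combining

The engine applies the guideline's combining clauses verbatim (module
docstring lists them). Two conflict conventions:

* **strict** — when a pathogenic-tier and a benign-tier rule both fire the
  verdict is VUS with `conflict_flag` set; BA1 stands alone as Benign in all
  circumstances (every published row containing BA1 is printed Benign).
* **paper_tolerant** — the benign side wins a conflict, and a Benign verdict
  is downgraded to Likely benign when moderate-or-stronger pathogenic codes
  co-occur. This reproduces published Likely-benign calls such as
  {PM1, PP2, PP3, BS1, BS2, BP6} and {PM2, PP2, BP4, BP6} while leaving
  {PP2, BP4, BP6, BS1, BS2} (supporting-only co-evidence) at Benign.

PP5/BP6 (reputable-source codes) count as ordinary supporting evidence —
they appear in the published tables. Rows whose printed verdict cannot be
derived from their own codes (e.g. {PM1, PM2, PP2} printed Likely pathogenic)
are reported as discordant by `validate_against_printed`, by design: the
engine reproduces the guideline, the concordance report documents the
deviations. Correctness is checked against an independent clause-enumeration
oracle on 10,000 random evidence sets plus all sets of size ≤ 2, and strict-
mode monotonicity in pathogenic evidence is property-tested.

## Burden testing

Collapsing follows the CMC scheme: a variant qualifies at cohort allele
frequency ≤ 0.01 (inclusive, matching "0.01 or less"); a sample is a carrier
with ≥ 1 alternate allele at ≥ 1 qualifying variant; missing genotypes are
excluded from both numerator and denominator of the AF. Allele frequencies
for qualification come from the analyzed cohort's genotypes by default
(burden tests collapse on in-sample frequency); an `annotation` mode accepts
external reference frequencies. A gene with no qualifying variant or no
carrier raises an explicit empty-collapse signal instead of fabricating a
p-value.

The 2×2 test is Fisher's exact test, two-sided by minimum-likelihood
summation (the convention of the widely used exact-test implementations; a
one-sided `greater` alternative is available). The implementation delegates
to `scipy.stats.fisher_exact`; the test suite verifies it against an
exact-rational hypergeometric enumeration oracle for every table with all
margins ≤ 12, at relative tolerance 1e-7. Degenerate all-zero margins give
p = 1 by convention. Note the minimum-likelihood two-sided test is close to
exact rather than strictly conservative: simulated type-I error sits near,
occasionally marginally above, the nominal level, which is why the
calibration check uses a three-standard-error upper bound.

Co-carrier grouping returns maximal sets (≥ 2 variants, ≥ 1 carrier) of
variants carried by exactly the same samples — a proxy for
linkage-disequilibrium observations in small carrier counts. No r² is
estimated.

## Synthetic cohort

The generator emulates the study conditions of a volunteer cohort with EHR
linkage:

| parameter | default | basis |
| --- | --- | --- |
| cohort size | 5,236 | published cohort size |
| ICP prevalence | 1.54% | published cohort prevalence |
| variants per gene | 30 | plausible post-filter candidate-gene yield |
| AF spectrum | log-uniform on [1e-4, 0.05] | rare-to-low-frequency filter window |
| cohort-private fraction | 0.34 | published share of gnomAD-absent variants |
| TSBA | log-normal, σ = 0.6 (log scale) | spans the 10 and 40 µmol/L thresholds like the published case values (14–115) |
| TSBA case calibration | 90% of cases ≥ 10 µmol/L; 5% of controls | diagnostic-threshold anchoring |
| bile-acid missingness | 10% | produces the code-positive/BA-missing discordance stratum |

Genotypes are Hardy–Weinberg draws at each variant's AF (samples unrelated
and variants independent — no kinship, no LD except what `plant_co_carriers`
injects explicitly). Case status uses a logistic link on the per-gene
collapsed rare-carrier indicator with configurable odds ratios; the intercept
is solved numerically so the mean risk equals the target prevalence. Cases
are assigned female sex and the ICD-10 code O26.6. Predictor panels and
evidence-code sets are drawn conditional on a planted pathogenicity flag.
The generator records complete ground truth (true AFs, case status, carrier
sets, planted inclusion decisions, planted co-carrier groups); identical
configs give bit-identical output files.

What passing tests on this generator do **not** show: robustness to
relatedness (the real cohort reports parental relatedness and the
independence assumption is knowingly violated there), population structure,
genotyping error, LD between causal and neutral variants, or a realistic
bile-acid distribution — the log-normal TSBA model is a stand-in chosen for
threshold behaviour, not fitted to data.

## Simulation studies and problem sizes

The seeded studies in `cholevar.simstudy` use per-replicate child seeds drawn
from a base seed:

* **Type-I calibration** — 1,000 null replicates (no enrichment, 2,000
  samples at 50% prevalence, so ≈ 1,000 cases vs 1,000 controls); rejection
  at α = 0.05 must stay below 0.05 + 3·√(0.05·0.95/1000) ≈ 0.0707.
* **Power curve** — 200 replicates per planted odds ratio in {1, 2, 4, 8} at
  the same size, same seed ladder across ratios; the rejection rate must be
  non-decreasing.
* **Parameter recovery** — 100 replicates at full cohort scale (5,236
  samples, 1.54% prevalence) with OR = 4 planted on one gene of the panel
  (rotating); the planted gene must attain the smallest burden p in ≥ 90%.

These sizes keep the full suite plus the acceptance script under a minute of
simulation time on one CPU while leaving the binomial error on each estimated
rate small relative to its acceptance margin.

## Known limitations

* Published cohort-level statistics that depend on access-controlled
  individual-level genotypes (the per-gene case–control p-values and the
  external-cohort comparisons) cannot be recomputed from summary tables; the
  calibration/power/recovery studies above stand in for them.
* The ACMG engine combines evidence codes; it does not assign them from raw
  annotations.
* Phenotype vocabulary is fixed to the six groups used by the packaged
  tables; free-text EHR parsing and clinician verification are input flags,
  not computations.
* The exact-carrier-set co-carrier proxy under-detects LD whenever carrier
  sets overlap without being identical.
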