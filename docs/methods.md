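# Methods

`bonevar` implements a desk-scale interpretation pipeline for detecting
underlying monogenic bone disorders in a fracture cohort from annotated
exome variant tables and SNP-array CNV calls. This note records the
procedures, the parameters that matter, the numerical conventions, and what
the synthetic data can and cannot establish.

## The variant-retention funnel

Input is one annotated observation per (patient, variant): gene, collapsed
consequence class, zygosity, call quality (QD), allele frequencies from two
reference population databases (1000 Genomes and gnomAD in the default
setup), a CADD deleteriousness score, and a ClinVar assertion. Upstream
alignment, joint calling and annotation are out of scope; the pipeline
consumes their output.

Three stages run in fixed order, each traced per variant:

1. **Call quality.** Variants with QD ≤ 5 are removed. QD (QUAL normalised
   by allele depth) is a property of raw caller output; records without a
   QD value — typically externally validated variants re-entered into the
   table — are retained and flagged rather than silently dropped.
2. **Consequence restriction.** Retained classes: nonsynonymous, stopgain,
   stoploss, splice-region, UTR, and exonic indels (frameshift and
   in-frame). Synonymous variants and anything outside transcripts are
   removed.
3. **Rarity.** A variant survives iff `max(af_db1, af_db2) < cutoff` for its
   gene, with absence from a database counted as frequency 0 (absence is
   the rarest observable state). The cutoff is an attribute of the panel
   gene: 0.001 for genes of dominantly inherited disorders, 0.01 for
   recessive ones, because a single disease allele of a recessive disorder
   need not be vanishingly rare in the population. The maximum over both
   databases is used — a variant common in either reference is not rare.
   The inequality is strict; this only matters at exact equality and is
   pinned by tests.

The funnel is idempotent, and retained + removed counts always equal the
input count (property-tested).

**Genotype patterns.** On the filtered set, per (patient, gene): any
heterozygous variant in a dominant-disorder gene flags the dominant
pathway; hemizygous calls in the X-linked genes (PLS3, PHEX) are flagged
separately but interpreted along the dominant pathway, matching their
placement in the 0.001 cutoff class. In recessive-disorder genes a
homozygote, a putative compound heterozygote (≥ 2 distinct heterozygous
variants, phase unknown — the cohort has no trio data, so *cis*
configurations cannot be excluded and the report says so), or a single-het
carrier state are flagged; carrier states remain reportable findings.

## Panel

The packaged default panel carries 37 genes: the 15 dominant-class genes
(COL1A1, COL1A2, IFITM5, SGMS2, P4HB, LRP5, WNT1, PLS3, CLCN7, PLEKHM1,
TNFRSF11A, ALPL, PHEX, DKK1, WNT3A) at cutoff 0.001 and 22 recessive-class
genes at 0.01, covering recessive osteogenesis imperfecta, osteopetrosis,
pycnodysostosis and hypophosphatemic disorders. Gene intervals are
indicative GRCh37 coordinates used only for CNV overlap; swap in your own
panel TSV for locus-precise work. Cutoffs can be overridden per row.

## Classification

Two layers, used for different purposes:

**Evidence engine.** `combine_acmg` applies the standard ACMG/AMP
evidence-combination matrix to a profile of evidence codes (PVS1, PS1–PS4,
PM1–PM6, PP1–PP5, BA1, BS1–BS4, BP1–BP7), each at its default strength
unless overridden. The matrix ships as an editable YAML table of minimum
strength counts, so refined combining rules can be swapped in without code
changes. The pathogenic and benign arms are evaluated independently; if
both fire, or neither, the verdict is uncertain significance. The engine is
verified against an independently written brute-force statement of the
published table for every evidence set of up to three codes.

`auto_assign_evidence` derives the automatable codes from annotations: PM2
iff max frequency < 1e-4 (absent = 0); PP3 iff CADD > 15 (strict); PVS1 for
loss of function — nonsense, frameshift, stop-loss, or splice disruption at
a canonical ±1/±2 site (non-canonical splice-region variants are not PVS1);
PS1 / PP5 / BP6 from the ClinVar assertion. Curated codes requiring human
judgment (hotspots, segregation, functional data) are attached to the
variant record. **A curated profile replaces, rather than merges with, the
auto-derived codes**: the curator has already weighed the annotation
evidence, and a union would double-count it (e.g. adding an automatic PP3
on top of a curated {PVS1, PM2} profile would promote a likely-pathogenic
call to pathogenic on no new information).

**Proxy classifier.** For settings where per-variant curation is infeasible
(large control populations), `proxy_classify` calls a variant (likely)
pathogenic iff it is (i) extremely rare (< 1e-4 in both databases), (ii)
computationally supported — CADD > 15, or no CADD available for an LOF
variant — and (iii) LOF or already asserted (likely) pathogenic in ClinVar.
ClinVar (likely) benign assertions pass through; everything else is a VUS.
Two deliberate properties of this rule are preserved, not patched:

- An in-frame indel with no CADD score fails arm (ii) even when clinically
  classifiable as likely pathogenic — the proxy undercounts exactly this
  case (one such carrier in the packaged cohort), which is why proxy-based
  prevalence runs slightly below the engine's.
- A non-LOF variant admitted only through a *likely*-pathogenic ClinVar
  assertion has no counterpart profile reaching likely pathogenic under the
  combining matrix ({PM2, PP3, PP5} is one moderate plus two supporting).
  On the LOF and ClinVar-pathogenic routes the proxy is provably no more
  permissive than the engine (grid-tested); this assertion arm is the
  documented exception.

**VUS report.** Reportable uncertain variants are those with CADD ≥ 20,
plus indel VUS for which no CADD score exists.

## Prevalence and statistics

A patient is a carrier iff ≥ 1 variant in the counted verdict classes
(default: pathogenic + likely pathogenic), under the one-qualifying-variant
-per-carrier assumption. Optional family deduplication keeps one carrier
per family and removes additional carrier relatives from numerator and
denominator, so a segregating familial variant is counted once.

Enrichment against a background population carrier rate `p0` uses the exact
binomial test, one-sided (`greater`) by default — the hypothesis is
enrichment — with the minimum-likelihood two-sided variant available. The
background rate is a parameter (default 0.01); estimating it from a real
reference population is out of scope and replaced by the control-population
generator at desk scale.

Group comparisons follow the cohort-table conventions: Pearson chi-square
without continuity correction when all observed cells are ≥ 5, otherwise
Fisher's exact test (dispatch on *observed* counts, per the stated rule).
Fisher sidedness is two-sided (minimum-likelihood) by default with
one-sided alternatives exposed: on the glucocorticoid-use table
[[4,11],[31,14]] the two-sided exact p is 0.0062 while the one-sided tail
is 0.0051 — the value the source analysis evidently reported (printed as
0.005); neither chi-square variant (0.004 / 0.010) reproduces that number.
Continuous variables use the one-way F test, which for two groups equals
the squared equal-variance t statistic (tested).

Reported percentages round half-up at the printed precision; counts, not
percentages, are the stable quantities (a published "54%" for 8/15 = 53.3%
is a printed-rounding anomaly).

## CNV analysis

Array QC removes probes with GenomeStudio cluster separation < 0.27 (0.27
passes) and flags samples with call rate ≤ 97.5%. Calls (PennCNV-style
TSV; detection itself is upstream) are retained iff supported by ≥ 10
consecutive SNPs, with no minimal size restriction. Overlap with panel
genes is closed-interval intersection (≥ 1 bp; a call ending exactly at a
gene's start counts). Spans are reported in Mb, rounded half-up to one
decimal.

Loss scoring follows the joint ACMG/ClinGen copy-number-loss rubric,
shipped as an editable table of criteria (sections 1–5) with published
default points and allowed ranges. Sections 2, 4 and 5 are evidence-
strength judgments, so every assessment may override a criterion's points
within its range; at most one criterion per section. The total maps to the
standard bands: ≥ 0.99 pathogenic, 0.90–0.98 likely pathogenic, −0.89–0.89
uncertain, −0.90 to −0.98 likely benign, ≤ −0.99 benign (evaluated on the
2-decimal rounded total). Scoring is additive over disjoint sections
(tested). The number of protein-coding genes in a segment (section 3) is
annotation-version-dependent and is taken as an input attribute of the
call, never recomputed from a bundled gene model.

In the packaged fixture the chromosome-6 deletion (6:71,561,194–84,303,230,
GRCh37; 12.7 Mb; 87 genes including the panel gene TENT5A) is assessed with
criteria 1A, 2A, 3C, 4C and 5G selected but only 3C contributing its +0.90
default. The source assessment lists 2A as fulfilled yet reports a total of
0.9, which is inconsistent with 2A's standard +1.0 weight; the package
therefore requires explicit per-assessment points (defaulting to rubric
values), and the fixture encodes 2A at 0 so the documented total is
reproduced. Whether "fulfilled" meant "evaluated" rather than "scored"
remains open; the discrepancy is surfaced, not silently resolved.

## Synthetic data

`generate_cohort` emulates the study conditions the defaults encode: 60
patients, 25% clinically suspected, per-group carrier rates 8/15 and 1/45,
one sibling pair sharing family and carrier status, and a Poisson VUS
burden (mean 0.35/patient, putting ~30% of patients at ≥ 1 VUS). Planted
carriers receive one variant whose attribute draw guarantees both
classifiers call it (likely) pathogenic; background VUS draws guarantee the
proxy rejects them. `generate_control_population` plants carriers at a
configurable background rate (default 1%) to exercise the enrichment
comparison at desk scale. Everything is reproducible from the seed.

What the generator does **not** emulate: nucleotide-level sequence context,
linkage between variants, annotation noise (mis-classified consequences,
discordant ClinVar assertions), genotyping error, and any correlation
between covariates and carrier status. Passing recovery tests therefore
show the pipeline's counting and filtering arithmetic is correct under the
planted model — not that the thresholds are clinically optimal on real
data.

`build_example_cohort` transcribes the motivating cohort: the 60-patient
manifest (group margins matching the published characteristics table), the
nine classified variants with their published consequence/CADD/ClinVar
attributes and *reconstructed minimal* evidence profiles (tagged
`reconstructed`) that reproduce each published verdict under the combining
matrix, the thirteen reportable VUS in twelve patients, and the chr6
deletion. Per-variant population frequencies were not published; they are
encoded as absent-from-database (tagged `assumed_af`), consistent with
every variant having survived the rarity filter.

## Problem sizes and determinism

All fixture computations are exact and deterministic. Simulation-based
tests use 100 replicates of the 60-patient default for interval-coverage
checks and 200 replicates of 600 patients for bias checks — sizes at which
the binomial standard errors make the assertions sharp while the whole
suite runs in seconds. Every random draw flows from a single
`numpy` generator seeded per run.

## Known limitations

- The minimal VCF dialect reads GT plus configured INFO keys only; use the
  TSV dialect for anything richer (multi-allelic sites must be pre-split).
- Compound-heterozygote detection is phase-unaware.
- The ACMG engine evaluates whatever profile it is given; it does not audit
  curated codes against annotations.
- Gene intervals in the default panel are indicative; supply a panel built
  from your annotation release for coordinate-sensitive CNV work.
- The gain/duplication rubric, mosaicism and allele-specific copy number
  are not implemented (only losses are exercised here).
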