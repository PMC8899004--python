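# Methods

This note documents the models, conventions and defaults behind `fibrovar`,
and what its synthetic data can and cannot demonstrate.

## Phenotype model

ECV is computed from longitudinal relaxation rates (R1 = 1/T1). Gadolinium
contrast distributes in extracellular water, so the contrast-induced change in
myocardial R1 relative to blood R1 — the partition coefficient
λ = ΔR1_myo / ΔR1_blood — measures the myocardial extracellular compartment
relative to blood. Scaling by the plasma fraction gives
ECV% = 100 · (1 − Hct) · λ. Assumptions inherited from the standard two-space
model: contrast equilibrium between blood and interstitium at the post-contrast
measurement, no significant intracellular uptake, and a hematocrit measured
near the scan. Inputs with post-contrast T1 ≥ pre-contrast T1 are rejected as
invalid contrast dynamics rather than silently producing negative λ. A
precomputed `ecv` column, when present, takes precedence over derivation.

**Case definition.** Cases are participants strictly above the q = 0.75
quantile of ECV *or* of native T1, computed on the post-exclusion population;
the strict inequality means a participant exactly at a threshold is a control.
The quantile uses linear interpolation between order statistics (NumPy's
default), since the estimator convention is otherwise unspecified; both q and
explicit thresholds are configurable, so a published threshold pair (e.g.
ECV > 28.8%, native T1 > 1,006 ms) can be supplied to reproduce an external
cohort's split exactly. Whether quantiles are computed before or after the
MI/HF exclusion is genuinely open; the default is after, because the exclusion
targets replacement fibrosis that would otherwise distort the interstitial
fibrosis distribution the quartiles are meant to summarize.

## Filter cascade

Stages, in fixed order: panel membership → non-monomorphic in the phenotyped
subsample → coding/canonical-splice → MAF < threshold (strict, in *both*
gnomAD and 1000 Genomes; a frequency absent from a database passes) →
non-synonymous → in-silico → ClinVar screen. Design choices:

- **Non-synonymous** is implemented as exclusion of synonymous and
  stop-retained changes; start/stop losses and splice-disrupting terms count as
  non-synonymous (a start-codon loss is a protein-altering event).
- **In-silico**: pass iff (PolyPhen damaging-spectrum AND CADD ≥ threshold) OR
  (SIFT deleterious AND FATHMM damaging), where any missing prediction counts
  in favour of keeping the variant — "no prediction" is not exculpatory. A
  variant with no scores at all therefore passes. PolyPhen's
  `possibly_damaging` counts as damaging-spectrum. Numeric scores, if supplied,
  are binned at the published cutoffs (PolyPhen 0.446, SIFT 0.05).
- **CADD threshold** defaults to phred 20 (top 1% of deleteriousness genome
  wide) — a conventional cutoff, configurable because no single value is
  canonical.
- **ClinVar screen**: only benign/likely-benign assertions remove a variant;
  absence from ClinVar or a conflicting record is not benign evidence.
- **Monomorphic** means all non-missing genotype codes equal in the phenotyped
  subsample (missing calls ignored; a variant with no non-missing calls shows
  no variation and is monomorphic).

The cascade is provably equivalent to the conjunction of the per-variant
predicates; the test suite asserts this against an independent brute-force
evaluation, plus the subset-chain invariant along stages.

## ACMG/AMP engine

Classification operates on evidence *strengths*, so per-code strength
overrides (`PS1@moderate`) are respected. Combining rules follow the standard
5-tier table: Pathogenic requires PVS1 plus corroboration, ≥2 strong, or
1 strong with sufficient moderate/supporting counts; Likely Pathogenic the
usual weaker combinations; Benign is BA1 or ≥2 strong benign; Likely Benign is
1 strong + 1 supporting or ≥2 supporting benign. Contradictory evidence
yields VUS; contradiction covers both sides qualifying for a call *and* one
side qualifying while the other holds strong-or-stronger evidence (so BA1
together with a strong pathogenic criterion is VUS, not Benign).

`auto_evidence` assigns only file-computable codes: PVS1 (loss-of-function
consequence in a gene whose panel entry is flagged as an LOF-mechanism gene),
PM2 (below the MAF threshold, default 0.1%, in both databases), PP3/BP4
(in-silico consensus requiring ≥2 concordant non-missing calls and no
dissent), PP5/BP6 (ClinVar assertions; deprecated in later guidance and
disabled by a flag), BA1 (gnomAD > 5%), BS1 (gnomAD above a disease-incidence
threshold, default 0.1%). Codes requiring family, de-novo, functional or
literature data (PS1–PS4, PM1, PM3–PM6, PP1, PP2, PP4, BS2–BS4, …) come from a
curator-supplied manual-evidence TSV; a manual code replaces an auto code of
the same name.

**VUS+** models phenotype-supported borderline pathogenicity: a VUS is flagged
when adding one supporting-strength pathogenic criterion would lift it to
Likely Pathogenic or Pathogenic. The added criterion's strength is
configurable; supporting is the default because phenotype concordance alone is
weak evidence. The upgrade never fires on contradictory profiles and never
changes non-VUS calls.

## Enrichment statistics

Carrier counting is person-level: a participant with several qualifying
variants counts once, and a variant in an autosomal-recessive panel gene
requires homozygosity to confer carrier status. Two tier-sets are reported:
{Pathogenic, Likely Pathogenic} and that set plus VUS+.

The two-sided exact test uses the minimum-likelihood convention — summing
hypergeometric point probabilities not exceeding the observed one — the most
common definition and the one whose output on the reported carrier tables
matches the headline p-value after rounding. Point probabilities are evaluated
from log-factorials (`lgamma`), a relative tie tolerance of 1e-7 absorbs
floating-point equality, and a fully included support returns exactly 1.
Degenerate margins (no carriers anywhere, or an empty group) yield p = 1 with
a warning. The odds ratio is a·d/(b·c) with an optional Haldane–Anscombe 0.5
correction; an infinite OR is reported as such rather than hidden. Group
comparisons use the Welch unequal-variance t test for continuous variables and
chi-square for categorical ones, matching standard baseline-table practice.

**Power.** `power_simulation` draws binomial carrier counts per group, applies
the exact test, and reports the rejection fraction with its binomial standard
error. Identical tables share one test evaluation, so 100,000 replicates of
the default design (420 vs 715, 1.6% vs 0.1%, α = 0.05) run in about a second.
Defaults encode the study design: control prevalence 0.1% (the observed
control rate) and a 1.5-percentage-point case excess.

## Synthetic cohorts

`SyntheticCohortSpec` defaults emulate the study conditions: n = 1,164 with 29
MI/HF exclusions; race mix 38/28/23/11% (White/African American/Hispanic/
Chinese American); case-group ECV 29.4 (SD 2.5)% and native T1 1,014
(SD 37.1) ms against control-group 25.6 (1.8)% and 957.2 (30.7) ms; ECV–T1
correlation 0.5 (chosen as a moderate within-person correlation — the two
surrogates index the same biology but are measured independently); P/LP
carrier prevalence 1.2%/0.1% in cases/controls, rising to 1.7%/0.3% with VUS+.

Generation draws a latent case label per participant (probability 420/1135),
then a bivariate normal phenotype per label. Because downstream case status is
*recomputed* from the cohort quartiles, the generator assigns carriers using
that same realized status, so planted 2×2 tables are recovered exactly by the
pipeline — this is what the planted-truth tests assert. Carrier counts are
binomial draws at the specified prevalences (recorded in the truth table, so
assertions are exact rather than approximate). Each planted carrier gets a
private missense variant in a random autosomal-dominant panel gene, placed at
an unused position inside the gene's coordinate window; tier is forced through
the manual-evidence channel (P/LP) or left to auto evidence (plain VUS).
Decoy variants are constructed to clear every cascade stage before their
designated one and fail exactly there; the monomorphic decoy is carried only
by genotyped-but-unphenotyped samples. Identical spec + seed yields
byte-identical output files.

What the generator does *not* emulate: linkage disequilibrium, a realistic
site-frequency spectrum, sequencing or genotyping error, relatedness,
population stratification of carrier status, or any genotype–phenotype causal
coupling beyond the planted group membership. Passing tests therefore
demonstrate correctness of the *pipeline mechanics* (filtering, counting,
classification, testing) under the stated statistical structure, not
robustness to real-data artifacts.

The packaged nine-variant fixture reproduces a published case/control variant
table verbatim where the source is public (positions, genes, consequences,
allele frequencies, ClinVar assertions, tiers, carrier groups) but its
evidence profiles are reverse-engineered synthetic stand-ins chosen to yield
the published tier calls under this engine, since the original per-variant
curation is not public. Its phenotype table is likewise constructed, not
measured: values are deterministic normal-quantile grids arranged so the
published thresholds give the published 139/139/142 exceedance split and
420/715 case/control margin.

## Numerical and interface conventions

- Coordinates 1-based; variant key `chrom:pos ref>alt`; UTF-8; `.` decimals.
- Genotype codes 0/1/2 with −1 for missing; any partially missing diploid call
  is missing.
- Only the GT field of the VCF is consumed; QUAL/FILTER are ignored because
  variant-quality recalibration happens upstream of this analysis.
- The packaged 82-gene panel is a documented compilation of established CM
  genes and is user-replaceable; its per-gene coordinate windows serve only to
  place synthetic variants.
- Test problem sizes (1,000-variant cascade oracle, exhaustive exact-test
  comparison to table total 60, ten planted-truth seeds, 10⁴–10⁵ power
  replicates) were chosen to exercise every code path exhaustively at small
  scale while keeping the default suite fast.

## Known limitations

- The ACMG engine implements the generic combining rules only — no
  gene-specific rule adaptations, Bayesian point systems, or literature
  mining; curator judgment enters solely through the manual-evidence table.
- VCF support is the biallelic-split subset: no structural variants, no indel
  normalization beyond multi-allelic decomposition, genotype phase ignored.
- No covariate-adjusted association modeling or multiple-testing correction is
  provided; the enrichment comparison is a single unadjusted exact test by
  design.
- ECV derivation assumes the two-space equilibrium model; saturation effects
  and partial-volume contamination are out of scope (scalar inputs only).
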