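# Methods

`reglocus` implements a post-GWAS prioritization workflow for candidate
regulatory variants at a disease-associated locus, together with the
companion statistics used in replication and rare-variant follow-up. This
note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data generator does and does
not emulate.

## Candidate selection

Summary statistics are one record per SNP: effect allele = alt, effect size
β = log-odds per alt allele (OR = e^β; files supplying an OR column are
converted by β = ln OR). Selection keeps SNPs inside a user-supplied region
with p ≤ threshold; the default threshold is the conventional suggestive
level 1×10⁻⁵ and the boundary is inclusive. Output is sorted by (p, position)
so results are deterministic. The exact base-pair window of a locus is a
scientific choice, not something the package can infer, so the region is a
required parameter.

## eQTL model

For each candidate SNP, expression is regressed on alt-allele dosage by
ordinary least squares; the slope is reported as the normalized effect size
(NES) with a two-sided t-test on n − k degrees of freedom. Expression is
assumed pre-normalized (portal-style NES values are consumed as-is); a
rank-based inverse-normal transform is available for synthetic vectors. An
optional covariate matrix enters the regression additively; the default is
none, since the intended inputs are portal-level per-gene values. Nominal
p-values are reported; multiplicity policy is left to the caller because
the correction applied by upstream eQTL resources is resource-specific.

Ranking of candidates is by eQTL significance, smallest p first. The
expression-direction call for a SNP classifies whether the *risk* allele
(alt if β > 0, else ref) is associated with lower or raised expression:
the per-alt-allele NES is sign-flipped when the risk allele is ref, and
calls are `indeterminate` when the eQTL p exceeds α (default 0.05,
configurable) or β is missing. The call is invariant to simultaneous
ref/alt relabelling with negation of both β and NES (property-tested).

## Hardy–Weinberg and LD

HWE uses the 1-df goodness-of-fit chi-square against p², 2pq, q² at the
observed allele frequency, with no continuity correction. Monomorphic
input is an error rather than p = 1.

Pairwise LD from unphased genotypes uses the standard two-locus EM: only
the double heterozygote is phase-ambiguous, and its cis/trans split is
re-estimated each iteration from the current haplotype frequencies.
Initialization is at linkage equilibrium (products of allele frequencies),
which is deterministic and interior; tolerance is 1e-10 on the maximum
haplotype-frequency change with a 1000-iteration cap (non-convergence
returns the last estimate flagged, rather than raising). The EM
log-likelihood is asserted non-decreasing at every step. D, D′ and r² are
computed from the fitted haplotype frequencies; "complete LD" is reported
at r² ≥ 0.99 by default (the phrase has no universal numeric definition;
the threshold is configurable).

## Case–control association

From genotype counts in two arms, five 2×2 codings are built: het vs
major-hom, minor-hom vs major-hom, allelic (2N chromosomes), dominant
(carriers vs major-hom) and recessive (minor-hom vs all others). Model
names follow the conventional groupings; published tables occasionally
label the carrier contrast "recessive", so reports carry both the model
name and the explicit grouping. Each table yields:

* OR = ad/bc with a Woolf CI, exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).
  z = 1.96 rather than 1.959964: the difference is below the 3-decimal
  display precision and the choice is recorded here for reproducibility.
* Pearson's 1-df chi-square *without* continuity correction as the default
  test — this is the test that reproduces published replication-table
  p-values from their printed counts — with Fisher's exact test (via
  scipy) as the sparse-cell fallback, applied automatically when a margin
  is zero.
* Any zero cell triggers the Haldane–Anscombe +0.5 correction on all four
  cells for the OR/CI, flagged in the result.

Allele counts can also be reconstructed from printed frequencies
(round(freq × 2n)) to re-analyse results reported only as percentages.

Two reproduction caveats, verified rather than assumed: (i) the upper Woolf
bounds of the very sparse rare-variant tables compute to 14.934/14.772
where the source prints 14.933/14.771 — a final-digit difference
attributable to the original tool's internal rounding; (ii) the printed
allele-row p of 0.116 for the rare-variant table is not reproduced by
Pearson (0.028), Yates-corrected, or two-sided Fisher tests on the printed
counts; the package reports its own tests and makes no claim about the
test used for that single cell.

## Hi-C DNIF

The distance-normalized interaction frequency of a bin pair is
observed / expected, where expected at distance d is the arithmetic mean
of the matrix's d-th diagonal. This is the simplest estimator consistent
with distance normalization; no smoothing, no ICE/KR balancing, and no
bias correction are applied, so values are not comparable to databases
that post-process matrices differently. DNIF is invariant to global depth
rescaling and symmetric in (i, j). A zero expected value yields DNIF 0
with a degenerate flag (sparse test matrices would otherwise error).
SNP–gene scoring uses the bin containing the SNP against either the TSS
bin (caller supplies the strand-aware TSS as the interval start) or the
maximum over gene-overlapping bins; cross-tissue ranking sorts by DNIF
descending with ties broken by tissue label. Matrices are intra-chromosomal
only; the default bin size is 40 kb (configurable). A SNP is scored by its
single containing bin; aggregation over a wider "associated region" is
left to the caller because region extent is a judgment call.

## TFBS overlap and rare-variant filtering

Peak intervals are BED-convention 0-based half-open; SNP positions are
1-based. The conversion (overlap iff s ≤ p−1 < e) lives in one utility so
the two conventions meet in exactly one place. Overlap uses an interval
tree and is tested against a brute-force all-pairs scan.

The rare coding-variant filter keeps variants with population AF strictly
below the cut-off, consequence among {nonsynonymous SNV, stopgain,
frameshift indel, nonframeshift indel}, and not in a segmental
duplication. The default cut-off is 1% (the standard exome-filtering
rule); a stricter 0.01% is selectable by flag. The two thresholds both
appear in follow-up literature and are internally inconsistent there (a
retained variant with population AF 0.03% is incompatible with a 0.01%
cut-off); the package defaults to the methods-level 1% rule and exposes
the choice. Missing population AF means never observed and passes the
rarity filter by convention. CADD and protein-stability values are
passthrough annotations; pathogenicity is never computed.

## Synthetic data

The generator produces inputs with the statistical structure the analysis
assumes, so every stage is testable without external downloads.

* **Genotypes/LD.** Haplotypes are drawn per block: the block's anchor SNP
  is Bernoulli at its allele frequency; each linked SNP copies the anchor
  allele with probability φ = √r²_target, otherwise redraws at its own
  frequency. When block members share an allele frequency this leaves
  marginals exact and gives allelic correlation φ, hence r² equal to the
  target — analytically checkable, unlike pool-resampling schemes whose
  realized frequencies and r² drift with pool size. With differing
  within-block frequencies the marginals of non-anchor SNPs are pulled
  toward the anchor's; block members are therefore given similar
  frequencies in all shipped configurations. Diploids are random pairs of
  haplotypes.
* **Disease.** Single-causal-SNP logistic model: log-odds per alt allele
  ln(disease OR), intercept solved numerically so population prevalence
  matches the configured baseline (default 0.05 — the case-control OR
  estimand is insensitive to this choice for any prevalence ≤ 0.1, which
  was verified analytically before fixing it). Individuals are drawn until
  the case/control quotas fill; an unattainable quota raises after a draw
  cap.
* **Expression.** expr = NES·dosage + N(0, σ); defaults NES −0.3, σ = 1.
* **Hi-C.** Poisson counts around C·(d+1)^(−α) with α = 1 (the classic
  contact-decay exponent), C = 100, plus an optional fold-enrichment at
  one bin pair (a planted loop).
* **Defaults** mirror the intended application's scales: three tightly
  linked lead SNPs with MAF 0.16–0.17 at a 3p21.31-like locus, disease OR
  1.32, replication cohort 202 cases / 929 controls, eQTL panel n = 208.
* **Fixtures.** The published replication genotype counts, the
  coding-variant table (with its six carriers) and the deletion-frequency
  comparison are emitted as files in the formats the other modules read.
  Population AFs for three of the four coding variants are synthetic
  placeholders below every threshold (only the lead rare variant's 0.03%
  is published); decoy variants (one synonymous, one at 2% AF) exercise
  the filter.

What the generator does **not** emulate: polygenic background, realistic
recombination maps or coalescent genealogies, genotyping/sequencing error,
expression covariate structure (batch, ancestry), Hi-C bias fields
(GC/mappability/fragment length) and TADs. Passing tests therefore show
the estimators are correct and well-calibrated under their assumed models,
not that those assumptions hold in any particular real dataset.

## End-to-end prioritization

`prioritize` chains selection → per-candidate eQTL → direction call →
per-tissue DNIF → TFBS overlap, and ranks candidates by (eQTL p ascending,
then maximal DNIF descending, then SNP id). The narrative procedure this
formalizes is a judgment call in practice; the composite rule here is an
explicit, configurable choice and is logged in the report's provenance
header, never a claim about how any published analysis weighted its
evidence. Reports are deterministic given inputs: a '#'-prefixed
provenance block (inputs, parameters, seed, version) followed by a
tab-delimited body. Stage failures abort before anything is written;
an empty candidate set exits with a distinct code (3).

## Problem sizes in shipped checks

The statistical checks run at: 2000 null cohorts (type-I error,
200/900 per arm, MAF 0.18), 500 replicates for OR recovery (planted 1.3)
and eQTL slope recovery (planted −0.3, n = 208), 200 matrices for
planted-loop detection (40 bins, background 100, fold 5), and a 6-SNP
locus with 3000/3000 discovery cohorts for the end-to-end run. These sizes
give sampling error comfortably inside the asserted bands (e.g. ±0.015 on
a 5% rejection rate needs ≈ 2000 draws).

## Known limitations

* The DNIF estimator deliberately omits matrix balancing; absolute values
  are not comparable across differently processed contact maps.
* The EM LD routine handles two loci; multi-SNP phasing is out of scope.
* Logistic-regression association with covariates and trend tests are out
  of scope; the association engine is count-based.
* The eQTL model is single-SNP OLS; no colocalization statistics.
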