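# Methods

This note documents the models, parameter choices and numerical decisions
behind `autozyg`, and what the simulation-based validation does and does
not establish.

## Pedigree model and F_PED

The pedigree module treats unknown parents as unrelated, non-inbred
founders. Consistency checks (duplicated ids, invalid sex codes,
self-parenthood, identical sire and dam, parental-sex mismatch, implausible
parental age, unrealistic birth dates) sever offending links and log every
action; parental-sex mismatches are flagged but kept, because the error may
lie in the sex code rather than the link. A parental age is deemed
plausible when the parent is 2–30 years older than the offspring — a window
chosen for equids and configurable for other species. Ancestry cycles,
which can only arise from recording errors, are broken by severing the
parent links of the newest animal in the cycle (newest by birth date,
falling back to record order) — deleting the most recently recorded, hence
least corroborated, edge.

The additive relationship matrix is built by the tabular method
(`A_ii = 1 + 0.5·A_sd`, `A_ij = 0.5(A_j,s(i) + A_j,d(i))`) after tracing
each target individual's ancestry to a five-generation horizon; tracing
first, rather than filtering afterwards, keeps the matrix small and makes
the horizon explicit. `F_PED = A_ii − 1` is reported only for individuals
with at least five *complete* ancestral generations (all 2^5 slots filled)
and is missing otherwise — never zero-filled, because an absent pedigree is
not evidence of outbreeding. A five-generation horizon deliberately trades
depth for comparability: it captures recent consanguinity uniformly across
animals but is blind to older autozygosity, which is precisely what the
genomic estimators add.

Correctness is checked against a Monte-Carlo gene-dropping oracle (drop
founder allele labels through the pedigree, count label coincidences).
Because the check involves thousands of matrix entries simultaneously, the
per-entry tolerance is a Bonferroni-corrected z bound (family-wise
α = 0.001, never below 3 standard errors); entries with zero Monte-Carlo
variance must match exactly.

## Genotype QC

The QC cascade runs in a fixed, logged order: non-autosomes out → SNP call
rate ≥ 0.90 → exact Hardy–Weinberg test p ≥ 1e-6 → individual missingness
≤ 0.10 → MAF ≥ 0.01. The order matters (individual removal changes per-SNP
statistics); a single pass in this documented order makes runs auditable
and idempotent. The HWE test is the exact conditional test (probability
summed over heterozygote counts no more probable than observed, given the
allele counts), computed with log-gamma arithmetic and validated against
full rational-arithmetic enumeration for all genotype triples with n ≤ 50.
The duplicate/relative screen is the classic method-of-moments IBS→IBD
decomposition with sample allele frequencies; pairs with PI_HAT ≥ 0.95 are
flagged but never removed automatically — sample identity is a curation
decision, not a filter.

## Frequency-based estimators

`F_HOM` uses `(O_HOM − E_HOM)/(m − E_HOM)` per individual over that
individual's non-missing loci. The estimator is invariant to reference
allele flips and may legitimately be negative (fewer homozygotes than the
HWE expectation). `F_GRM` is the VanRaden method-I diagonal minus one;
missing genotypes are set to `2p` (zero after centring), the standard
choice, so they contribute nothing to relationships. Both estimators use
in-sample allele frequencies by default; founder/base-population
frequencies can be supplied, and must be for unbiasedness checks on
simulated data — with in-sample frequencies both estimators centre on zero
*by construction* (the GRM grand sum vanishes), which is a property, not a
bug, of frequency-referenced inbreeding.

## ROH detection

The scan is the standard SNP-array procedure: fully contained 50-SNP
windows (no partial windows at chromosome ends), window homozygous iff
≤ 1 heterozygote and ≤ 5 missing calls, SNP flagged when ≥ 5 % of the
windows covering it are homozygous (denominator = windows actually
formed). Flagged runs are split at inter-SNP gaps > 1 Mb and retained iff
span ≥ 1 Mb, ≥ 15 SNPs, and ≤ 200 kb per SNP. Segment span is
`end_bp − start_bp + 1` over the bounding SNPs; the convention only
matters at exact class-boundary ties, which go to the upper class per the
half-open notation (1–<2, 2–<4, 4–<8, 8–<16, ≥16 Mb). No segment-level
heterozygote allowance exists beyond what the window flags admit. All
eight constants are configurable fields with these defaults. `F_ROH` is
total segment length over the autosomal genome length (2410 Mb for the
horse assembly; the pipeline substitutes the simulated genome length for
simulated data). The implementation is validated against an exhaustive
window-and-run enumeration on 1000 random 500-SNP chromosomes with
randomised parameters.

## HBD hidden Markov model

Hidden classes k = 1..K carry exponential rates `R_k = 2^k` (default
K = 10, rates 2..1024); classes 1..K−1 are HBD, the last is non-HBD. The
literature is genuinely ambiguous about whether the top rate is an HBD or
the non-HBD class and about the age grouping of classes; both groupings
ship as presets (`"methods"`: R2–R8 very recent, R16–R64 recent, R128–R256
intermediate, R≥512 ancient; `"results"`: R2–R4 / R8–R32 / R64+), and the
class structure is configurable. Between markers d Morgan apart the chain
stays in class k with `exp(−R_k d)`; otherwise the segment ends and the
next class is drawn from the mixing weights (re-entry allowed). Emissions:
HBD classes copy one allele with error ε (het probability `2pqε`, hom-ref
`p(1−ε) + p²ε`), non-HBD emits Hardy–Weinberg frequencies; missing
genotypes are uninformative. ε defaults to 0.001; genetic distance comes
from physical position at 1 cM/Mb unless a genetic map is supplied.

Mixing weights are fitted per individual by EM with rates fixed: the
E-step accumulates expected segment starts per class (initial states plus
transition resets — the latent reset indicator inside self-transitions is
handled exactly), the M-step renormalises them. The log-likelihood is
non-decreasing; collapsing weights are floored at 1e-12. `F_HBD` is the
marker-average posterior over HBD classes (not Viterbi coverage); Viterbi
is used only for segment tables, where run boundaries matter more than
calibrated mass. Chromosomes are independent sequences; internally all
individuals and chromosomes are decoded in one padded array pass, which is
what makes 200-individual × 20K-marker cohorts run in ~2 minutes on one
CPU. Forward–backward, posteriors and Viterbi are validated against
exhaustive K^L path enumeration to 1e-10.

## Comparison layer

Descriptives use the sample standard deviation; normality by Shapiro–Wilk
(3 ≤ n ≤ 5000, delegated to scipy); associations by Spearman rank
correlation with average ranks for ties; regressions of F_PED on each
genomic coefficient by OLS (statsmodels), reporting slope, R², adjusted R²
and the slope p-value (identical to the model F-test with one predictor).
Missing data are handled pairwise; p < 0.05 is reported as significant
with no multiple-testing correction, matching common practice in this
literature. Class contributions are per-individual shares (class F over
total F) averaged across individuals, with zero-total individuals excluded
rather than contributing 0/0. Birth-year summaries are per-cohort medians
with small cohorts flagged.

## The simulator and what validation shows

The generator emulates the study system: a small closed population with
deep pedigree loops, SNP-array genotypes at desk scale (default 10
chromosomes × 100 Mb × 2000 evenly spaced SNPs ≈ 20 K markers — a
scaled-down stand-in for a ~56 K array), founder minor-allele frequencies
uniform on [0.05, 0.5], symmetric single-allele genotyping errors and
missingness applied only after truth recording. Crossovers follow a
Poisson process on the genetic map (Haldane, no interference) at 1 cM/Mb.
Identity is defined by founder haplotype labels, so identity-by-state by
chance is excluded from the truth — the autozygosity concept the
estimators target. Each transmitted segment records its full chain of
haplotype copies back to the founder, making the generations-to-coalescence
of every autozygous tract exact (for asymmetric loops, the mean of the two
path lengths).

One statistical subtlety the validation design must respect: all offspring
of a single mating share their parents' realised haplotype mosaics, so a
single full-sib family's mean autozygosity does not converge to the
expected 0.25 however many offspring are simulated. Cohort-level checks
therefore use many independent full-sib units (e.g. 25 units × 4
offspring).

Validation problem sizes were chosen to give tight sampling error at
desk scale: 20 random pedigrees (≤ 25 animals, 1e5 Monte-Carlo drops) for
the A-matrix; 100 random parameterisations of a 3-class HMM on 5–6 markers
for path enumeration; 1000 random 500-SNP fixtures for the ROH scan; all
genotype triples with n ≤ 50 for HWE; a 200-individual, 20 K-marker
gene-dropped cohort for end-to-end recovery (full-sib group mean F_ROH and
F_HBD within ±0.05 of 0.25, truth-vs-estimate rank correlation > 0.9,
≥ 80 % of full-sib HBD mass in classes R2–R8); and 200 × 5000 HWE
genotypes for the null calibration of F_HOM/F_GRM.

What passing does **not** show: the simulator has no selection, migration,
mutation, linkage-map heterogeneity, array ascertainment bias or
population-structured allele frequencies, so real-data behaviour of the
frequency-based estimators (which are sensitive to exactly these) will be
noisier than the simulation suggests; medium-density arrays also bound the
detectable segment-length range in ways the evenly spaced simulated map
only partially reproduces.

## Known limitations

- The tabular A-matrix is dense O(n²); national-scale pedigrees (tens of
  thousands of animals) would need the sparse-inverse machinery that is
  explicitly out of scope.
- HBD rates are fixed by design (the ladder defines the age classes);
  likelihood estimation of rates is not attempted.
- The QC cascade is single-pass; it does not iterate SNP statistics after
  individual removal.
- Phasing, imputation and X-chromosome handling are out of scope;
  chromosomes are modelled independently.
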